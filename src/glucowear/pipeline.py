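"""End-to-end orchestration: simulate -> preprocess -> featurize -> model.

Participants are generated, preprocessed and featurised one at a time so an
8-participant multi-day cohort (hundreds of millions of raw samples) never
has to be held in memory at once; only the per-epoch feature rows survive.
"""

from __future__ import annotations

import pandas as pd

from .features import clean_features, featurize_epochset
from .modeling import MODEL_FAMILIES, RepetitionReport, run_protocol
from .preprocess import preprocess_participant
from .synthetic import SimConfig, inject_missingness, iter_cohort


def build_feature_table(
    config: SimConfig,
    apply_missingness: bool = True,
    verbose: bool = False,
) -> pd.DataFrame:
    """Simulate a cohort and return the raw (uncleaned) epoch feature table."""
    parts = []
    for record, _components in iter_cohort(config):
        if apply_missingness and config.missing_frac > 0:
            inject_missingness(record, config)
        epoch_set = preprocess_participant(record)
        del record
        parts.append(featurize_epochset(epoch_set))
        if verbose:
            print(f"{parts[-1]['participant_id'].iloc[0]}: {len(parts[-1])} epochs")
    return pd.concat(parts, ignore_index=True)


def run_study(
    config: SimConfig,
    n_reps: int = 20,
    base_seed: int | None = None,
    families=MODEL_FAMILIES,
    grids: dict | None = None,
    k: int = 30,
    selector_n_estimators: int = 100,
    cv_folds: int = 5,
    keep_predictions: bool = False,
    verbose: bool = False,
) -> tuple[RepetitionReport, pd.DataFrame]:
    """Full study: feature table, cleaning, and the repetition protocol.

    Returns the report and the cleaned feature table.  ``base_seed``
    defaults to the simulation seed.
    """
    raw = build_feature_table(config, verbose=verbose)
    cleaned, _log = clean_features(raw)
    report = run_protocol(
        cleaned,
        n_reps=n_reps,
        base_seed=config.seed if base_seed is None else base_seed,
        families=families,
        grids=grids,
        k=k,
        selector_n_estimators=selector_n_estimators,
        cv_folds=cv_folds,
        keep_predictions=keep_predictions,
    )
    return report, cleaned
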