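import numpy as np
import pytest

from glucowear.dataio import (
    BiologicalSex,
    Channel,
    GlucoseSeries,
    ParticipantRecord,
    SignalRecord,
)
from glucowear.features import featurize_epochset
from glucowear.preprocess import preprocess_participant
from glucowear.synthetic import SimConfig, inject_missingness, simulate_cohort


def make_participant(
    n_epochs: int = 3,
    t0: float = 0.0,
    glucose: float = 110.0,
    sex: BiologicalSex = BiologicalSex.FEMALE,
    regular: bool = True,
    seed: int = 0,
) -> ParticipantRecord:
    """A small fully-covered participant with simple deterministic channels."""
    rng = np.random.default_rng(seed)
    duration = 300.0 * n_epochs
    signals = {}
    for channel, fs, base, amp in [
        (Channel.HR, 1.0, 70.0, 3.0),
        (Channel.EDA, 4.0, 5.0, 0.2),
        (Channel.TEMP, 4.0, 33.5, 0.1),
        (Channel.BVP, 64.0, 0.0, 40.0),
        (Channel.ACC_MAG, 32.0, 9.8, 0.3),
    ]:
        n = int(duration * fs)
        t = np.arange(n) / fs
        if channel is Channel.BVP:
            vals = amp * -np.sin(2 * np.pi * 1.0 * t)  # 60 bpm pulse train
        else:
            vals = base + amp * rng.standard_normal(n)
        if regular:
            signals[channel] = SignalRecord(channel=channel, fs=fs, values=vals, t0=t0)
        else:
            signals[channel] = SignalRecord(
                channel=channel, fs=fs, values=vals, _timestamps=t0 + t
            )
    cgm_t = t0 + 300.0 * np.arange(1, n_epochs + 1)
    cgm = GlucoseSeries(cgm_t, np.full(n_epochs, glucose))
    return ParticipantRecord("S01", sex, signals, cgm)


@pytest.fixture(scope="session")
def day_cohort():
    """One simulated participant over one day, with default missingness."""
    cfg = SimConfig(n_participants=1, days=1, seed=11)
    records, truth = simulate_cohort(cfg)
    inject_missingness(records[0], cfg)
    return cfg, records[0], truth


@pytest.fixture(scope="session")
def day_feature_table(day_cohort):
    """Raw (uncleaned) 236-column feature table for the one-day participant."""
    _cfg, record, _truth = day_cohort
    return featurize_epochset(preprocess_participant(record))
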