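"""Prediction-accuracy and clinical-accuracy evaluation of glucose models.

Prediction accuracy: R^2, RMSE, NRMSE (RMSE divided by the standard
deviation of the reference series) and MARD (mean absolute relative
difference, in %), the standard CGM accuracy metric.

Agreement: Bland-Altman mean difference (reference - predicted) and limits
of agreement MD +/- 1.96 * SD of the differences.

Clinical accuracy: the Clarke Error Grid (CEG), which partitions the
(reference, predicted) plane into zones A-E of increasing clinical risk.
Zone rules are the canonical piecewise boundaries, resolved in the order
A -> E -> C -> D -> B (first match wins; the 20% criterion of zone A is
inclusive), so every pair lands in exactly one zone:

    A: (ref < 70 and pred < 70) or |pred - ref| <= 0.2 * ref
    E: (ref <= 70 and pred >= 180) or (ref >= 180 and pred <= 70)
    C: (70 <= ref <= 290 and pred >= ref + 110)
       or (130 <= ref <= 180 and pred <= (7/5) * ref - 182)
    D: (ref >= 240 and 70 <= pred <= 180)
       or (ref <= 175/3 and 70 <= pred <= 180)
       or (175/3 <= ref <= 70 and pred >= (6/5) * ref)
    B: otherwise
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

ZONES = ("A", "B", "C", "D", "E")

#: Conventional CEG zone colours for plotting.
ZONE_COLORS = {"A": "green", "B": "gold", "C": "orange", "D": "purple", "E": "pink"}


# ---------------------------------------------------------------------------
# Prediction metrics
# ---------------------------------------------------------------------------


def _check_pairs(reference: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be equal-length 1-D vectors")
    if len(ref) < 2:
        raise ValueError("need at least 2 prediction pairs")
    if np.any(ref <= 0):
        raise ValueError("reference glucose must be positive")
    return ref, pred


def prediction_metrics(reference: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """R^2, RMSE (mg/dL), NRMSE (dimensionless) and MARD (%)."""
    ref, pred = _check_pairs(reference, predicted)
    resid = pred - ref
    sse = float(np.sum(resid**2))
    sst = float(np.sum((ref - ref.mean()) ** 2))
    sd_ref = float(ref.std())
    if sd_ref == 0:
        raise ValueError("reference SD is zero: NRMSE undefined")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return {
        "r2": 1.0 - sse / sst,
        "rmse": rmse,
        "nrmse": rmse / sd_ref,
        "mard": float(100.0 * np.mean(np.abs(resid) / ref)),
    }


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass
class BAStats:
    """Bland-Altman agreement statistics (difference = reference - predicted)."""

    md: float
    sd: float
    loa_low: float
    loa_high: float


def bland_altman(reference: np.ndarray, predicted: np.ndarray) -> BAStats:
    ref, pred = _check_pairs(reference, predicted)
    diff = ref - pred
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BAStats(md=md, sd=sd, loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd)


# ---------------------------------------------------------------------------
# Clarke Error Grid
# ---------------------------------------------------------------------------


def ceg_zone(reference: float, predicted: float) -> str:
    """Clarke Error Grid zone for one (reference, predicted) pair, mg/dL."""
    zones = ceg_zones(np.array([reference]), np.array([predicted]))
    return str(zones[0])


def ceg_zones(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Vectorised CEG zone assignment; exactly one zone per pair."""
    ref = np.asarray(reference, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ValueError("glucose values must be positive")
    out = np.full(ref.shape, "B", dtype="<U1")
    a = ((ref < 70) & (pred < 70)) | (np.abs(pred - ref) <= 0.2 * ref)
    e = ((ref <= 70) & (pred >= 180)) | ((ref >= 180) & (pred <= 70))
    c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182)
    )
    d = (
        ((ref >= 240) & (pred >= 70) & (pred <= 180))
        | ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180))
        | ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))
    )
    # first match wins: A -> E -> C -> D -> B (apply in reverse priority)
    out[d] = "D"
    out[c] = "C"
    out[e] = "E"
    out[a] = "A"
    return out


@dataclass
class CEGResult:
    zone_counts: dict[str, int]
    zone_percentages: dict[str, float]
    ab_percentage: float
    n: int


def ceg_percentages(reference: np.ndarray, predicted: np.ndarray) -> CEGResult:
    """Per-zone percentage of predictions plus the A+B aggregate."""
    ref = np.asarray(reference, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if len(ref) < 1:
        raise ValueError("need at least one pair")
    zones = ceg_zones(ref, pred)
    n = len(zones)
    counts = {z: int(np.count_nonzero(zones == z)) for z in ZONES}
    pct = {z: 100.0 * counts[z] / n for z in ZONES}
    return CEGResult(
        zone_counts=counts,
        zone_percentages=pct,
        ab_percentage=pct["A"] + pct["B"],
        n=n,
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    """All evaluation metrics for one model's predictions."""

    model: str
    n: int
    r2: float
    rmse: float
    nrmse: float
    mard: float
    ba: BAStats
    ceg: CEGResult

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AccuracyReport":
        d = dict(d)
        d["ba"] = BAStats(**d["ba"])
        d["ceg"] = CEGResult(**d["ceg"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AccuracyReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_report(
    reference: np.ndarray,
    predicted: np.ndarray,
    model: str = "",
    ba_plot: str | Path | None = None,
    ceg_plot: str | Path | None = None,
) -> AccuracyReport:
    """Compose metrics, Bland-Altman and CEG results (plots optional)."""
    ref, pred = _check_pairs(reference, predicted)
    metrics = prediction_metrics(ref, pred)
    report = AccuracyReport(
        model=model,
        n=len(ref),
        r2=metrics["r2"],
        rmse=metrics["rmse"],
        nrmse=metrics["nrmse"],
        mard=metrics["mard"],
        ba=bland_altman(ref, pred),
        ceg=ceg_percentages(ref, pred),
    )
    if ba_plot is not None:
        plot_bland_altman(ref, pred, report.ba, ba_plot, model)
    if ceg_plot is not None:
        plot_ceg(ref, pred, ceg_plot, model)
    return report


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def plot_bland_altman(
    reference: np.ndarray,
    predicted: np.ndarray,
    ba: BAStats,
    path: str | Path,
    model: str = "",
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=np.float64)
    diff = ref - np.asarray(predicted, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ref, diff, s=4, alpha=0.4, color="gray")
    ax.axhline(ba.md, color="blue", label=f"MD = {ba.md:.2f}")
    ax.axhline(ba.loa_low, color="orange", linestyle=":", label="LOA")
    ax.axhline(ba.loa_high, color="orange", linestyle=":")
    ax.set_xlabel("Reference glucose (mg/dL)")
    ax.set_ylabel("Reference - predicted (mg/dL)")
    ax.set_title(f"Bland-Altman {model}".strip())
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceg(
    reference: np.ndarray,
    predicted: np.ndarray,
    path: str | Path,
    model: str = "",
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    zones = ceg_zones(ref, pred)
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for z in ZONES:
        m = zones == z
        if m.any():
            ax.scatter(ref[m], pred[m], s=5, alpha=0.5, color=ZONE_COLORS[z], label=z)
    lim = max(400.0, ref.max(), pred.max())
    ax.plot([0, lim], [0, lim], "k--", linewidth=0.8)
    # zone A boundary wedge
    xs = np.linspace(1, lim, 200)
    ax.plot(xs, 1.2 * xs, color="green", linewidth=0.6)
    ax.plot(xs, 0.8 * xs, color="green", linewidth=0.6)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("Reference glucose (mg/dL)")
    ax.set_ylabel("Predicted glucose (mg/dL)")
    ax.set_title(f"Clarke Error Grid {model}".strip())
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
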