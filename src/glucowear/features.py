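"""The 236-feature battery computed on 5-minute epochs.

Categories (fixed manifest, versioned — changing it is a breaking change):

* data-driven features per signal, for HR and skin temperature (sTemp):
  31 time-domain + 14 frequency-domain + 42 non-linear = 87 each;
* 13 heart-rate-variability (HRV) features from the inter-beat intervals of
  the band-passed BVP waveform;
* 42 electrodermal features from the tonic/phasic decomposition of EDA
  (17 distribution statistics per component + 8 phasic SCR event features);
* 3 behavioral features from the accelerometry magnitude over the 2 hours
  preceding each glucose reading (ACC_2h_min / _max / _mean);
* 3 circadian encodings of the reading's clock time (minutes from midnight
  and its sine/cosine);
* 1 demographic encoding (biological sex, male=1 / female=0).

The non-linear battery (entropy, fractal, complexity and recurrence
quantification families) is implemented directly on numpy/scipy with the
parameter choices recorded in :class:`NLParams`.  Skin-temperature epochs
(1200 samples at 4 Hz) are block-averaged 4:1 before the non-linear
estimators, which operate on 300-point series; time- and frequency-domain
features always use the native epoch.

Feature cleaning drops columns with >20% missing values, overflow
(non-finite) values, constant values, duplicates or variance below 1e-5,
then drops rows with infinities or >20% missing feature cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats

from .dataio import BiologicalSex, Channel
from .preprocess import Epoch, EpochSet

MANIFEST_VERSION = "1.0"

# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

TD_NAMES = [
    "mean", "median", "std", "variance", "min", "max", "range", "iqr",
    "skewness", "kurtosis", "rms", "mad", "medad", "cv",
    "p5", "p10", "p25", "p75", "p90", "p95",
    "diff1_meanabs", "diff1_std", "diff2_meanabs", "zcr",
    "slope", "intercept", "energy",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity", "line_length",
]  # 31

FD_NAMES = [
    "total_power",
    "band_power_1", "band_power_2", "band_power_3", "band_power_4",
    "rel_power_1", "rel_power_2", "rel_power_3", "rel_power_4",
    "spectral_entropy", "dominant_freq", "spectral_centroid",
    "spectral_bandwidth", "edge95",
]  # 14

NL_NAMES = [
    # entropy family (16)
    "apen", "sampen", "fuzzyen", "perm3", "perm4", "perm5", "wperm3",
    "svd_en", "shannon_en", "renyi_en", "tsallis_en", "mse2", "mse3",
    "dispen", "bubble_en", "incr_en",
    # fractal family (8)
    "dfa_alpha", "higuchi_fd", "katz_fd", "petrosian_fd", "hurst",
    "corr_dim", "lyap_r", "dma_alpha",
    # complexity family (8)
    "lzc", "hjorth_mobility", "hjorth_complexity", "diff_zcr",
    "forbidden_frac", "stat_complexity", "c0_complexity", "fdispen",
    # RQA family (10)
    "rqa_rr", "rqa_det", "rqa_lmean", "rqa_lmax", "rqa_div", "rqa_lentr",
    "rqa_lam", "rqa_tt", "rqa_vmax", "rqa_det_rr",
]  # 42

HRV_NAMES = [
    "meanNN", "medianNN", "SDNN", "RMSSD", "SDSD", "pNN20", "pNN50",
    "CVNN", "meanHR", "stdHR", "minNN", "maxNN", "IQRNN",
]  # 13

EDA_STAT_NAMES = [
    "mean", "std", "min", "max", "range", "median", "iqr", "skewness",
    "kurtosis", "rms", "energy", "auc", "slope", "diff1_meanabs",
    "diff1_std", "line_length", "cv",
]  # 17 per component

EDA_EVENT_NAMES = [
    "scr_count", "scr_rate_per_min", "scr_amp_mean", "scr_amp_max",
    "scr_amp_sum", "scr_rise_mean", "scr_half_recovery_mean",
    "scr_interval_mean",
]  # 8

BEHAVIORAL_NAMES = ["ACC_2h_min", "ACC_2h_max", "ACC_2h_mean"]
CIRCADIAN_NAMES = ["mins_midnight", "mins_midnight_sin", "mins_midnight_cos"]
DEMOGRAPHIC_NAMES = ["BiologicalSex"]

#: Data-driven signals: manifest label -> (epoch channel, sampling rate).
DATA_DRIVEN_SIGNALS: dict[str, tuple[Channel, float]] = {
    "HR": (Channel.HR, 1.0),
    "sTemp": (Channel.TEMP, 4.0),
}

#: Welch band edges (Hz) per sampling rate, partitioning [0, fs/2].
FREQ_BANDS: dict[float, list[tuple[float, float]]] = {
    1.0: [(0.0, 0.05), (0.05, 0.15), (0.15, 0.3), (0.3, 0.5)],
    4.0: [(0.0, 0.05), (0.05, 0.2), (0.2, 0.6), (0.6, 2.0)],
}


def build_manifest() -> pd.DataFrame:
    """The fixed, ordered feature manifest: name, category, source channel."""
    rows: list[tuple[str, str, str]] = []
    for sig in DATA_DRIVEN_SIGNALS:
        rows += [(f"TD_{sig}_{n}", "physiological_td", sig) for n in TD_NAMES]
        rows += [(f"FD_{sig}_{n}", "physiological_fd", sig) for n in FD_NAMES]
        rows += [(f"NL_{sig}_{n}", "physiological_nl", sig) for n in NL_NAMES]
    rows += [(f"HRV_{n}", "hrv", "BVP") for n in HRV_NAMES]
    rows += [(f"EDA_tonic_{n}", "eda", "EDA") for n in EDA_STAT_NAMES]
    rows += [(f"EDA_phasic_{n}", "eda", "EDA") for n in EDA_STAT_NAMES]
    rows += [(f"EDA_phasic_{n}", "eda", "EDA") for n in EDA_EVENT_NAMES]
    rows += [(n, "behavioral", "ACC_MAG") for n in BEHAVIORAL_NAMES]
    rows += [(n, "circadian", "timestamp") for n in CIRCADIAN_NAMES]
    rows += [(n, "demographic", "demographics") for n in DEMOGRAPHIC_NAMES]
    manifest = pd.DataFrame(rows, columns=["feature_name", "category", "source"])
    if manifest["feature_name"].duplicated().any():
        raise AssertionError("manifest feature names must be unique")
    if len(manifest) != 236:
        raise AssertionError(f"manifest must have 236 features, got {len(manifest)}")
    return manifest


MANIFEST = build_manifest()
FEATURE_NAMES: list[str] = MANIFEST["feature_name"].tolist()


# ---------------------------------------------------------------------------
# Time-domain battery (31)
# ---------------------------------------------------------------------------


def _moment_skew_kurt(x: np.ndarray, mean: float, var: float) -> tuple[float, float]:
    """Biased Fisher-Pearson skewness and excess kurtosis (0 when degenerate)."""
    if var <= 0:
        return 0.0, 0.0
    c = x - mean
    m3 = np.mean(c**3)
    m4 = np.mean(c**4)
    return float(m3 / var**1.5), float(m4 / var**2 - 3.0)


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """31 time-domain statistics of an imputed epoch vector (length >= 4)."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 4 or not np.all(np.isfinite(x)):
        return {n: np.nan for n in TD_NAMES}
    n = len(x)
    mean = x.mean()
    std = x.std()
    var = x.var()
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    centered = x - mean
    zc = np.count_nonzero(np.signbit(centered[1:]) != np.signbit(centered[:-1]))
    # least-squares line against the sample index
    t_mean = (n - 1) / 2.0
    t_var = (n * n - 1) / 12.0
    slope = float(np.mean(centered * (np.arange(n) - t_mean)) / t_var)
    intercept = mean - slope * t_mean
    var_d1 = d1.var()
    mobility = math.sqrt(var_d1 / var) if var > 0 else 0.0
    mobility_d1 = math.sqrt(d2.var() / var_d1) if var_d1 > 0 else 0.0
    complexity = mobility_d1 / mobility if mobility > 0 else 0.0
    p = np.percentile(x, [5, 10, 25, 75, 90, 95])
    skew, kurt = _moment_skew_kurt(x, mean, var)
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "std": std,
        "variance": var,
        "min": x.min(),
        "max": x.max(),
        "range": x.max() - x.min(),
        "iqr": p[3] - p[2],
        "skewness": float(skew) if np.isfinite(skew) else 0.0,
        "kurtosis": float(kurt) if np.isfinite(kurt) else 0.0,
        "rms": math.sqrt(np.mean(x * x)),
        "mad": float(np.mean(np.abs(centered))),
        "medad": float(np.median(np.abs(x - np.median(x)))),
        "cv": std / mean if mean != 0 else np.nan,
        "p5": p[0], "p10": p[1], "p25": p[2],
        "p75": p[3], "p90": p[4], "p95": p[5],
        "diff1_meanabs": float(np.mean(np.abs(d1))),
        "diff1_std": float(d1.std()),
        "diff2_meanabs": float(np.mean(np.abs(d2))),
        "zcr": zc / (n - 1),
        "slope": float(slope),
        "intercept": float(intercept),
        "energy": float(np.sum(x * x)),
        "hjorth_activity": var,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "line_length": float(np.sum(np.abs(d1))),
    }


# ---------------------------------------------------------------------------
# Frequency-domain battery (14)
# ---------------------------------------------------------------------------


def frequency_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Welch-PSD battery (Hann window, 50% overlap, nperseg=min(256, n))."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 64 or not np.all(np.isfinite(x)):
        return {n: np.nan for n in FD_NAMES}
    nperseg = min(256, len(x))
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    df = freqs[1] - freqs[0]
    total = float(psd.sum() * df)
    bands = FREQ_BANDS.get(fs) or _default_bands(fs)
    bp = []
    for i, (lo, hi) in enumerate(bands):
        mask = (freqs > lo) & (freqs <= hi) if i else (freqs >= lo) & (freqs <= hi)
        bp.append(float(psd[mask].sum() * df))
    bp_sum = sum(bp)
    rel = [b / bp_sum if bp_sum > 0 else np.nan for b in bp]
    p = psd / psd.sum() if psd.sum() > 0 else np.full_like(psd, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp_ent = float(-np.nansum(p * np.where(p > 0, np.log(p), 0.0)) / np.log(len(p)))
    centroid = float((freqs * p).sum())
    bandwidth = float(np.sqrt((((freqs - centroid) ** 2) * p).sum()))
    cum = np.cumsum(psd)
    edge95 = float(freqs[np.searchsorted(cum, 0.95 * cum[-1])])
    out = {
        "total_power": total,
        "spectral_entropy": sp_ent,
        "dominant_freq": float(freqs[int(np.argmax(psd))]),
        "spectral_centroid": centroid,
        "spectral_bandwidth": bandwidth,
        "edge95": edge95,
    }
    for i in range(4):
        out[f"band_power_{i + 1}"] = bp[i]
        out[f"rel_power_{i + 1}"] = rel[i]
    return out


def _default_bands(fs: float) -> list[tuple[float, float]]:
    edges = np.linspace(0, fs / 2, 5)
    return list(zip(edges[:-1], edges[1:]))


# ---------------------------------------------------------------------------
# Non-linear battery (42)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NLParams:
    """Parameters of the non-linear estimators (fixed per manifest version)."""

    m_entropy: int = 2  # template length for ApEn/SampEn/FuzzyEn/MSE
    m_embed: int = 3  # embedding dimension for RQA, corr-dim, Lyapunov
    tau: int = 1  # embedding delay
    r_factor: float = 0.2  # tolerance r = r_factor * SD
    rqa_eps_frac: float = 0.1  # recurrence threshold: fraction of max distance
    rqa_lmin: int = 2  # minimum diagonal / vertical line length
    higuchi_kmax: int = 10
    hist_bins: int = 16
    disp_classes: int = 6
    disp_m: int = 3


NL_DEFAULTS = NLParams()


def _cheb_from(d1: np.ndarray, m: int) -> np.ndarray:
    """Template distance matrix of order m from the pointwise |x_i - x_j|."""
    n = d1.shape[0]
    d = d1[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        np.maximum(d, d1[k : n - m + 1 + k, k : n - m + 1 + k], out=d)
    return d


def _cheb_dist(x: np.ndarray, m: int) -> np.ndarray:
    """Chebyshev distance matrix between all m-length templates (delay 1)."""
    return _cheb_from(np.abs(x[:, None] - x[None, :]), m)


def _sampen_from_dists(dm: np.ndarray, dm1: np.ndarray, r: float) -> float:
    # matched template count for both orders; full symmetric matrix minus
    # the diagonal counts every ordered pair twice, which cancels in A/B
    n1 = dm1.shape[0]
    b = np.count_nonzero(dm[:n1, :n1] <= r) - n1
    a = np.count_nonzero(dm1 <= r) - n1
    if b == 0 or a == 0:
        return np.nan
    return -math.log(a / b)


def _sample_entropy(
    x: np.ndarray,
    m: int,
    r: float,
    dm: np.ndarray | None = None,
    dm1: np.ndarray | None = None,
) -> float:
    if len(x) < m + 2:
        return np.nan
    if np.ptp(x) == 0:
        return 0.0  # no surprise in a constant series, by convention
    if dm is None or dm1 is None:
        d1 = np.abs(x[:, None] - x[None, :])
        dm, dm1 = _cheb_from(d1, m), _cheb_from(d1, m + 1)
    return _sampen_from_dists(dm, dm1, r)


def _approx_entropy(x: np.ndarray, m: int, r: float,
                    dm: np.ndarray | None = None,
                    dm1: np.ndarray | None = None) -> float:
    if np.ptp(x) == 0:
        return 0.0
    if dm is None or dm1 is None:
        d1 = np.abs(x[:, None] - x[None, :])
        dm, dm1 = _cheb_from(d1, m), _cheb_from(d1, m + 1)

    def phi(d: np.ndarray) -> float:
        c = np.count_nonzero(d <= r, axis=1) / d.shape[0]
        return float(np.mean(np.log(c)))

    return phi(dm) - phi(dm1)


def _fuzzy_entropy(x: np.ndarray, m: int, r: float,
                   dm: np.ndarray | None = None,
                   dm1: np.ndarray | None = None) -> float:
    if np.ptp(x) == 0 or r == 0:
        return 0.0
    if dm is None or dm1 is None:
        d1 = np.abs(x[:, None] - x[None, :])
        dm, dm1 = _cheb_from(d1, m), _cheb_from(d1, m + 1)

    def phi(d: np.ndarray) -> float:
        n = d.shape[0]
        sim = np.exp(-((d / r) ** 2))
        return float((sim.sum() - n) / (n * (n - 1)))

    p_m, p_m1 = phi(dm), phi(dm1)
    if p_m <= 0 or p_m1 <= 0:
        return np.nan
    return math.log(p_m / p_m1)


def _ordinal_patterns(x: np.ndarray, order: int) -> np.ndarray:
    w = sliding_window_view(x, order)
    return (np.argsort(np.argsort(w, axis=1), axis=1)
            * (order ** np.arange(order))).sum(axis=1)


def _perm_entropy(x: np.ndarray, order: int, normalize: bool = True) -> float:
    codes = _ordinal_patterns(x, order)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(order))) if normalize else float(h)


def _weighted_perm_entropy(x: np.ndarray, order: int) -> float:
    w = sliding_window_view(x, order)
    codes = _ordinal_patterns(x, order)
    weights = w.var(axis=1)
    if weights.sum() == 0:
        return 0.0
    df = np.zeros(int(codes.max()) + 1)
    np.add.at(df, codes, weights)
    p = df[df > 0] / weights.sum()
    return float(-np.sum(p * np.log(p)) / math.log(math.factorial(order)))


def _svd_entropy(x: np.ndarray, order: int = 3) -> float:
    w = sliding_window_view(x, order)
    sv = np.linalg.svd(w, compute_uv=False)
    if sv.sum() == 0:
        return 0.0
    p = sv / sv.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / math.log(order))


def _hist_probs(x: np.ndarray, bins: int) -> np.ndarray:
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    return p[p > 0]


def _shannon_entropy(x: np.ndarray, bins: int) -> float:
    p = _hist_probs(x, bins)
    return float(-np.sum(p * np.log(p)) / math.log(bins))


def _renyi_entropy(x: np.ndarray, bins: int, q: float = 2.0) -> float:
    p = _hist_probs(x, bins)
    return float(math.log(np.sum(p**q)) / (1 - q))


def _tsallis_entropy(x: np.ndarray, bins: int, q: float = 2.0) -> float:
    p = _hist_probs(x, bins)
    return float((1 - np.sum(p**q)) / (q - 1))


def _coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    n = len(x) // scale
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def _dispersion_patterns(x: np.ndarray, c: int, m: int) -> np.ndarray:
    mu, sigma = x.mean(), x.std()
    if sigma == 0:
        z = np.full(len(x), (c + 1) // 2)
    else:
        y = stats.norm.cdf(x, loc=mu, scale=sigma)
        z = np.minimum(np.maximum(np.ceil(y * c), 1), c).astype(int)
    w = sliding_window_view(z, m)
    return (w * (c ** np.arange(m))).sum(axis=1)


def _dispersion_entropy(x: np.ndarray, c: int, m: int) -> float:
    codes = _dispersion_patterns(x, c, m)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)) / (m * math.log(c)))


def _fdispersion_entropy(x: np.ndarray, c: int, m: int) -> float:
    """Fluctuation-based dispersion entropy (patterns of class increments)."""
    mu, sigma = x.mean(), x.std()
    if sigma == 0:
        return 0.0
    y = stats.norm.cdf(x, loc=mu, scale=sigma)
    z = np.minimum(np.maximum(np.ceil(y * c), 1), c).astype(int)
    dz = np.diff(sliding_window_view(z, m), axis=1) + (c - 1)  # 0..2c-2
    codes = (dz * ((2 * c - 1) ** np.arange(m - 1))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)) / ((m - 1) * math.log(2 * c - 1)))


def _bubble_entropy(x: np.ndarray, m: int = 10) -> float:
    """Renyi-2 entropy growth of the per-window inversion-count distribution."""

    def h2_swaps(mm: int) -> float:
        w = sliding_window_view(x, mm)
        inv = np.zeros(w.shape[0], dtype=np.int64)
        for i in range(mm - 1):
            inv += (w[:, i, None] > w[:, i + 1 :]).sum(axis=1)
        _, counts = np.unique(inv, return_counts=True)
        p = counts / counts.sum()
        return -math.log(float(np.sum(p**2)))

    if len(x) < m + 2 or np.ptp(x) == 0:
        return 0.0
    return (h2_swaps(m + 1) - h2_swaps(m)) / math.log((m + 1) / m)


def _increment_entropy(x: np.ndarray, m: int = 2, res: int = 4) -> float:
    d = np.diff(x)
    sigma = d.std()
    if sigma == 0:
        return 0.0
    q = np.sign(d) * np.minimum(np.floor(np.abs(d) * res / sigma), res)
    w = sliding_window_view(q + res, m)  # values in 0..2*res
    codes = (w * ((2 * res + 1) ** np.arange(m))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)) / (m * math.log(2 * res + 1)))


def _dfa(x: np.ndarray) -> float:
    y = np.cumsum(x - x.mean())
    n = len(y)
    scales = np.unique(np.floor(np.logspace(np.log10(4), np.log10(n // 4), 10)).astype(int))
    scales = scales[scales >= 4]
    flucts = []
    for s in scales:
        k = n // s
        segs = y[: k * s].reshape(k, s)
        # closed-form linear detrend residuals per segment
        tc = np.arange(s) - (s - 1) / 2.0
        sxx = float(np.sum(tc * tc))
        seg_mean = segs.mean(axis=1, keepdims=True)
        sxy = (segs * tc).sum(axis=1)
        syy = ((segs - seg_mean) ** 2).sum(axis=1)
        resid_ms = (syy - sxy * sxy / sxx) / s
        flucts.append(np.sqrt(max(np.mean(resid_ms), 0.0)))
    flucts = np.asarray(flucts)
    ok = flucts > 0
    if ok.sum() < 2:
        return np.nan
    return float(np.polyfit(np.log(scales[ok]), np.log(flucts[ok]), 1)[0])


def _dma(x: np.ndarray) -> float:
    """Detrended-moving-average scaling exponent."""
    y = np.cumsum(x - x.mean())
    scales = [4, 8, 16, 32]
    flucts = []
    for s in scales:
        if len(y) < 2 * s:
            continue
        ma = np.convolve(y, np.ones(s) / s, mode="valid")
        resid = y[s - 1 :] - ma
        flucts.append(np.sqrt(np.mean(resid**2)))
    if len(flucts) < 2:
        return np.nan
    ok = np.asarray(flucts) > 0
    if ok.sum() < 2:
        return np.nan
    ls = np.log(np.asarray(scales[: len(flucts)])[ok])
    return float(np.polyfit(ls, np.log(np.asarray(flucts)[ok]), 1)[0])


def _higuchi_fd(x: np.ndarray, kmax: int) -> float:
    n = len(x)
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        s = np.abs(x[k:] - x[:-k])  # s[j] = |x[j+k] - x[j]|
        groups = np.arange(len(s)) % k
        sums = np.bincount(groups, weights=s, minlength=k)
        counts = np.bincount(groups, minlength=k)
        ok = counts >= 1
        if not ok.any():
            continue
        lengths = sums[ok] * (n - 1) / counts[ok] / k
        mean_l = lengths.mean()
        if mean_l > 0:
            lk.append(math.log(mean_l / k))
            ks.append(math.log(1.0 / k))
    if len(lk) < 2:
        return np.nan
    return float(np.polyfit(ks, lk, 1)[0])


def _katz_fd(x: np.ndarray) -> float:
    dists = np.abs(np.diff(x))
    total = dists.sum()
    if total == 0:
        return 1.0
    n = len(dists)
    d = np.max(np.abs(x - x[0]))
    if d == 0:
        return 1.0
    return float(math.log10(n) / (math.log10(n) + math.log10(d / total)))


def _petrosian_fd(x: np.ndarray) -> float:
    d = np.diff(x)
    n_delta = np.count_nonzero(np.signbit(d[1:]) != np.signbit(d[:-1]))
    n = len(x)
    return float(math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * n_delta))))


def _hurst_rs(x: np.ndarray) -> float:
    n = len(x)
    sizes = np.unique(np.floor(np.logspace(np.log10(8), np.log10(n // 2), 8)).astype(int))
    rs_vals, ok_sizes = [], []
    for s in sizes:
        k = n // s
        segs = x[: k * s].reshape(k, s)
        mean = segs.mean(axis=1, keepdims=True)
        z = np.cumsum(segs - mean, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1)
        good = sd > 0
        if good.sum() == 0:
            continue
        rs = np.mean(r[good] / sd[good])
        if rs > 0:
            rs_vals.append(rs)
            ok_sizes.append(s)
    if len(rs_vals) < 2:
        return np.nan
    return float(np.polyfit(np.log(ok_sizes), np.log(rs_vals), 1)[0])


def _corr_dim(d: np.ndarray) -> float:
    """Grassberger-Procaccia slope between two correlation-sum radii."""
    flat = d.ravel()
    pos = flat[flat > 0]  # symmetric: every pair twice; ratios are unaffected
    if len(pos) < 20:
        return np.nan
    # radii from a strided subsample (deterministic); sums over all pairs
    r1, r2 = np.percentile(pos[:: max(1, len(pos) // 8192)], [10, 40])
    if r1 <= 0 or r2 <= r1:
        return np.nan
    c1 = np.count_nonzero(pos <= r1) / len(pos)
    c2 = np.count_nonzero(pos <= r2) / len(pos)
    if c1 == 0 or c2 <= c1:
        return np.nan
    return float((math.log(c2) - math.log(c1)) / (math.log(r2) - math.log(r1)))


def _lyap_rosenstein(d: np.ndarray, min_sep: int = 10, k_steps: int = 12) -> float:
    n = d.shape[0]
    if n <= min_sep + k_steps + 1:
        return np.nan
    masked = d.copy()
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= min_sep
    masked[band] = np.inf
    nn = np.argmin(masked, axis=1)
    base = n - k_steps
    i_idx = np.arange(base)
    valid = nn[:base] < base
    if valid.sum() < 10:
        return np.nan
    i_idx = i_idx[valid]
    j_idx = nn[:base][valid]
    logs = np.zeros(k_steps)
    for k in range(1, k_steps + 1):
        dk = d[i_idx + k, j_idx + k]
        good = dk > 0
        if good.sum() == 0:
            return np.nan
        logs[k - 1] = np.mean(np.log(dk[good]))
    return float(np.polyfit(np.arange(1, k_steps + 1), logs, 1)[0])


def _lz_complexity(x: np.ndarray) -> float:
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    n = len(s)
    if n == 0:
        return np.nan
    # LZ76 parsing: count phrases not seen in the prefix
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return float(c * math.log2(n) / n)


def _runs_of_true(mask: np.ndarray) -> np.ndarray:
    """Lengths of runs of True in a 1-D boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)


def _rqa_features(d: np.ndarray, eps_frac: float, lmin: int) -> dict[str, float]:
    n = d.shape[0]
    out = {k: np.nan for k in ("rqa_rr", "rqa_det", "rqa_lmean", "rqa_lmax",
                               "rqa_div", "rqa_lentr", "rqa_lam", "rqa_tt",
                               "rqa_vmax", "rqa_det_rr")}
    if n < 10:
        return out
    dmax = d.max()
    eps = eps_frac * dmax if dmax > 0 else 0.0
    r = d <= eps
    n_off = n * n - n
    rec_points = int(r.sum()) - n  # exclude the line of identity
    rr = rec_points / n_off if n_off else np.nan
    out["rqa_rr"] = rr

    # diagonal lines (upper triangle, excluding the LOI), via a sheared
    # copy so all diagonals are scanned in one run-length pass
    i_idx = np.arange(n)[None, :]
    j_idx = i_idx + np.arange(1, n)[:, None]
    valid = j_idx < n
    sheared = np.zeros((n - 1, n + 1), dtype=bool)  # spare column separates rows
    sheared[:, :n][valid] = r[np.broadcast_to(i_idx, j_idx.shape)[valid], j_idx[valid]]
    dl = _runs_of_true(sheared.ravel())
    total_diag = dl.sum()
    long_d = dl[dl >= lmin]
    det = float(long_d.sum() / total_diag) if total_diag > 0 else 0.0
    out["rqa_det"] = det
    out["rqa_det_rr"] = det / rr if rr and rr > 0 else np.nan
    if len(long_d):
        out["rqa_lmean"] = float(long_d.mean())
        lmax = int(dl.max())
        out["rqa_lmax"] = float(lmax)
        out["rqa_div"] = 1.0 / lmax
        _, counts = np.unique(long_d, return_counts=True)
        p = counts / counts.sum()
        out["rqa_lentr"] = float(-np.sum(p * np.log(p)))
    else:
        out["rqa_lmean"] = 0.0
        out["rqa_lmax"] = 0.0
        out["rqa_lentr"] = 0.0

    # vertical lines (full columns); separator row keeps runs per-column
    flat = np.vstack([r, np.zeros((1, n), dtype=bool)]).flatten(order="F")
    vl = _runs_of_true(flat)
    total_vert = vl.sum()
    long_v = vl[vl >= lmin]
    out["rqa_lam"] = float(long_v.sum() / total_vert) if total_vert > 0 else 0.0
    out["rqa_tt"] = float(long_v.mean()) if len(long_v) else 0.0
    out["rqa_vmax"] = float(vl.max()) if len(vl) else 0.0
    return out


def nonlinear_features(x: np.ndarray, params: NLParams = NL_DEFAULTS) -> dict[str, float]:
    """42 non-linear descriptors of an imputed epoch vector (length >= 100)."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 100 or not np.all(np.isfinite(x)):
        return {n: np.nan for n in NL_NAMES}
    sd = x.std()
    r = params.r_factor * sd
    out: dict[str, float] = {}

    # shared pointwise and template distance matrices (delay 1)
    d1 = np.abs(x[:, None] - x[None, :])
    d_m = _cheb_from(d1, params.m_entropy)
    d_m1 = _cheb_from(d1, params.m_entropy + 1)
    d_embed = d_m1 if params.m_embed == params.m_entropy + 1 else _cheb_from(d1, params.m_embed)

    # --- entropy family
    out["apen"] = _approx_entropy(x, params.m_entropy, r, d_m, d_m1)
    out["sampen"] = _sample_entropy(x, params.m_entropy, r, d_m, d_m1)
    out["fuzzyen"] = _fuzzy_entropy(x, params.m_entropy, r, d_m, d_m1)
    out["perm3"] = _perm_entropy(x, 3)
    out["perm4"] = _perm_entropy(x, 4)
    out["perm5"] = _perm_entropy(x, 5)
    out["wperm3"] = _weighted_perm_entropy(x, 3)
    out["svd_en"] = _svd_entropy(x, 3)
    out["shannon_en"] = _shannon_entropy(x, params.hist_bins)
    out["renyi_en"] = _renyi_entropy(x, params.hist_bins)
    out["tsallis_en"] = _tsallis_entropy(x, params.hist_bins)
    out["mse2"] = _sample_entropy(_coarse_grain(x, 2), params.m_entropy, r)
    out["mse3"] = _sample_entropy(_coarse_grain(x, 3), params.m_entropy, r)
    out["dispen"] = _dispersion_entropy(x, params.disp_classes, params.disp_m)
    out["bubble_en"] = _bubble_entropy(x)
    out["incr_en"] = _increment_entropy(x)

    # --- fractal family
    out["dfa_alpha"] = _dfa(x)
    out["higuchi_fd"] = _higuchi_fd(x, params.higuchi_kmax)
    out["katz_fd"] = _katz_fd(x)
    out["petrosian_fd"] = _petrosian_fd(x)
    out["hurst"] = _hurst_rs(x)
    out["corr_dim"] = _corr_dim(d_embed)
    out["lyap_r"] = _lyap_rosenstein(d_embed)
    out["dma_alpha"] = _dma(x)

    # --- complexity family
    out["lzc"] = _lz_complexity(x)
    var = x.var()
    d1 = np.diff(x)
    var_d1 = d1.var()
    mob = math.sqrt(var_d1 / var) if var > 0 else 0.0
    mob_d1 = math.sqrt(np.diff(x, n=2).var() / var_d1) if var_d1 > 0 else 0.0
    out["hjorth_mobility"] = mob
    out["hjorth_complexity"] = mob_d1 / mob if mob > 0 else 0.0
    out["diff_zcr"] = (
        np.count_nonzero(np.signbit(d1[1:]) != np.signbit(d1[:-1])) / (len(d1) - 1)
        if len(d1) > 1
        else np.nan
    )
    codes4 = _ordinal_patterns(x, 4)
    out["forbidden_frac"] = 1.0 - len(np.unique(codes4)) / 24.0
    # Jensen-Shannon statistical complexity on the order-4 ordinal distribution
    n_pat = 24
    p_full = np.zeros(n_pat)
    pat_ids, counts = np.unique(codes4, return_counts=True)
    # map arbitrary codes onto a dense index
    p_full[: len(counts)] = counts / counts.sum()
    u = np.full(n_pat, 1.0 / n_pat)
    mix = 0.5 * (p_full + u)

    def _h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    js = _h(mix) - 0.5 * _h(p_full) - 0.5 * _h(u)
    q_max = -0.5 * (
        (n_pat + 1) / n_pat * math.log(n_pat + 1) - 2 * math.log(2 * n_pat) + math.log(n_pat)
    )
    h_norm = _h(p_full) / math.log(n_pat)
    out["stat_complexity"] = float(js / q_max * h_norm) if q_max != 0 else np.nan
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    total_p = spec.sum()
    if total_p > 0:
        out["c0_complexity"] = float(spec[spec <= spec.mean()].sum() / total_p)
    else:
        out["c0_complexity"] = 0.0
    out["fdispen"] = _fdispersion_entropy(x, params.disp_classes, params.disp_m)

    # --- RQA family
    out.update(_rqa_features(d_embed, params.rqa_eps_frac, params.rqa_lmin))
    return {k: out[k] for k in NL_NAMES}


# ---------------------------------------------------------------------------
# HRV battery (13)
# ---------------------------------------------------------------------------


def detect_beats(bvp: np.ndarray, fs: float = 64.0) -> np.ndarray:
    """Systolic-peak sample indices from a band-passed BVP epoch.

    Local-maximum search with a 0.25 s minimum peak distance (240 bpm bound)
    and an adaptive height threshold of 0.5x the rolling (5 s block) 75th
    percentile of the signal.
    """
    bvp = np.asarray(bvp, dtype=np.float64)
    if len(bvp) < fs or not np.all(np.isfinite(bvp)):
        return np.empty(0, dtype=int)
    block = max(1, int(5 * fs))
    n_blocks = len(bvp) // block
    p75 = np.percentile(bvp[: n_blocks * block].reshape(n_blocks, block), 75, axis=1)
    thresh = np.repeat(0.5 * p75, block)
    if len(thresh) < len(bvp):  # tail shorter than one block reuses the last value
        thresh = np.concatenate([thresh, np.full(len(bvp) - len(thresh), thresh[-1])])
    peaks, _ = sps.find_peaks(bvp, distance=max(1, int(0.25 * fs)))
    return peaks[bvp[peaks] > thresh[peaks]]


def hrv_from_ibi(nn_ms: np.ndarray) -> dict[str, float]:
    """The 13 HRV statistics from an inter-beat-interval series (ms)."""
    nn = np.asarray(nn_ms, dtype=np.float64)
    if len(nn) < 4:
        return {n: np.nan for n in HRV_NAMES}
    d = np.diff(nn)
    hr = 60000.0 / nn
    q75, q25 = np.percentile(nn, [75, 25])
    return {
        "meanNN": float(nn.mean()),
        "medianNN": float(np.median(nn)),
        "SDNN": float(nn.std(ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "SDSD": float(d.std(ddof=1)),
        "pNN20": float(100.0 * np.mean(np.abs(d) > 20.0)),
        "pNN50": float(100.0 * np.mean(np.abs(d) > 50.0)),
        "CVNN": float(nn.std(ddof=1) / nn.mean()),
        "meanHR": float(hr.mean()),
        "stdHR": float(hr.std(ddof=1)),
        "minNN": float(nn.min()),
        "maxNN": float(nn.max()),
        "IQRNN": float(q75 - q25),
    }


def hrv_features(bvp: np.ndarray, fs: float = 64.0) -> dict[str, float]:
    """13 HRV features from a filtered BVP epoch (needs >= 5 beats)."""
    peaks = detect_beats(bvp, fs)
    if len(peaks) < 5:
        return {n: np.nan for n in HRV_NAMES}
    nn = np.diff(peaks) / fs * 1000.0
    return hrv_from_ibi(nn)


# ---------------------------------------------------------------------------
# EDA battery (42)
# ---------------------------------------------------------------------------

_EDA_TONIC_CUTOFF = 0.05  # Hz


def eda_decompose(eda: np.ndarray, fs: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Split EDA into tonic (low-pass 0.05 Hz, zero-phase) + phasic residual.

    Reconstruction is exact by construction: tonic + phasic == input.
    """
    eda = np.asarray(eda, dtype=np.float64)
    sos = sps.butter(4, _EDA_TONIC_CUTOFF, btype="lowpass", fs=fs, output="sos")
    pad = 3 * (2 * sos.shape[0] + 1)
    if len(eda) <= pad:
        tonic = np.full_like(eda, eda.mean()) if len(eda) else eda.copy()
    else:
        tonic = sps.sosfiltfilt(sos, eda)
    return tonic, eda - tonic


def _component_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 4:
        return {k: np.nan for k in EDA_STAT_NAMES}
    t = np.arange(n) / fs
    d1 = np.diff(x)
    mean = x.mean()
    std = x.std()
    q75, q25 = np.percentile(x, [75, 25])
    skew, kurt = _moment_skew_kurt(x, mean, std * std)
    t_mean = t.mean()
    slope = float(np.mean((x - mean) * (t - t_mean)) / t.var()) if n > 1 else np.nan
    return {
        "mean": mean,
        "std": std,
        "min": x.min(),
        "max": x.max(),
        "range": x.max() - x.min(),
        "median": float(np.median(x)),
        "iqr": q75 - q25,
        "skewness": float(skew) if np.isfinite(skew) else 0.0,
        "kurtosis": float(kurt) if np.isfinite(kurt) else 0.0,
        "rms": float(np.sqrt(np.mean(x * x))),
        "energy": float(np.sum(x * x)),
        "auc": float(np.trapezoid(np.abs(x), t)),
        "slope": slope,
        "diff1_meanabs": float(np.mean(np.abs(d1))),
        "diff1_std": float(d1.std()),
        "line_length": float(np.sum(np.abs(d1))),
        "cv": std / mean if mean != 0 else np.nan,
    }


@dataclass
class SCREvent:
    peak_idx: int
    amplitude: float
    rise_time_s: float
    half_recovery_s: float


def detect_scr(
    phasic: np.ndarray,
    fs: float = 4.0,
    min_amplitude: float = 0.01,
    recovery_cap_s: float = 10.0,
) -> list[SCREvent]:
    """Skin-conductance responses: peaks >= ``min_amplitude`` above the
    preceding trough; half-recovery time capped at ``recovery_cap_s``."""
    phasic = np.asarray(phasic, dtype=np.float64)
    peaks, _ = sps.find_peaks(phasic)
    troughs, _ = sps.find_peaks(-phasic)
    if len(peaks) == 0:
        return []
    # preceding trough per peak (vectorised); peaks before the first trough
    # fall back to the running minimum up to the peak
    pos = np.searchsorted(troughs, peaks) - 1
    t_idx = np.where(pos >= 0, troughs[np.maximum(pos, 0)], 0)
    for w in np.flatnonzero(pos < 0):
        t_idx[w] = int(np.argmin(phasic[: peaks[w] + 1]))
    amps = phasic[peaks] - phasic[t_idx]
    keep = amps >= min_amplitude
    events: list[SCREvent] = []
    for pk, ti, amp in zip(peaks[keep], t_idx[keep], amps[keep]):
        half_level = phasic[pk] - amp / 2.0
        below = np.flatnonzero(phasic[pk:] <= half_level)
        half_rec = below[0] / fs if len(below) else recovery_cap_s
        events.append(
            SCREvent(
                peak_idx=int(pk),
                amplitude=float(amp),
                rise_time_s=float((pk - ti) / fs),
                half_recovery_s=float(min(half_rec, recovery_cap_s)),
            )
        )
    return events


def eda_features(
    tonic: np.ndarray, phasic: np.ndarray, fs: float = 4.0
) -> dict[str, float]:
    """42 EDA features: 17 stats per component + 8 phasic event features."""
    out = {f"EDA_tonic_{k}": v for k, v in _component_stats(tonic, fs).items()}
    out.update({f"EDA_phasic_{k}": v for k, v in _component_stats(phasic, fs).items()})
    events = detect_scr(phasic, fs)
    duration_min = len(phasic) / fs / 60.0
    n_ev = len(events)
    ev: dict[str, float] = {
        "scr_count": float(n_ev),
        "scr_rate_per_min": n_ev / duration_min if duration_min > 0 else np.nan,
    }
    if n_ev:
        amps = np.array([e.amplitude for e in events])
        ev["scr_amp_mean"] = float(amps.mean())
        ev["scr_amp_max"] = float(amps.max())
        ev["scr_amp_sum"] = float(amps.sum())
        ev["scr_rise_mean"] = float(np.mean([e.rise_time_s for e in events]))
        ev["scr_half_recovery_mean"] = float(np.mean([e.half_recovery_s for e in events]))
        if n_ev >= 2:
            ev["scr_interval_mean"] = float(
                np.mean(np.diff([e.peak_idx for e in events])) / fs
            )
        else:
            ev["scr_interval_mean"] = np.nan
    else:
        for k in EDA_EVENT_NAMES[2:]:
            ev[k] = np.nan
    out.update({f"EDA_phasic_{k}": v for k, v in ev.items()})
    return out


# ---------------------------------------------------------------------------
# Behavioral, circadian, demographic
# ---------------------------------------------------------------------------

BEHAVIOR_WINDOW_S = 7200.0


def behavioral_features(
    acc_history: np.ndarray,
    fs: float = 32.0,
    window_s: float = BEHAVIOR_WINDOW_S,
    min_available: float = 0.5,
) -> dict[str, float]:
    """Min/max/mean ACC magnitude over the trailing 2-h window.

    All three are missing when less than ``min_available`` of the window's
    expected samples are observed.
    """
    acc = np.asarray(acc_history, dtype=np.float64)
    finite = acc[np.isfinite(acc)]
    expected = window_s * fs
    if len(finite) < min_available * expected:
        return {n: np.nan for n in BEHAVIORAL_NAMES}
    return {
        "ACC_2h_min": float(finite.min()),
        "ACC_2h_max": float(finite.max()),
        "ACC_2h_mean": float(finite.mean()),
    }


def _behavioral_from_blocks(
    block_stats: pd.DataFrame, t: float, fs: float = 32.0
) -> dict[str, float]:
    """Behavioral features from precomputed per-5-min-block ACC statistics."""
    sel = block_stats[
        (block_stats["block_end"] > t - BEHAVIOR_WINDOW_S)
        & (block_stats["block_end"] <= t + 1e-9)
    ]
    total = sel["count"].sum()
    if total < 0.5 * BEHAVIOR_WINDOW_S * fs:
        return {n: np.nan for n in BEHAVIORAL_NAMES}
    return {
        "ACC_2h_min": float(sel["min"].min()),
        "ACC_2h_max": float(sel["max"].max()),
        "ACC_2h_mean": float(sel["sum"].sum() / total),
    }


def circadian_features(t: float, tz_offset_s: float = 0.0) -> dict[str, float]:
    """Minutes from (local) midnight and its sine/cosine encodings."""
    m = float(((t + tz_offset_s) % 86400.0) / 60.0)
    ang = 2 * np.pi * m / 1440.0
    return {
        "mins_midnight": m,
        "mins_midnight_sin": float(np.sin(ang)),
        "mins_midnight_cos": float(np.cos(ang)),
    }


def demographic_feature(sex: BiologicalSex | str) -> int:
    """Binary biological-sex encoding: male -> 1, female -> 0."""
    if isinstance(sex, str):
        try:
            sex = BiologicalSex(sex.strip().lower())
        except ValueError as exc:
            raise ValueError(f"unknown biological sex {sex!r}") from exc
    return 1 if sex is BiologicalSex.MALE else 0


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_STEMP_NL_DECIMATE = 4  # block-average factor before non-linear estimators


def _nl_input(x: np.ndarray, sig: str) -> np.ndarray:
    if sig == "sTemp" and len(x) >= _STEMP_NL_DECIMATE * 100:
        return _coarse_grain(np.asarray(x, dtype=np.float64), _STEMP_NL_DECIMATE)
    return x


def featurize_epoch(
    epoch: Epoch,
    sex: BiologicalSex,
    acc_block_stats: pd.DataFrame | None = None,
    tz_offset_s: float = 0.0,
    nl_params: NLParams = NL_DEFAULTS,
) -> dict[str, float]:
    """All 236 features for one imputed epoch, in manifest order."""
    row: dict[str, float] = {}
    for sig, (channel, fs) in DATA_DRIVEN_SIGNALS.items():
        x = epoch.channels.get(channel, np.empty(0))
        for k, v in time_domain_features(x).items():
            row[f"TD_{sig}_{k}"] = v
        for k, v in frequency_features(x, fs).items():
            row[f"FD_{sig}_{k}"] = v
        for k, v in nonlinear_features(_nl_input(x, sig), nl_params).items():
            row[f"NL_{sig}_{k}"] = v
    bvp = epoch.channels.get(Channel.BVP, np.empty(0))
    for k, v in hrv_features(bvp).items():
        row[f"HRV_{k}"] = v
    eda = epoch.channels.get(Channel.EDA, np.empty(0))
    if len(eda) and np.all(np.isfinite(eda)):
        tonic, phasic = eda_decompose(eda)
        row.update(eda_features(tonic, phasic))
    else:
        for name in MANIFEST.loc[MANIFEST["category"] == "eda", "feature_name"]:
            row[name] = np.nan
    if acc_block_stats is not None:
        row.update(_behavioral_from_blocks(acc_block_stats, epoch.glucose_time))
    else:
        row.update(
            behavioral_features(epoch.channels.get(Channel.ACC_MAG, np.empty(0)))
        )
    row.update(circadian_features(epoch.glucose_time, tz_offset_s))
    row["BiologicalSex"] = float(demographic_feature(sex))
    return {name: row.get(name, np.nan) for name in FEATURE_NAMES}


def featurize_epochset(
    epoch_set: EpochSet,
    tz_offset_s: float = 0.0,
    nl_params: NLParams = NL_DEFAULTS,
) -> pd.DataFrame:
    """Feature table (epochs x 236 features + metadata) for one participant."""
    rows = np.empty((len(epoch_set.epochs), len(FEATURE_NAMES)), dtype=np.float64)
    meta = []
    for i, ep in enumerate(epoch_set.epochs):
        row = featurize_epoch(
            ep,
            epoch_set.biological_sex,
            epoch_set.acc_block_stats,
            tz_offset_s,
            nl_params,
        )
        rows[i] = [row[name] for name in FEATURE_NAMES]
        meta.append((ep.participant_id, ep.glucose_time, ep.glucose))
    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    meta_df = pd.DataFrame(meta, columns=["participant_id", "glucose_time", "glucose"])
    return pd.concat([meta_df, table], axis=1)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

_META = ["participant_id", "glucose_time", "glucose"]


def clean_features(
    table: pd.DataFrame,
    missing_threshold: float = 0.2,
    variance_threshold: float = 1e-5,
    overflow_policy: str = "drop_column",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the column and row cleaning rules; returns (table, removal log).

    Column rules, in order: >20% missing -> overflow (any non-finite) ->
    constant -> duplicate (keep earliest in manifest order) -> variance
    below 1e-5.  Row rules: any infinity, or >20% of the surviving feature
    cells missing.
    """
    feats = [c for c in table.columns if c not in _META]
    if not feats:
        raise ValueError("no feature columns to clean")
    log: list[tuple[str, str, str, str]] = []
    x = table[feats]

    missing_frac = x.isna().mean()
    drop = missing_frac[missing_frac > missing_threshold].index
    for c in drop:
        log.append(("column", c, "missing", f"{missing_frac[c]:.3f}"))
    x = x.drop(columns=drop)

    inf_mask = ~np.isfinite(x.to_numpy(dtype=np.float64, na_value=np.nan))
    inf_mask &= ~x.isna().to_numpy()
    if inf_mask.any():
        if overflow_policy == "drop_column":
            bad = x.columns[inf_mask.any(axis=0)]
            for c in bad:
                log.append(("column", c, "overflow", "non-finite values"))
            x = x.drop(columns=bad)
        else:  # drop-cell: turn isolated infinities into missing
            arr = x.to_numpy(dtype=np.float64, na_value=np.nan)
            arr[inf_mask] = np.nan
            x = pd.DataFrame(arr, columns=x.columns, index=x.index)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variances = x.var(ddof=0, skipna=True)
    constant = variances.index[(variances == 0) | x.notna().sum().le(1)]
    for c in constant:
        log.append(("column", c, "constant", ""))
    x = x.drop(columns=constant)

    dup_mask = x.T.duplicated(keep="first")
    dups = x.columns[dup_mask.to_numpy()]
    for c in dups:
        log.append(("column", c, "duplicate", ""))
    x = x.drop(columns=dups)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        variances = x.var(ddof=0, skipna=True)
    lowvar = variances.index[variances < variance_threshold]
    for c in lowvar:
        log.append(("column", c, "low_variance", f"{variances[c]:.2e}"))
    x = x.drop(columns=lowvar)

    if x.shape[1] == 0:
        raise ValueError("cleaning removed every feature column")

    arr = x.to_numpy(dtype=np.float64, na_value=np.nan)
    row_inf = np.isinf(arr).any(axis=1)
    row_missing = np.isnan(arr).mean(axis=1) > missing_threshold
    bad_rows = row_inf | row_missing
    for i in np.flatnonzero(bad_rows):
        reason = "infinite" if row_inf[i] else "missing"
        log.append(("row", str(table.index[i]), reason, ""))

    cleaned = pd.concat(
        [table.loc[~bad_rows, _META].reset_index(drop=True),
         x.loc[~bad_rows].reset_index(drop=True)],
        axis=1,
    )
    log_df = pd.DataFrame(log, columns=["kind", "name", "rule", "detail"])
    return cleaned, log_df
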