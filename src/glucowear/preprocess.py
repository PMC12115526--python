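"""Signal preprocessing: magnitude, filtering, plausibility, epochs, imputation.

The chain has four steps, run per participant:

1. preparation — derive the accelerometry vector magnitude from the three
   axes (missing in any axis makes the magnitude missing);
2. filtering + plausibility — zero-phase Butterworth filtering of BVP
   (band-pass 0.5-5 Hz), ACC magnitude (low-pass 10 Hz) and EDA (low-pass
   0.5 Hz), then masking of samples outside physiologically plausible
   ranges (HR and skin temperature are range-masked only, never filtered);
3. segmentation — one candidate epoch per CGM timestamp covering the
   5-minute window (t-300 s, t], each channel on a fixed nominal grid of
   fs x 300 slots; epochs with more than 50% missing in at least one
   channel are discarded (and counted);
4. imputation — remaining missing slots are filled epoch-wise with the
   mean when the observed distribution is approximately normal
   (|skewness| < 0.5, adjusted Fisher-Pearson estimator) and the median
   otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .dataio import (
    CGM_PERIOD_S,
    BiologicalSex,
    Channel,
    ParticipantRecord,
    SignalRecord,
)

EPOCH_S = 300.0

#: Inclusive physiological plausibility bounds per channel.
PLAUSIBILITY_RANGES: dict[Channel, tuple[float, float]] = {
    Channel.HR: (25.0, 240.0),  # bpm
    Channel.TEMP: (30.0, 40.0),  # deg C
    Channel.BVP: (-500.0, 500.0),  # a.u.
    Channel.EDA: (0.01, 100.0),  # microsiemens
    Channel.ACC_MAG: (0.0, 68.0),  # m/s^2
}

#: Channels that make up an epoch, with the expected per-epoch slot counts.
EPOCH_CHANNELS: dict[Channel, int] = {
    Channel.HR: 300,
    Channel.EDA: 1200,
    Channel.TEMP: 1200,
    Channel.BVP: 19200,
    Channel.ACC_MAG: 9600,
}

# Butterworth designs: (order, critical freq(s) Hz, type).  Only the BVP
# order is prescribed; the low-pass filters reuse it.
_FILTERS: dict[Channel, tuple[int, object, str]] = {
    Channel.BVP: (4, (0.5, 5.0), "bandpass"),
    Channel.ACC_MAG: (4, 10.0, "lowpass"),
    Channel.EDA: (4, 0.5, "lowpass"),
}


# ---------------------------------------------------------------------------
# Step 1: preparation
# ---------------------------------------------------------------------------


def acc_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise vector magnitude sqrt(x^2 + y^2 + z^2); NaN propagates."""
    x, y, z = (np.asarray(a, dtype=np.float64) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("axis vectors must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def acc_magnitude_record(record: ParticipantRecord) -> SignalRecord:
    """Build the ACC_MAG channel from the three axis records."""
    x = record.signals[Channel.ACC_X]
    y = record.signals[Channel.ACC_Y]
    z = record.signals[Channel.ACC_Z]
    mag = acc_magnitude(x.values, y.values, z.values)
    return SignalRecord(
        channel=Channel.ACC_MAG,
        fs=x.fs,
        values=mag,
        participant_id=record.participant_id,
        _timestamps=None if x.is_regular else x.timestamps.copy(),
        t0=x.t0,
    )


# ---------------------------------------------------------------------------
# Step 2: filtering + plausibility
# ---------------------------------------------------------------------------


def _sos(channel: Channel, fs: float) -> np.ndarray:
    order, freq, btype = _FILTERS[channel]
    return sps.butter(order, freq, btype=btype, fs=fs, output="sos")


def _padlen(sos: np.ndarray) -> int:
    return 3 * (2 * sos.shape[0] + 1)


def filter_channel(record: SignalRecord) -> SignalRecord:
    """Zero-phase Butterworth filtering of BVP / ACC_MAG / EDA.

    Filtering is applied independently to each contiguous non-missing
    segment; segments shorter than the filter warm-up are marked missing.
    HR and TEMP pass through unchanged.
    """
    if record.channel not in _FILTERS:
        return record
    sos = _sos(record.channel, record.fs)
    pad = _padlen(sos)
    vals = np.asarray(record.values, dtype=np.float64)
    out = np.full_like(vals, np.nan)
    finite = np.isfinite(vals)
    # contiguous runs of finite samples
    edges = np.flatnonzero(np.diff(finite.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(vals)]])
    for s, e in zip(starts, ends):
        if not finite[s]:
            continue
        if e - s <= pad:
            continue  # too short to filter: stays missing
        out[s:e] = sps.sosfiltfilt(sos, vals[s:e])
    filtered = record.copy()
    filtered.values = out
    return filtered


def apply_plausibility(
    record: SignalRecord,
    ranges: dict[Channel, tuple[float, float]] | None = None,
) -> SignalRecord:
    """Mask samples outside the inclusive physiological range as missing."""
    ranges = ranges or PLAUSIBILITY_RANGES
    if record.channel not in ranges:
        return record
    lo, hi = ranges[record.channel]
    vals = np.asarray(record.values, dtype=np.float64)
    out = np.where((vals >= lo) & (vals <= hi), vals, np.nan)
    masked = record.copy()
    masked.values = out
    return masked


# ---------------------------------------------------------------------------
# Step 3: segmentation into epochs
# ---------------------------------------------------------------------------


@dataclass
class Epoch:
    """One 5-minute multi-channel window preceding a CGM reading."""

    participant_id: str
    glucose_time: float
    glucose: float
    channels: dict[Channel, np.ndarray] = field(default_factory=dict)
    missing_fraction: dict[Channel, float] = field(default_factory=dict)

    def max_missing(self) -> float:
        return max(self.missing_fraction.values()) if self.missing_fraction else 0.0


@dataclass
class EpochSet:
    """Retained epochs for one participant plus discard accounting."""

    participant_id: str
    biological_sex: BiologicalSex
    epochs: list[Epoch] = field(default_factory=list)
    discarded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["participant_id", "glucose_time", "reason"]
        )
    )
    #: Per-5-min-block ACC magnitude stats (for the 2-h behavioral window):
    #: columns block_end, min, max, sum, count.
    acc_block_stats: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.epochs)


def _assign_slots(rel: np.ndarray, fs: float, n_slots: int) -> np.ndarray:
    """Slot index for samples at ``rel`` seconds into a right-closed window.

    Samples landing exactly on a slot boundary belong to the earlier slot,
    consistent with the (t-300, t] window convention, so a sample at the
    window's right edge fills the last slot.
    """
    slot = np.ceil(rel * fs - 1e-9).astype(np.int64) - 1
    return np.clip(slot, 0, n_slots - 1)


def _segment_general(
    ts: np.ndarray,
    vals: np.ndarray,
    fs: float,
    cgm_times: np.ndarray,
    n_slots: int,
    max_clock_skew: float,
) -> np.ndarray:
    """(n_epochs, n_slots) grid for an arbitrary timestamped channel."""
    out = np.full((len(cgm_times), n_slots), np.nan)
    for k, t in enumerate(cgm_times):
        lo = np.searchsorted(ts, t - EPOCH_S - max_clock_skew, side="right")
        hi = np.searchsorted(ts, t + max_clock_skew, side="right")
        if hi <= lo:
            continue
        sub_ts = np.clip(ts[lo:hi], t - EPOCH_S, t)
        sub_v = vals[lo:hi]
        ok = np.isfinite(sub_v)
        if not ok.any():
            continue
        slots = _assign_slots(sub_ts[ok] - (t - EPOCH_S), fs, n_slots)
        sums = np.zeros(n_slots)
        counts = np.zeros(n_slots)
        np.add.at(sums, slots, sub_v[ok])
        np.add.at(counts, slots, 1.0)
        row = np.full(n_slots, np.nan)
        nz = counts > 0
        row[nz] = sums[nz] / counts[nz]
        out[k] = row
    return out


def _segment_regular(
    record: SignalRecord, cgm_times: np.ndarray, n_slots: int
) -> np.ndarray | None:
    """Fast path: channel on an exact uniform grid aligned with uniform CGM."""
    if not record.is_regular or len(cgm_times) == 0:
        return None
    if len(cgm_times) > 1 and not np.allclose(np.diff(cgm_times), EPOCH_S):
        return None
    start_idx = (cgm_times[0] - EPOCH_S - record.t0) * record.fs
    if abs(start_idx - round(start_idx)) > 1e-6:
        return None
    # the window is (t-300, t]: the sample at exactly t-300 belongs to the
    # previous epoch, the one at exactly t to this epoch
    start_idx = int(round(start_idx)) + 1
    out = np.full((len(cgm_times), n_slots), np.nan)
    vals = np.asarray(record.values, dtype=np.float64)
    for k in range(len(cgm_times)):
        s = start_idx + k * n_slots
        e = s + n_slots
        s2, e2 = max(s, 0), min(e, len(vals))
        if s2 < e2:
            out[k, s2 - s : e2 - s] = vals[s2:e2]
    return out


def _acc_block_stats(record: SignalRecord, cgm_times: np.ndarray) -> pd.DataFrame:
    """Min/max/sum/count of the ACC magnitude per 5-min block ending on the
    CGM grid, reaching back far enough to cover every 2-h behavioral window."""
    ts = None if record.is_regular else record.timestamps
    vals = np.asarray(record.values, dtype=np.float64)
    if len(cgm_times) == 0:
        return pd.DataFrame(columns=["block_end", "min", "max", "sum", "count"])
    t_first = cgm_times[0]
    start_ref = record.start_time
    n_back = int(np.ceil(max(0.0, (t_first - start_ref)) / EPOCH_S)) + 1
    block_ends = np.concatenate(
        [t_first - EPOCH_S * np.arange(n_back, 0, -1), cgm_times]
    )
    block_ends = np.unique(block_ends)
    rows = []
    fs = record.fs
    for be in block_ends:
        if record.is_regular:
            lo = int(np.floor((be - EPOCH_S - record.t0) * fs + 1e-9)) + 1
            hi = int(np.floor((be - record.t0) * fs + 1e-9)) + 1
            lo, hi = max(lo, 0), min(hi, len(vals))
            seg = vals[lo:hi] if hi > lo else np.empty(0)
        else:
            lo = np.searchsorted(ts, be - EPOCH_S, side="right")
            hi = np.searchsorted(ts, be, side="right")
            seg = vals[lo:hi]
        seg = seg[np.isfinite(seg)]
        if len(seg):
            rows.append((be, seg.min(), seg.max(), seg.sum(), len(seg)))
        else:
            rows.append((be, np.nan, np.nan, 0.0, 0))
    return pd.DataFrame(rows, columns=["block_end", "min", "max", "sum", "count"])


def segment_epochs(
    participant: ParticipantRecord,
    max_clock_skew: float = 0.0,
    discard_threshold: float = 0.5,
) -> EpochSet:
    """Segment preprocessed channels into per-CGM-reading epochs.

    One candidate epoch is created per glucose timestamp; each channel is
    resampled onto its nominal grid of fs x 300 slots within (t-300 s, t]
    (multiple samples per slot are averaged, empty slots are missing).
    Epochs with more than ``discard_threshold`` missing in at least one
    channel are dropped and counted.  Exactly-at-threshold epochs are kept.
    """
    cgm = participant.cgm
    pid = participant.participant_id
    out = EpochSet(pid, participant.biological_sex)
    if cgm is None or len(cgm) == 0:
        warnings.warn(f"{pid}: no CGM rows; empty epoch set")
        return out
    cgm_times = cgm.timestamps

    grids: dict[Channel, np.ndarray] = {}
    for channel, n_slots in EPOCH_CHANNELS.items():
        if channel not in participant.signals:
            continue
        rec = participant.signals[channel]
        grid = _segment_regular(rec, cgm_times, n_slots)
        if grid is None:
            grid = _segment_general(
                rec.timestamps,
                np.asarray(rec.values, dtype=np.float64),
                rec.fs,
                cgm_times,
                n_slots,
                max_clock_skew,
            )
        grids[channel] = grid

    if Channel.ACC_MAG in participant.signals:
        out.acc_block_stats = _acc_block_stats(
            participant.signals[Channel.ACC_MAG], cgm_times
        )

    miss = {ch: np.isnan(g).mean(axis=1) for ch, g in grids.items()}
    discard_rows = []
    for k, t in enumerate(cgm_times):
        frac = {ch: float(m[k]) for ch, m in miss.items()}
        bad = [ch.value for ch, f in frac.items() if f > discard_threshold]
        if bad:
            discard_rows.append((pid, t, "missing>50%:" + ",".join(sorted(bad))))
            continue
        out.epochs.append(
            Epoch(
                participant_id=pid,
                glucose_time=float(t),
                glucose=float(cgm.glucose[k]),
                channels={ch: g[k] for ch, g in grids.items()},
                missing_fraction=frac,
            )
        )
    out.discarded = pd.DataFrame(
        discard_rows, columns=["participant_id", "glucose_time", "reason"]
    )
    return out


# ---------------------------------------------------------------------------
# Step 4: skewness-gated imputation
# ---------------------------------------------------------------------------


def epoch_skewness(observed: np.ndarray) -> float:
    """Adjusted (bias-corrected) Fisher-Pearson skewness; 0 for degenerate."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = stats.skew(observed, bias=False)
    return float(g) if np.isfinite(g) else 0.0


def impute_epoch(values: np.ndarray, skew_gate: float = 0.5) -> np.ndarray:
    """Fill missing slots with the mean (|skew| < gate) or median.

    Observed samples are never altered.  Requires at least 3 observed values.
    """
    values = np.asarray(values, dtype=np.float64)
    missing = np.isnan(values)
    if not missing.any():
        return values.copy()
    observed = values[~missing]
    if len(observed) < 3:
        raise ValueError("impute_epoch requires >= 3 observed values")
    fill = (
        float(np.mean(observed))
        if abs(epoch_skewness(observed)) < skew_gate
        else float(np.median(observed))
    )
    out = values.copy()
    out[missing] = fill
    return out


def impute_epochs(epoch_set: EpochSet) -> EpochSet:
    """Apply epoch-wise imputation to every retained epoch, in place."""
    for ep in epoch_set.epochs:
        for ch, vec in ep.channels.items():
            if ep.missing_fraction[ch] > 0:
                ep.channels[ch] = impute_epoch(vec)
                ep.missing_fraction[ch] = 0.0
    return epoch_set


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def preprocess_participant(
    record: ParticipantRecord,
    ranges: dict[Channel, tuple[float, float]] | None = None,
    max_clock_skew: float = 0.0,
) -> EpochSet:
    """Run the full preparation -> filter -> mask -> segment -> impute chain."""
    working = dict(record.signals)
    if Channel.ACC_MAG not in working and Channel.ACC_X in working:
        working[Channel.ACC_MAG] = acc_magnitude_record(record)
    processed: dict[Channel, SignalRecord] = {}
    for channel in EPOCH_CHANNELS:
        if channel not in working:
            continue
        rec = filter_channel(working[channel])
        processed[channel] = apply_plausibility(rec, ranges)
    prepared = ParticipantRecord(
        record.participant_id, record.biological_sex, processed, record.cgm
    )
    return impute_epochs(segment_epochs(prepared, max_clock_skew=max_clock_skew))
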