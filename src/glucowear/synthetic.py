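"""Synthetic wearable cohort generator with a known glucose-generating model.

Emulates the sampling structure of a wrist-wearable + CGM study: five sensor
channels (BVP 64 Hz as a pulse train, EDA 4 Hz tonic drift + phasic SCRs,
skin temperature 4 Hz, tri-axial accelerometry 32 Hz with activity bouts,
heart rate 1 Hz) over multi-day recordings, and a CGM glucose series every
5 minutes driven by an explicit additive model:

    glucose(t) = beta0 + beta_sex * 1[male]
               + circ_amp * sin(2*pi*(m(t) - circ_phase)/1440)
               + sum_meals meal_amp * exp(-dt/meal_decay) * 1[dt >= 0]
               + beta_act * (mean ACC magnitude over preceding 2 h, normalised
                             by the cohort-level 95th percentile of 2-h means)
               + AR(1) noise

where m(t) is minutes from midnight.  Every latent component is stored in a
:class:`GroundTruth` object so downstream signal-recovery is testable: the
emitted glucose is the exact sum of the stored components.

The functional forms and default coefficients are calibrated so the cohort
summary is plausible for a normoglycemic/prediabetic group (mean glucose
around 115 mg/dL, nearly all readings in the 70-180 mg/dL range); they are
configuration, not physiological truth claims.

A single global seed fans out into per-participant, per-channel substreams,
so the cohort is bit-reproducible and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .dataio import (
    CGM_PERIOD_S,
    BiologicalSex,
    Channel,
    GlucoseSeries,
    ParticipantRecord,
    SignalRecord,
)

#: Default simulation start: 2021-01-01 00:00:00 UTC.
DEFAULT_START = 1609459200.0

# Substream labels (third word of each SeedSequence key).
_STREAM_ACT, _STREAM_HR, _STREAM_BVP, _STREAM_EDA, _STREAM_TEMP = 0, 1, 2, 3, 4
_STREAM_NOISE, _STREAM_MEALS = 5, 6
_STREAM_MISS = 100  # + channel code


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Cohort simulation parameters (defaults define the study conditions)."""

    n_participants: int = 8
    days: float = 9.0  # recording span per participant (study span 8-10 days)
    seed: int = 0
    beta0: float = 110.0  # baseline glucose, mg/dL
    beta_sex: float = 8.0  # additive male offset, mg/dL
    circ_amp: float = 10.0  # circadian amplitude, mg/dL
    circ_phase: float = 0.0  # circadian phase, minutes from midnight
    meal_amp: float = 40.0  # excursion peak, mg/dL
    meal_decay: float = 60.0  # excursion decay constant, minutes
    meals_per_day: int = 3  # jittered around 08:00, 13:00, 19:00
    meal_jitter_sd: float = 30.0  # per-meal per-day timing jitter SD, minutes
    beta_act: float = -15.0  # mg/dL per unit normalised 2-h mean ACC
    ar_rho: float = 0.9  # AR(1) coefficient of the noise term
    ar_sigma: float = 5.0  # AR(1) innovation SD, mg/dL
    missing_frac: float = 0.05  # per-channel dropout prob per 5-min block
    start_time: float = DEFAULT_START

    def __post_init__(self) -> None:
        if not 0 <= self.ar_rho < 1:
            raise SimConfigError("ar_rho must be in [0, 1)")
        if not 0 <= self.missing_frac <= 1:
            raise SimConfigError("missing_frac must be in [0, 1]")
        if not 1 <= self.days <= 30:
            raise SimConfigError("days must be in [1, 30]")
        if self.n_participants < 1:
            raise SimConfigError("n_participants must be >= 1")
        if self.ar_sigma < 0 or self.meal_decay <= 0:
            raise SimConfigError("ar_sigma >= 0 and meal_decay > 0 required")

    @property
    def duration_s(self) -> float:
        return self.days * 86400.0

    @property
    def n_cgm(self) -> int:
        return int(round(self.days * 86400.0 / CGM_PERIOD_S))


@dataclass
class GroundTruth:
    """True parameters and latent glucose components per participant.

    ``components[pid]`` is a DataFrame with one row per CGM timestamp and
    columns ``baseline, sex_offset, circadian, meal, activity, noise,
    glucose`` where glucose is the exact (bitwise) sum of the other columns.
    """

    config: SimConfig
    params: dict[str, dict] = field(default_factory=dict)
    components: dict[str, pd.DataFrame] = field(default_factory=dict)
    acc_norm_q95: float = float("nan")


def _rng(config: SimConfig, participant: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(participant), int(stream)])
    )


def participant_id(index: int) -> str:
    return f"S{index + 1:02d}"


def participant_index(pid: str) -> int:
    return int(pid.lstrip("S")) - 1


def _sex(index: int) -> BiologicalSex:
    # Alternate so every cohort contains both sexes.
    return BiologicalSex.MALE if index % 2 == 0 else BiologicalSex.FEMALE


# ---------------------------------------------------------------------------
# Channel generators (all at their native rates, values float32)
# ---------------------------------------------------------------------------


def _activity_profile(config: SimConfig, idx: int) -> np.ndarray:
    """Latent activity envelope in [0, 1] at 1 Hz (shared by ACC and HR)."""
    rng = _rng(config, idx, _STREAM_ACT)
    n = int(round(config.duration_s))
    act = np.zeros(n, dtype=np.float64)
    n_days = int(np.ceil(config.days))
    for day in range(n_days):
        for _ in range(rng.integers(2, 5)):
            start_h = rng.uniform(8.0, 21.0)
            dur_s = rng.uniform(15 * 60, 45 * 60)
            s = int(day * 86400 + start_h * 3600)
            e = min(n, int(s + dur_s))
            if s < n:
                act[s:e] = np.maximum(act[s:e], rng.uniform(0.5, 1.0))
    # smooth the bout edges (2-min boxcar)
    return uniform_filter1d(act, size=120, mode="nearest")


def _gen_acc(
    config: SimConfig, idx: int, act_1hz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tri-axial accelerometry at 32 Hz: gravity + noise + oscillatory bouts."""
    rng = _rng(config, idx, _STREAM_ACT + 50)
    fs = 32
    n = int(round(config.duration_s * fs))
    act = np.repeat(act_1hz, fs)[:n]
    # static orientation unit vector, fixed per participant
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    t = np.arange(n, dtype=np.float64) / fs
    f_move = rng.uniform(1.5, 2.5)
    axes = []
    for ax in range(3):
        base = 9.81 * u[ax]
        osc_amp = rng.uniform(2.0, 4.0)
        phase = rng.uniform(0, 2 * np.pi)
        vals = (
            base
            + rng.standard_normal(n, dtype=np.float32) * 0.12
            + (act * osc_amp) * np.sin(2 * np.pi * f_move * t + phase)
            + rng.standard_normal(n, dtype=np.float32) * (0.8 * act)
        )
        axes.append(vals.astype(np.float32))
    return axes[0], axes[1], axes[2]


def _gen_hr_latent(config: SimConfig, idx: int, act_1hz: np.ndarray) -> np.ndarray:
    """Latent heart rate (bpm) at 1 Hz: rest 60-80, elevated during bouts."""
    rng = _rng(config, idx, _STREAM_HR)
    n = len(act_1hz)
    rest = rng.uniform(60.0, 80.0)
    slow = uniform_filter1d(rng.standard_normal(n) * 30.0, size=1800, mode="nearest")
    hr = rest + slow + 40.0 * act_1hz
    return np.clip(hr, 45.0, 185.0)


def _gen_hr_channel(config: SimConfig, idx: int, hr_latent: np.ndarray) -> np.ndarray:
    rng = _rng(config, idx, _STREAM_HR + 50)
    return (hr_latent + rng.standard_normal(len(hr_latent)) * 2.0).astype(np.float32)


def _gen_bvp(config: SimConfig, idx: int, hr_latent: np.ndarray) -> np.ndarray:
    """BVP at 64 Hz: stereotyped beat waveform phase-warped to the latent HR."""
    rng = _rng(config, idx, _STREAM_BVP)
    fs = 64
    n = int(round(config.duration_s * fs))
    rate_hz = np.repeat(hr_latent / 60.0, fs)[:n]
    phase = np.cumsum(rate_hz) / fs  # beat phase; one cycle per beat
    wave = -np.sin(2 * np.pi * phase) + 0.25 * np.sin(4 * np.pi * phase + 0.8)
    bvp = 40.0 * wave + rng.standard_normal(n, dtype=np.float32) * 3.0
    return bvp.astype(np.float32)


_SCR_TAU_RISE, _SCR_TAU_DECAY = 0.7, 3.0  # seconds


def _scr_template(fs: float) -> np.ndarray:
    t = np.arange(0, 15.0, 1 / fs)
    shape = np.exp(-t / _SCR_TAU_DECAY) - np.exp(-t / _SCR_TAU_RISE)
    return shape / shape.max()


def _gen_eda(config: SimConfig, idx: int) -> np.ndarray:
    """EDA at 4 Hz: bounded tonic random walk plus sparse phasic SCR bumps."""
    rng = _rng(config, idx, _STREAM_EDA)
    fs = 4
    n = int(round(config.duration_s * fs))
    tonic = rng.uniform(1.0, 8.0) + np.cumsum(rng.standard_normal(n) * 0.002)
    tonic = np.clip(tonic, 0.05, 20.0)
    eda = tonic + rng.standard_normal(n, dtype=np.float32) * 0.004
    template = _scr_template(fs)
    n_events = rng.poisson(4.0 * config.duration_s / 3600.0)  # ~4 SCRs/hour
    starts = np.sort(rng.integers(0, max(1, n - len(template)), size=n_events))
    amps = rng.uniform(0.05, 0.6, size=n_events)
    for s, a in zip(starts, amps):
        eda[s : s + len(template)] += a * template[: n - s]
    return np.clip(eda, 0.05, 20.0).astype(np.float32)


def _gen_temp(config: SimConfig, idx: int) -> np.ndarray:
    """Skin temperature at 4 Hz: 33.5 C + 0.5 C daily sinusoid + noise."""
    rng = _rng(config, idx, _STREAM_TEMP)
    fs = 4
    n = int(round(config.duration_s * fs))
    t = config.start_time + np.arange(n, dtype=np.float64) / fs
    phase = rng.uniform(0, 86400.0)
    temp = (
        33.5
        + 0.5 * np.sin(2 * np.pi * (t - phase) / 86400.0)
        + rng.standard_normal(n) * 0.05
    )
    return temp.astype(np.float32)


# ---------------------------------------------------------------------------
# Glucose model
# ---------------------------------------------------------------------------


def _acc_block_means(config: SimConfig, idx: int) -> np.ndarray:
    """Mean ACC magnitude per 5-min block (used for the activity term)."""
    act = _activity_profile(config, idx)
    x, y, z = _gen_acc(config, idx, act)
    mag = np.sqrt(
        x.astype(np.float64) ** 2 + y.astype(np.float64) ** 2 + z.astype(np.float64) ** 2
    )
    block = int(CGM_PERIOD_S * 32)
    n_blocks = len(mag) // block
    return mag[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)


def _two_hour_means(block_means: np.ndarray) -> np.ndarray:
    """Trailing 2-h (24-block) mean for each 5-min block end, partial at start."""
    csum = np.concatenate([[0.0], np.cumsum(block_means)])
    n = len(block_means)
    idx_hi = np.arange(1, n + 1)
    idx_lo = np.maximum(idx_hi - 24, 0)
    return (csum[idx_hi] - csum[idx_lo]) / (idx_hi - idx_lo)


def _meal_times(config: SimConfig, idx: int) -> np.ndarray:
    """Meal onset times (s since start), jittered per day per meal."""
    rng = _rng(config, idx, _STREAM_MEALS)
    base_hours = np.linspace(8.0, 19.0, max(1, config.meals_per_day))
    times = []
    for day in range(int(np.ceil(config.days))):
        jitter_min = rng.standard_normal(len(base_hours)) * config.meal_jitter_sd
        times.extend(day * 86400.0 + base_hours * 3600.0 + jitter_min * 60.0)
    times = np.sort(np.asarray(times))
    return times[(times >= 0) & (times < config.duration_s)]


def _glucose_components(
    config: SimConfig, idx: int, acc_2h_means: np.ndarray, acc_q95: float
) -> pd.DataFrame:
    n = config.n_cgm
    # CGM timestamps: the first reading falls one full epoch after start.
    ts = config.start_time + CGM_PERIOD_S * np.arange(1, n + 1)

    male = _sex(idx) is BiologicalSex.MALE
    baseline = np.full(n, config.beta0)
    sex_offset = np.full(n, config.beta_sex if male else 0.0)

    mins = (ts % 86400.0) / 60.0
    circadian = config.circ_amp * np.sin(2 * np.pi * (mins - config.circ_phase) / 1440.0)

    rel = ts - config.start_time
    meal = np.zeros(n)
    if config.meal_amp != 0:
        for tm in _meal_times(config, idx):
            dt_min = (rel - tm) / 60.0
            mask = dt_min >= 0
            meal[mask] += config.meal_amp * np.exp(-dt_min[mask] / config.meal_decay)

    if config.beta_act != 0:
        activity = config.beta_act * (acc_2h_means[:n] / acc_q95)
    else:
        activity = np.zeros(n)

    rng = _rng(config, idx, _STREAM_NOISE)
    noise = np.zeros(n)
    if config.ar_sigma > 0:
        eps = rng.standard_normal(n) * config.ar_sigma
        noise[0] = eps[0] / np.sqrt(1 - config.ar_rho**2)
        for k in range(1, n):
            noise[k] = config.ar_rho * noise[k - 1] + eps[k]

    glucose = baseline + sex_offset + circadian + meal + activity + noise
    return pd.DataFrame(
        {
            "timestamp": ts,
            "baseline": baseline,
            "sex_offset": sex_offset,
            "circadian": circadian,
            "meal": meal,
            "activity": activity,
            "noise": noise,
            "glucose": glucose,
        }
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _cohort_acc_q95(config: SimConfig) -> tuple[float, list[np.ndarray]]:
    """First pass: per-participant 2-h ACC means and their cohort 95th pct."""
    all_2h = []
    for idx in range(config.n_participants):
        all_2h.append(_two_hour_means(_acc_block_means(config, idx)))
    q95 = float(np.percentile(np.concatenate(all_2h), 95))
    return q95, all_2h


def simulate_participant(
    config: SimConfig, idx: int, acc_2h_means: np.ndarray, acc_q95: float
) -> tuple[ParticipantRecord, pd.DataFrame]:
    """Generate one participant's full record plus their latent components."""
    pid = participant_id(idx)
    t0 = config.start_time
    act = _activity_profile(config, idx)
    x, y, z = _gen_acc(config, idx, act)
    hr_lat = _gen_hr_latent(config, idx, act)

    def reg(channel: Channel, values: np.ndarray, fs: float) -> SignalRecord:
        return SignalRecord(channel=channel, fs=fs, values=values, participant_id=pid, t0=t0)

    signals = {
        Channel.ACC_X: reg(Channel.ACC_X, x, 32),
        Channel.ACC_Y: reg(Channel.ACC_Y, y, 32),
        Channel.ACC_Z: reg(Channel.ACC_Z, z, 32),
        Channel.HR: reg(Channel.HR, _gen_hr_channel(config, idx, hr_lat), 1),
        Channel.BVP: reg(Channel.BVP, _gen_bvp(config, idx, hr_lat), 64),
        Channel.EDA: reg(Channel.EDA, _gen_eda(config, idx), 4),
        Channel.TEMP: reg(Channel.TEMP, _gen_temp(config, idx), 4),
    }
    comp = _glucose_components(config, idx, acc_2h_means, acc_q95)
    cgm = GlucoseSeries(comp["timestamp"].to_numpy(), comp["glucose"].to_numpy(), pid)
    return ParticipantRecord(pid, _sex(idx), signals, cgm), comp


def iter_cohort(
    config: SimConfig,
) -> Iterator[tuple[ParticipantRecord, pd.DataFrame]]:
    """Yield participants one at a time (memory-friendly for long cohorts)."""
    q95, all_2h = _cohort_acc_q95(config)
    for idx in range(config.n_participants):
        yield simulate_participant(config, idx, all_2h[idx], q95)


def simulate_cohort(config: SimConfig) -> tuple[list[ParticipantRecord], GroundTruth]:
    """Generate the whole cohort.  Identical seed => bit-identical output.

    Missingness is *not* applied here; use :func:`inject_missingness`.
    """
    q95, all_2h = _cohort_acc_q95(config)
    truth = GroundTruth(config=config, acc_norm_q95=q95)
    records = []
    for idx in range(config.n_participants):
        rec, comp = simulate_participant(config, idx, all_2h[idx], q95)
        records.append(rec)
        truth.components[rec.participant_id] = comp
        truth.params[rec.participant_id] = {
            "biological_sex": rec.biological_sex.value,
            "beta0": config.beta0,
            "beta_sex": config.beta_sex if _sex(idx) is BiologicalSex.MALE else 0.0,
            "circ_amp": config.circ_amp,
            "circ_phase": config.circ_phase,
            "meal_amp": config.meal_amp,
            "meal_decay": config.meal_decay,
            "beta_act": config.beta_act,
            "ar_rho": config.ar_rho,
            "ar_sigma": config.ar_sigma,
        }
    return records, truth


# ---------------------------------------------------------------------------
# Missingness injection (emulates free-living non-wear)
# ---------------------------------------------------------------------------

#: Channels that drop out jointly (one device stream each).
_MISS_GROUPS: dict[int, tuple[Channel, ...]] = {
    0: (Channel.BVP,),
    1: (Channel.EDA,),
    2: (Channel.TEMP,),
    3: (Channel.HR,),
    4: (Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z),
}


def inject_missingness(record: ParticipantRecord, config: SimConfig) -> ParticipantRecord:
    """Blank whole 5-min blocks per channel with probability ``missing_frac``.

    The CGM series and ground truth are untouched; dropped samples become NaN
    (timestamps remain).  Returns the same record, modified in place.
    """
    if config.missing_frac == 0:
        return record
    idx = participant_index(record.participant_id)
    for code, group in _MISS_GROUPS.items():
        present = [ch for ch in group if ch in record.signals]
        if not present:
            continue
        rng = _rng(config, idx, _STREAM_MISS + code)
        n = len(record.signals[present[0]])
        fs = record.signals[present[0]].fs
        block = int(CGM_PERIOD_S * fs)
        n_blocks = int(np.ceil(n / block))
        drop = rng.random(n_blocks) < config.missing_frac
        mask = np.repeat(drop, block)[:n]
        for ch in present:
            vals = record.signals[ch].values
            if not np.issubdtype(vals.dtype, np.floating):
                vals = vals.astype(np.float64)
                record.signals[ch].values = vals
            vals[mask] = np.nan
    return record
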