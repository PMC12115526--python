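"""Domain containers and on-disk formats for the wearable glucose pipeline.

The pipeline works with five wrist-worn sensor channels (BVP 64 Hz, EDA 4 Hz,
skin temperature 4 Hz, tri-axial accelerometry 32 Hz, derived heart rate 1 Hz)
plus a CGM glucose series on a nominal 5-minute grid.  Raw inputs are plain
CSV (one file per channel per participant); feature tables and reports round
trip through CSV/Parquet/JSON.

Timestamps are float seconds since the Unix epoch internally.  Input CSVs may
carry either numeric Unix seconds or ISO-8601 strings.  The missing-value
marker in CSVs is the empty field.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class Channel(str, enum.Enum):
    """Sensor channel identifiers with their nominal sampling rates."""

    BVP = "BVP"
    EDA = "EDA"
    TEMP = "TEMP"
    ACC_X = "ACC_X"
    ACC_Y = "ACC_Y"
    ACC_Z = "ACC_Z"
    ACC_MAG = "ACC_MAG"
    HR = "HR"


#: Nominal sampling rate (Hz) per channel.
CHANNEL_FS: dict[Channel, float] = {
    Channel.BVP: 64.0,
    Channel.EDA: 4.0,
    Channel.TEMP: 4.0,
    Channel.ACC_X: 32.0,
    Channel.ACC_Y: 32.0,
    Channel.ACC_Z: 32.0,
    Channel.ACC_MAG: 32.0,
    Channel.HR: 1.0,
}

#: Channels stored on disk for a raw participant (magnitude is derived later).
RAW_CHANNEL_FILES: dict[Channel, str] = {
    Channel.BVP: "bvp.csv",
    Channel.EDA: "eda.csv",
    Channel.TEMP: "temp.csv",
    Channel.HR: "hr.csv",
}
ACC_FILE = "acc.csv"
CGM_FILE = "cgm.csv"

#: CGM nominal cadence in seconds.
CGM_PERIOD_S = 300.0


class DataFormatError(ValueError):
    """Raised when an on-disk file violates the expected schema."""


class EmptyRecordError(DataFormatError):
    """Raised when a file yields zero valid rows after cleaning."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class SignalRecord:
    """One channel's timestamped samples.

    ``values`` may contain NaN (missing samples whose timestamps are known).
    For memory efficiency a record can be *regular*: timestamps are then an
    implicit uniform grid ``t0 + k / fs`` and are materialised on demand.
    """

    channel: Channel
    fs: float
    values: np.ndarray
    participant_id: str = ""
    _timestamps: np.ndarray | None = None
    t0: float | None = None  # start of the implicit regular grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self._timestamps is not None:
            self._timestamps = np.asarray(self._timestamps, dtype=np.float64)
            if len(self._timestamps) != len(self.values):
                raise ValueError(
                    f"{self.channel}: timestamps ({len(self._timestamps)}) and "
                    f"values ({len(self.values)}) length mismatch"
                )
        elif self.t0 is None:
            raise ValueError("either timestamps or t0 (regular grid) required")

    @property
    def is_regular(self) -> bool:
        return self._timestamps is None

    @property
    def timestamps(self) -> np.ndarray:
        if self._timestamps is None:
            return self.t0 + np.arange(len(self.values), dtype=np.float64) / self.fs
        return self._timestamps

    @property
    def start_time(self) -> float:
        return float(self.t0) if self.is_regular else float(self._timestamps[0])

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "SignalRecord":
        return SignalRecord(
            channel=self.channel,
            fs=self.fs,
            values=self.values.copy(),
            participant_id=self.participant_id,
            _timestamps=None if self._timestamps is None else self._timestamps.copy(),
            t0=self.t0,
        )


@dataclass
class GlucoseSeries:
    """CGM readings (mg/dL) on a nominal 5-minute grid; gaps allowed."""

    timestamps: np.ndarray
    glucose: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.glucose = np.asarray(self.glucose, dtype=np.float64)
        if len(self.timestamps) != len(self.glucose):
            raise ValueError("timestamps and glucose length mismatch")
        if len(self.glucose) and np.nanmin(self.glucose) <= 0:
            raise ValueError("glucose values must be positive")

    def __len__(self) -> int:
        return len(self.glucose)


class BiologicalSex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass
class ParticipantRecord:
    """All channels plus the CGM series for one participant."""

    participant_id: str
    biological_sex: BiologicalSex
    signals: dict[Channel, SignalRecord] = field(default_factory=dict)
    cgm: GlucoseSeries | None = None

    def __post_init__(self) -> None:
        for rec in self.signals.values():
            if rec.participant_id and rec.participant_id != self.participant_id:
                raise ValueError("signal participant_id mismatch")
        if self.cgm is not None and self.cgm.participant_id:
            if self.cgm.participant_id != self.participant_id:
                raise ValueError("cgm participant_id mismatch")


# ---------------------------------------------------------------------------
# Timestamp parsing
# ---------------------------------------------------------------------------


def _parse_timestamps(col: pd.Series) -> np.ndarray:
    """Parse a timestamp column accepting Unix seconds or ISO-8601 strings.

    Unparseable entries become NaN.
    """
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().any() or col.isna().all():
        return numeric.to_numpy(dtype=np.float64)
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    out = np.full(len(col), np.nan)
    mask = parsed.notna().to_numpy()
    if mask.any():
        out[mask] = parsed[mask].astype("int64").to_numpy(np.float64) / 1e9
    return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_signal(path: str | os.PathLike, channel: Channel, fs: float | None = None) -> SignalRecord:
    """Load one channel CSV into a :class:`SignalRecord`.

    Cleaning applied on load: rows with missing/unparseable timestamps are
    dropped; for duplicate timestamps only the first occurrence is retained;
    rows are sorted ascending by timestamp (stable, so equal-timestamp
    survivors keep file order).

    For tri-axial accelerometry files (``timestamp,x,y,z``) pass one of the
    axis channels; the requested axis column is extracted.
    """
    if fs is None:
        fs = CHANNEL_FS[channel]
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read signal file {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise EmptyRecordError(f"{path}: no data") from exc
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected >=2 columns, got {df.shape[1]}")

    ts = _parse_timestamps(df.iloc[:, 0])
    if channel in (Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z) and df.shape[1] >= 4:
        axis_col = {"ACC_X": 1, "ACC_Y": 2, "ACC_Z": 3}[channel.value]
        vals = pd.to_numeric(df.iloc[:, axis_col], errors="coerce").to_numpy(np.float64)
    else:
        vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(np.float64)

    ok = np.isfinite(ts)
    ts, vals = ts[ok], vals[ok]
    if len(ts) == 0:
        raise EmptyRecordError(f"{path}: zero valid rows after timestamp cleaning")

    order = np.argsort(ts, kind="stable")
    ts, vals = ts[order], vals[order]
    keep = np.ones(len(ts), dtype=bool)
    keep[1:] = ts[1:] != ts[:-1]  # first occurrence wins (stable sort)
    return SignalRecord(channel=channel, fs=fs, values=vals[keep], _timestamps=ts[keep])


def load_glucose(path: str | os.PathLike, participant_id: str = "") -> GlucoseSeries:
    """Load a CGM CSV (``timestamp,glucose_mgdl``) with the same cleaning."""
    rec = load_signal(path, Channel.HR, fs=1 / CGM_PERIOD_S)  # reuse CSV cleaning
    ok = np.isfinite(rec.values) & (rec.values > 0)
    if not ok.any():
        raise EmptyRecordError(f"{path}: no positive glucose rows")
    return GlucoseSeries(rec.timestamps[ok], rec.values[ok], participant_id)


def load_demographics(path: str | os.PathLike) -> pd.DataFrame:
    """Load the demographics table (``participant_id,biological_sex``)."""
    df = pd.read_csv(path, dtype=str)
    required = {"participant_id", "biological_sex"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"{path}: demographics needs columns {sorted(required)}")
    return df


def load_participant(
    directory: str | os.PathLike,
    demographics: pd.DataFrame,
    strict: bool = True,
) -> ParticipantRecord:
    """Load a per-participant folder (one CSV per channel plus CGM).

    The folder name is the participant id.  With ``strict=True`` a missing
    channel file raises; otherwise it is skipped with a warning mark (the
    channel is simply absent from ``signals``).
    """
    directory = Path(directory)
    pid = directory.name
    row = demographics.loc[demographics["participant_id"] == pid]
    if row.empty:
        raise KeyError(f"participant {pid!r} absent from demographics table")
    sex = BiologicalSex(row.iloc[0]["biological_sex"].strip().lower())

    signals: dict[Channel, SignalRecord] = {}
    for channel, fname in RAW_CHANNEL_FILES.items():
        fpath = directory / fname
        if not fpath.exists():
            if strict:
                raise FileNotFoundError(f"{pid}: missing channel file for {channel.value} ({fname})")
            continue
        rec = load_signal(fpath, channel)
        rec.participant_id = pid
        signals[channel] = rec
    acc_path = directory / ACC_FILE
    if acc_path.exists():
        for axis in (Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z):
            rec = load_signal(acc_path, axis)
            rec.participant_id = pid
            signals[axis] = rec
    elif strict:
        raise FileNotFoundError(f"{pid}: missing channel file for ACC ({ACC_FILE})")

    cgm_path = directory / CGM_FILE
    if not cgm_path.exists():
        raise FileNotFoundError(f"{pid}: missing CGM file ({CGM_FILE})")
    cgm = load_glucose(cgm_path, pid)
    return ParticipantRecord(pid, sex, signals, cgm)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_signal(record: SignalRecord, path: str | os.PathLike) -> None:
    """Write a single-channel record as ``timestamp,value`` CSV."""
    pd.DataFrame({"timestamp": record.timestamps, "value": record.values}).to_csv(
        path, index=False
    )


def write_acc(
    x: SignalRecord, y: SignalRecord, z: SignalRecord, path: str | os.PathLike
) -> None:
    """Write tri-axial accelerometry as ``timestamp,x,y,z`` CSV."""
    pd.DataFrame(
        {"timestamp": x.timestamps, "x": x.values, "y": y.values, "z": z.values}
    ).to_csv(path, index=False)


def write_glucose(series: GlucoseSeries, path: str | os.PathLike) -> None:
    pd.DataFrame({"timestamp": series.timestamps, "glucose_mgdl": series.glucose}).to_csv(
        path, index=False
    )


def write_participant(record: ParticipantRecord, directory: str | os.PathLike) -> None:
    """Write a participant to the raw per-folder CSV layout."""
    directory = Path(directory) / record.participant_id
    directory.mkdir(parents=True, exist_ok=True)
    for channel, fname in RAW_CHANNEL_FILES.items():
        if channel in record.signals:
            write_signal(record.signals[channel], directory / fname)
    if Channel.ACC_X in record.signals:
        write_acc(
            record.signals[Channel.ACC_X],
            record.signals[Channel.ACC_Y],
            record.signals[Channel.ACC_Z],
            directory / ACC_FILE,
        )
    if record.cgm is not None:
        write_glucose(record.cgm, directory / CGM_FILE)


def write_demographics(records: Iterable[ParticipantRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "biological_sex": [r.biological_sex.value for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

#: Non-feature columns every feature table carries.
META_COLUMNS = ("participant_id", "glucose_time", "glucose")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature table (manifest order)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table to CSV or Parquet (by extension), losslessly.

    Parquet preserves NaN/typing exactly; CSV uses empty fields for missing.
    """
    if table.shape[0] == 0 or not feature_columns(table):
        raise ValueError("refusing to write an empty feature table")
    if "glucose" not in table.columns:
        raise ValueError("feature table must contain the 'glucose' target column")
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path)
    if "glucose" not in table.columns or not feature_columns(table):
        raise DataFormatError(f"{path}: not a feature table (needs target + features)")
    return table
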