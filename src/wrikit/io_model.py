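"""Data model and file I/O for dual-wrist inertial recordings.

A recording session is one participant performing the wrist-rotation-imitation
(WRI) protocol: three 20-second imitation blocks separated by 10-second rests,
with a six-axis inertial sensor (3-axis accelerometer in g, 3-axis gyroscope in
deg/s) on each wrist sampling at a nominal 50 Hz.  The on-disk format is one
CSV per session (long format, both wrists stacked) plus a JSON sidecar holding
group, age and the protocol schedule.

Unit convention: acceleration in g, angular velocity in deg/s; the y-axis is
the wrist pronation/supination axis, so ``gy`` carries the rotation signal the
metrics consume.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImuSeries",
    "ProtocolSchedule",
    "SessionRecording",
    "FormatError",
    "IncompleteRecordingError",
    "CoverageError",
    "AGE_BANDS",
    "age_band_of",
    "segment_blocks",
    "read_session",
    "write_session",
    "build_cohort_table",
]

#: Age bands used to stratify the cohort (years), keyed by label.
AGE_BANDS = {
    "3.5-4.5": (42.0, 54.0),
    "4.5-5.5": (54.0, 66.0),
    "5.5-6.5": (66.0, 78.0),
}

STUDY_AGE_RANGE_MONTHS = (42.0, 78.0)

IMU_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

SESSION_COLUMNS = [
    "participant_id",
    "wrist",
    "t_s",
    "ax_g",
    "ay_g",
    "az_g",
    "gx_dps",
    "gy_dps",
    "gz_dps",
]


class FormatError(ValueError):
    """A recording file violates the documented format."""


class IncompleteRecordingError(ValueError):
    """A session is missing one of the two wrists."""


class CoverageError(ValueError):
    """A series is too short to cover the protocol schedule."""


@dataclass
class ImuSeries:
    """Six-channel inertial time series for one wrist.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds, monotone non-decreasing on input; duplicates
        are dropped (first kept) so that ``t`` is strictly increasing.
    ax, ay, az : array of float
        Linear acceleration in g.
    gx, gy, gz : array of float
        Angular velocity in deg/s.  ``gy`` is the wrist-rotation axis.
    nominal_rate : float
        Nominal sampling rate in Hz (50 for the study hardware).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    nominal_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError(f"nominal_rate must be > 0, got {self.nominal_rate}")
        arrays = {"t": np.asarray(self.t, dtype=float)}
        for ch in IMU_CHANNELS:
            arrays[ch] = np.asarray(getattr(self, ch), dtype=float)
        n = arrays["t"].size
        for ch, arr in arrays.items():
            if arr.ndim != 1:
                raise ValueError(f"channel {ch} must be 1-D")
            if arr.size != n:
                raise ValueError(
                    f"channel {ch} has {arr.size} samples, expected {n} (same as t)"
                )
        if n and np.any(np.diff(arrays["t"]) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")
        # Strict monotonicity is required downstream (interpolation); keep the
        # first sample of each duplicated timestamp.
        if n:
            keep = np.concatenate([[True], np.diff(arrays["t"]) > 0])
            if not keep.all():
                for ch in ("t", *IMU_CHANNELS):
                    arrays[ch] = arrays[ch][keep]
        for ch in ("t", *IMU_CHANNELS):
            object.__setattr__(self, ch, arrays[ch])

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Span of the series in seconds (0 for fewer than 2 samples)."""
        return float(self.t[-1] - self.t[0]) if len(self) >= 2 else 0.0

    def channels(self) -> dict[str, np.ndarray]:
        return {ch: getattr(self, ch) for ch in IMU_CHANNELS}

    def replace(self, **kwargs) -> "ImuSeries":
        return dataclasses.replace(self, **kwargs)

    def crop(self, t0: float, t1: float) -> "ImuSeries":
        """Samples with t in the half-open window [t0, t1)."""
        mask = (self.t >= t0) & (self.t < t1)
        kw = {ch: getattr(self, ch)[mask] for ch in ("t", *IMU_CHANNELS)}
        return ImuSeries(nominal_rate=self.nominal_rate, **kw)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Block structure of the WRI task: imitation blocks separated by rests."""

    n_blocks: int = 3
    block_duration: float = 20.0
    rest_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.block_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be > 0")

    @property
    def total_duration(self) -> float:
        """Seconds from block-1 onset to the end of the last block."""
        return (
            self.n_blocks * self.block_duration
            + (self.n_blocks - 1) * self.rest_duration
        )

    def block_window(self, k: int) -> tuple[float, float]:
        """Half-open [start, end) window of block ``k`` (0-based), in seconds."""
        start = k * (self.block_duration + self.rest_duration)
        return start, start + self.block_duration


@dataclass
class SessionRecording:
    """One participant's dual-wrist recording plus protocol metadata."""

    participant_id: str
    group: str  # "ASD" or "TD"
    age_months: float
    left: ImuSeries
    right: ImuSeries
    schedule: ProtocolSchedule = field(default_factory=ProtocolSchedule)

    def __post_init__(self) -> None:
        if self.group not in ("ASD", "TD"):
            raise ValueError(f"group must be 'ASD' or 'TD', got {self.group!r}")
        lo, hi = STUDY_AGE_RANGE_MONTHS
        if not lo <= self.age_months <= hi:
            warnings.warn(
                f"age {self.age_months} months outside the study range "
                f"[{lo}, {hi}] (3.5-6.5 y)",
                stacklevel=2,
            )

    @property
    def wrists(self) -> dict[str, ImuSeries]:
        return {"left": self.left, "right": self.right}


def age_band_of(age_months: float) -> str:
    """Deterministic age-band label for an age in months.

    Bands are half-open [lo, hi) except the last, which includes its upper
    edge so the full study range maps to a band.
    """
    labels = list(AGE_BANDS)
    for i, (label, (lo, hi)) in enumerate(AGE_BANDS.items()):
        last = i == len(labels) - 1
        if lo <= age_months < hi or (last and age_months == hi):
            return label
    raise ValueError(f"age {age_months} months outside bands {list(AGE_BANDS.values())}")


def segment_blocks(series: ImuSeries, schedule: ProtocolSchedule) -> list[ImuSeries]:
    """Cut a wrist series into its imitation blocks.

    Block boundaries come from the protocol clock — the recording is assumed
    to start at block-1 onset — so block ``k`` covers the half-open window
    ``[k*(block+rest), k*(block+rest) + block)`` seconds.  Trailing samples
    beyond the last block are ignored.

    Raises
    ------
    CoverageError
        If the series does not span the full schedule.
    """
    needed = schedule.total_duration
    # a recording sampled on [0, needed) covers the schedule even though its
    # last timestamp falls one sample interval short of `needed`
    if series.duration < needed - 1.0 / series.nominal_rate:
        missing = needed - series.duration
        raise CoverageError(
            f"series spans {series.duration:.2f} s but the schedule needs "
            f"{needed:.2f} s ({missing:.2f} s missing)"
        )
    t0 = float(series.t[0])
    out = []
    for k in range(schedule.n_blocks):
        start, end = schedule.block_window(k)
        out.append(series.crop(t0 + start, t0 + end))
    return out


# ---------------------------------------------------------------------------
# File round-trip: CSV with JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session as ``<path>.csv`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    frames = []
    for wrist, series in session.wrists.items():
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": session.participant_id,
                    "wrist": wrist,
                    "t_s": series.t,
                    "ax_g": series.ax,
                    "ay_g": series.ay,
                    "az_g": series.az,
                    "gx_dps": series.gx,
                    "gy_dps": series.gy,
                    "gz_dps": series.gz,
                }
            )
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly, keeping the write/read identity
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "group": session.group,
        "age_months": session.age_months,
        "schedule": {
            "n_blocks": session.schedule.n_blocks,
            "block_duration": session.schedule.block_duration,
            "rest_duration": session.schedule.rest_duration,
        },
        "nominal_rate": session.left.nominal_rate,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read a session written by :func:`write_session`.

    Raises
    ------
    FormatError
        Missing columns or non-numeric cells (the offending column and row
        index are named).
    IncompleteRecordingError
        If either wrist is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "wrist": str},
        float_precision="round_trip",  # exact IEEE round-trip of %.17g output
    )
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    numeric_cols = SESSION_COLUMNS[2:]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise FormatError(f"{path}: empty cell in column {col!r} at row {row}")
        df[col] = coerced

    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"{path}: sidecar {sidecar_file.name} not found")
    meta = json.loads(sidecar_file.read_text())
    schedule = ProtocolSchedule(**meta.get("schedule", {}))
    rate = float(meta.get("nominal_rate", 50.0))

    wrists: dict[str, ImuSeries] = {}
    for wrist, sub in df.groupby("wrist"):
        if wrist not in ("left", "right"):
            raise FormatError(f"{path}: unknown wrist label {wrist!r}")
        wrists[wrist] = ImuSeries(
            t=sub["t_s"].to_numpy(),
            ax=sub["ax_g"].to_numpy(),
            ay=sub["ay_g"].to_numpy(),
            az=sub["az_g"].to_numpy(),
            gx=sub["gx_dps"].to_numpy(),
            gy=sub["gy_dps"].to_numpy(),
            gz=sub["gz_dps"].to_numpy(),
            nominal_rate=rate,
        )
    for wrist in ("left", "right"):
        if wrist not in wrists:
            raise IncompleteRecordingError(f"{path}: wrist {wrist!r} missing")
    pid = str(df["participant_id"].iloc[0])
    return SessionRecording(
        participant_id=pid,
        group=meta["group"],
        age_months=float(meta["age_months"]),
        left=wrists["left"],
        right=wrists["right"],
        schedule=schedule,
    )


def build_cohort_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble the cohort table: participants x {group, age band, metrics}.

    Each row needs ``participant_id``, ``group``, ``age_months`` and the
    per-participant WRI features (``trt_s``, ``roa_deg``, ``symmetry``);
    clinical-score columns pass through untouched.  ``age_band`` is derived
    deterministically from ``age_months``.
    """
    df = pd.DataFrame(list(rows))
    if df.empty:
        return df
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant_id values: {dupes}")
    df["age_band"] = df["age_months"].map(age_band_of)
    lead = [
        c
        for c in ("participant_id", "group", "age_months", "age_band", "trt_s", "roa_deg", "symmetry")
        if c in df.columns
    ]
    return df[lead + [c for c in df.columns if c not in lead]]
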