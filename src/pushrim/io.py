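"""Reading and writing wheel time series, trial metadata, and metric tables.

File dialect: comma-delimited text with one header row and lowercase
channel names ``time, fx, fy, fz, mx, my, mz, theta``. Angle is stored in
radians, cumulative (not wrapped), so push angle and angular velocity can
be computed without unwrapping heuristics. Sign convention after loading:
forward propulsion is positive theta and positive mz on both wheels; the
left wheel is sign-flipped at load via ``invert``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, SamplingError

CHANNELS = ("time", "fx", "fy", "fz", "mx", "my", "mz", "theta")
#: Channels that carry kinetic signals (everything except time/theta).
KINETIC_CHANNELS = ("fx", "fy", "fz", "mx", "my", "mz")
SIDES = ("left", "right")
CONDITIONS = ("with_racket", "without_racket")

#: Column order of the per-push metrics table.
METRIC_COLUMNS = (
    "ftot_peak", "mz_peak", "ror", "fef", "po_peak", "ai", "pt", "ct", "pa",
)


@dataclass
class WheelGeometry:
    """Wheel and handrim dimensions.

    Defaults describe a 26-inch multi-sport wheel (radius 0.3302 m) with a
    0.267 m handrim and 18 degrees of camber; camber is informational only
    (no metric depends on it).
    """

    wheel_radius: float = 0.3302
    handrim_radius: float = 0.267
    camber_deg: float = 18.0

    def __post_init__(self) -> None:
        if not (0.0 < self.handrim_radius < self.wheel_radius):
            raise ValueError(
                "handrim_radius must satisfy 0 < handrim_radius < wheel_radius"
            )


@dataclass
class TrialMeta:
    """Metadata of one trial (one pass of the course by one participant)."""

    participant_id: str
    condition: str
    dominant_side: str
    target_speed: float = 1.4

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.dominant_side not in SIDES:
            raise ValueError(f"dominant_side must be one of {SIDES}")


@dataclass
class WheelTimeSeries:
    """Synchronized force/moment/angle channels of one wheel for one trial.

    All arrays have identical length; ``time`` is strictly increasing with
    a median step within 1% of ``1/fs``; ``theta`` is the cumulative wheel
    angle in radians. Forces are in newtons, moments in newton-metres.
    """

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    theta: np.ndarray
    side: str = "right"
    fs: float = 240.0

    def __post_init__(self) -> None:
        for name in CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.time.size

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def copy(self) -> "WheelTimeSeries":
        return replace(self, **{c: self.channel(c).copy() for c in CHANNELS})

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.time.size
        if n < 2:
            raise IntegrityError("time series must contain at least 2 samples")
        for name in CHANNELS:
            arr = self.channel(name)
            if arr.shape != (n,):
                raise IntegrityError(
                    f"channel {name!r} has length {arr.size}, expected {n}"
                )
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise IntegrityError(
                    f"channel {name!r} contains non-finite value at row {bad[0]}"
                )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise IntegrityError("time must be strictly increasing")
        median_dt = float(np.median(dt))
        if abs(median_dt - 1.0 / self.fs) > 0.01 / self.fs:
            raise SamplingError(
                f"median sampling interval {median_dt:.6g} s deviates more than "
                f"1% from 1/fs = {1.0 / self.fs:.6g} s"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: self.channel(c) for c in CHANNELS})


def read_trial(
    path,
    side: str,
    fs: float = 240.0,
    invert: bool = False,
) -> WheelTimeSeries:
    """Read one wheel's CSV and return a validated :class:`WheelTimeSeries`.

    Rows are sorted by time before validation, so row order on disk is
    irrelevant. ``invert=True`` flips the sign of ``theta`` and of all
    moment channels, mapping a left wheel's native convention onto the
    propulsion-positive convention used by every downstream metric.

    Raises
    ------
    FormatError
        If a required channel column is missing.
    SamplingError
        If the median time step deviates more than 1% from ``1/fs``.
    IntegrityError
        If any channel contains NaN (the offending row is named).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    for name in CHANNELS:
        if name not in df.columns:
            raise FormatError(f"missing channel: {name}")
    df = df.loc[:, list(CHANNELS)].sort_values("time", kind="stable")
    arrays = {c: df[c].to_numpy(dtype=float) for c in CHANNELS}
    for name in CHANNELS:
        bad = np.flatnonzero(~np.isfinite(arrays[name]))
        if bad.size:
            raise IntegrityError(
                f"channel {name!r} contains non-finite value at row {bad[0]}"
            )
    if invert:
        for name in ("theta", "mx", "my", "mz"):
            arrays[name] = -arrays[name]
    return WheelTimeSeries(side=side, fs=fs, **arrays)


def write_trial(ts: WheelTimeSeries, path) -> Path:
    """Write a wheel time series as CSV; round-trips to 6 significant digits."""
    path = Path(path)
    ts.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


def write_metrics(metrics: Sequence, path) -> Path:
    """Write per-push metrics as CSV (one row per push).

    ``metrics`` is a sequence of :class:`pushrim.kinetics.PushMetrics`.
    Columns are push index, side, then the nine outcome parameters.
    """
    if len(metrics) == 0:
        raise ValueError("cannot write an empty metrics collection")
    rows = [m.to_dict() for m in metrics]
    df = pd.DataFrame(rows)
    cols = ["push", "side", *METRIC_COLUMNS]
    df = df.loc[:, cols]
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_metrics(path) -> pd.DataFrame:
    """Read a per-push metrics CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in ("push", "side", *METRIC_COLUMNS) if c not in df.columns]
    if missing:
        raise FormatError(f"missing metric columns: {missing}")
    return df
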