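"""Per-push outcome parameters and per-trial summaries.

Nine parameters are computed for every analyzed push:

==========  =====================================================  ========
name        definition                                             units
==========  =====================================================  ========
ftot_peak   max of sqrt(fx^2 + fy^2 + fz^2) during the push        N
mz_peak     max propulsive moment during the push                  N*m
ror         max time-derivative of total force during the push     N/s
fef         time-average of \\|Ftan/Ftot\\| * 100, Ftan = mz/r_rim    %
po_peak     max of omega(t) * mz(t) during the push                W
ai          mean mz during the push * push time (= integral of mz) N*m*s
pt          (end_index - start_index + 1) / fs                     s
ct          start-to-start time to the next analyzed push          s
pa          angle traversed during the push                        deg
==========  =====================================================  ========

``ct`` is undefined for the last analyzed push of a trial. ``ror`` and
``fef`` admit alternative definitions (rise-time based RoR, ratio-of-means
or at-peak FEF) kept for sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import signal

from .errors import DegeneratePushError, InsufficientPushesError, ShortPushError
from .io import METRIC_COLUMNS, WheelGeometry
from .preprocessing import VelocitySeries
from .segmentation import Push, PushSet


class QCWarning(UserWarning):
    """Signal-quality anomaly that does not abort the analysis."""


@dataclass
class PushMetrics:
    """The nine outcome parameters of one push."""

    push: int
    side: str
    ftot_peak: float
    mz_peak: float
    ror: float
    fef: float
    po_peak: float
    ai: float
    pt: float
    ct: Optional[float]
    pa: float

    def to_dict(self) -> Dict:
        d = {
            "push": self.push,
            "side": self.side,
            **{name: getattr(self, name) for name in METRIC_COLUMNS},
        }
        if d["ct"] is None:
            d["ct"] = math.nan
        return d


@dataclass
class TrialSummary:
    """Per-side means of the push metrics over the analyzed pushes."""

    side: str
    n_analyzed: int
    means: Dict[str, float]
    mean_velocity: float


def ftot_peak(ftot: np.ndarray, p: Push) -> float:
    """Maximal total force during the push."""
    return float(np.max(ftot[p.start_index : p.end_index + 1]))


def mz_peak(mz: np.ndarray, p: Push) -> float:
    """Maximal propulsive moment during the push.

    Emits a :class:`QCWarning` when the moment is negative throughout the
    push (braking contact under the propulsion-positive convention).
    """
    seg = mz[p.start_index : p.end_index + 1]
    peak = float(np.max(seg))
    if peak < 0:
        warnings.warn(
            f"push [{p.start_index}, {p.end_index}]: propulsive moment "
            "negative throughout contact (braking push)",
            QCWarning,
            stacklevel=2,
        )
    return peak


def rate_of_rise(
    ftot: np.ndarray,
    p: Push,
    fs: float,
    window: int = 15,
    method: str = "max_derivative",
) -> float:
    """Rate of rise of total force for one push (N/s).

    Primary definition: maximum of the Savitzky-Golay time-derivative of
    the total force (order 2, ``window`` samples, computed over the whole
    series so the window can extend past push boundaries) within the push
    interval. Alternative ``peak_over_rise_time`` divides the in-push peak
    force by the time from push start to the peak.
    """
    if p.n_samples < 3:
        raise ShortPushError("rate of rise requires a push of >= 3 samples")
    ftot = np.asarray(ftot, dtype=float)
    if method == "peak_over_rise_time":
        seg = ftot[p.start_index : p.end_index + 1]
        i_peak = int(np.argmax(seg))
        if i_peak == 0:
            i_peak = 1  # peak at onset: use one sample to avoid /0
        return float(seg[i_peak] / (i_peak / fs))
    if method != "max_derivative":
        raise ValueError(f"unknown RoR method {method!r}")
    if ftot.size < window:
        window = ftot.size if ftot.size % 2 == 1 else ftot.size - 1
    dftot = signal.savgol_filter(
        ftot, window_length=window, polyorder=2, deriv=1,
        delta=1.0 / fs, mode="interp",
    )
    return float(np.max(dftot[p.start_index : p.end_index + 1]))


def fef(
    ftot: np.ndarray,
    mz: np.ndarray,
    p: Push,
    geometry: WheelGeometry,
    method: str = "time_average",
) -> float:
    """Fraction of effective force (%).

    The tangential force is derived from the propulsive moment,
    ``Ftan = mz / handrim_radius``. The primary definition averages the
    instantaneous ``|Ftan/Ftot|`` over the push; ``ratio_of_means`` and
    ``at_peak`` variants are available for sensitivity checks.

    Values above 100% (|Ftan| exceeding Ftot at some samples) trigger a
    :class:`QCWarning`, never silent clamping.
    """
    f = ftot[p.start_index : p.end_index + 1]
    ftan = mz[p.start_index : p.end_index + 1] / geometry.handrim_radius
    if np.any(f == 0):
        raise DegeneratePushError(
            f"push [{p.start_index}, {p.end_index}] contains zero total force"
        )
    if method == "time_average":
        value = float(np.mean(np.abs(ftan / f)) * 100.0)
    elif method == "ratio_of_means":
        value = float(np.mean(np.abs(ftan)) / np.mean(f) * 100.0)
    elif method == "at_peak":
        i = int(np.argmax(f))
        value = float(abs(ftan[i] / f[i]) * 100.0)
    else:
        raise ValueError(f"unknown FEF method {method!r}")
    if value > 100.0:
        warnings.warn(
            f"push [{p.start_index}, {p.end_index}]: FEF {value:.1f}% exceeds "
            "100% (tangential force exceeds total force)",
            QCWarning,
            stacklevel=2,
        )
    return value


def po_peak(omega: np.ndarray, mz: np.ndarray, p: Push) -> float:
    """Maximal power output at the handrim, max over the push of omega*mz (W)."""
    seg = (
        omega[p.start_index : p.end_index + 1]
        * mz[p.start_index : p.end_index + 1]
    )
    return float(np.max(seg))


def angular_impulse(mz: np.ndarray, p: Push, fs: float) -> float:
    """Angular impulse (N*m*s): mean propulsive moment times push time.

    Equals the time integral of mz over the contact interval at the
    sampling resolution.
    """
    seg = mz[p.start_index : p.end_index + 1]
    return float(np.mean(seg) * push_time(p, fs))


def push_time(p: Push, fs: float) -> float:
    """Contact duration (s), with the inclusive-interval convention."""
    return p.n_samples / fs


def cycle_time(p_i: Push, p_next: Push, fs: float) -> float:
    """Start-to-start time between consecutive pushes (s)."""
    from .errors import OverlapError

    if p_next.start_index <= p_i.end_index:
        raise OverlapError("cycle time requires strictly ordered pushes")
    return (p_next.start_index - p_i.start_index) / fs


def push_angle(theta: np.ndarray, p: Push) -> float:
    """Wheel angle traversed during the push, in degrees.

    Requires cumulative (unwrapped) angle. A negative result (backward
    motion during contact) emits a :class:`QCWarning`.
    """
    delta = float(theta[p.end_index] - theta[p.start_index])
    value = math.degrees(delta)
    if value < 0:
        warnings.warn(
            f"push [{p.start_index}, {p.end_index}]: negative push angle "
            f"({value:.2f} deg): backward motion during contact",
            QCWarning,
            stacklevel=2,
        )
    return value


def compute_push_metrics(
    ftot: np.ndarray,
    mz: np.ndarray,
    theta: np.ndarray,
    velocity: VelocitySeries,
    push_set: PushSet,
    fs: float,
    geometry: WheelGeometry,
    ror_window: int = 15,
    ror_method: str = "max_derivative",
    fef_method: str = "time_average",
    ftot_amplitude: Optional[np.ndarray] = None,
    mz_amplitude: Optional[np.ndarray] = None,
) -> List[PushMetrics]:
    """All nine parameters for every analyzed push of one wheel.

    ``push_set`` must already have transitional pushes excluded. The push
    index recorded in each :class:`PushMetrics` is the position in
    detection order (0-based), so provenance survives exclusion.

    ``ftot_amplitude``/``mz_amplitude`` optionally supply a
    narrower-band copy of the signals used for the amplitude metrics
    (peaks and rate of rise); they default to ``ftot``/``mz``.
    """
    analyzed = push_set.analyzed
    if not analyzed:
        raise InsufficientPushesError("no analyzed pushes in push set")
    f_amp = ftot if ftot_amplitude is None else ftot_amplitude
    mz_amp = mz if mz_amplitude is None else mz_amplitude
    out: List[PushMetrics] = []
    first = push_set.analyzed_slice.start
    for k, p in enumerate(analyzed):
        ct: Optional[float] = None
        if k + 1 < len(analyzed):
            ct = cycle_time(p, analyzed[k + 1], fs)
        out.append(
            PushMetrics(
                push=first + k,
                side=p.side,
                ftot_peak=ftot_peak(f_amp, p),
                mz_peak=mz_peak(mz_amp, p),
                ror=rate_of_rise(f_amp, p, fs, window=ror_window, method=ror_method),
                fef=fef(ftot, mz, p, geometry, method=fef_method),
                po_peak=po_peak(velocity.omega, mz_amp, p),
                ai=angular_impulse(mz, p, fs),
                pt=push_time(p, fs),
                ct=ct,
                pa=push_angle(theta, p),
            )
        )
    return out


def summarize_trial(
    metrics: Sequence[PushMetrics],
    velocity: VelocitySeries,
) -> TrialSummary:
    """Arithmetic mean of each parameter over the analyzed pushes of one side.

    ``ct`` is averaged over the pushes where it is defined. The mean
    linear wheel velocity over the trial is attached for pace checks.
    """
    if len(metrics) == 0:
        raise InsufficientPushesError("cannot summarize zero analyzed pushes")
    sides = {m.side for m in metrics}
    if len(sides) != 1:
        raise ValueError("summarize_trial expects metrics from a single side")
    means: Dict[str, float] = {}
    for name in METRIC_COLUMNS:
        values = [
            getattr(m, name)
            for m in metrics
            if getattr(m, name) is not None
        ]
        means[name] = float(np.mean(values)) if values else math.nan
    return TrialSummary(
        side=sides.pop(),
        n_analyzed=len(metrics),
        means=means,
        mean_velocity=float(np.mean(velocity.v)),
    )
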