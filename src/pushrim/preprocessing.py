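"""Sensor-offset cancellation, channel filtering, and wheel velocity.

Instrumented wheels exhibit dynamic offsets: slowly varying, largely
angle-dependent baselines in the force/moment channels caused by gravity
acting on the rotating sensor assembly. The model used here is a constant
plus the first angular harmonic, ``c0 + a*sin(theta) + b*cos(theta)``,
fitted per channel by least squares over non-contact (coast) samples.
This captures the gravity-driven component that dominates in practice.

Wheel angular velocity is the Savitzky-Golay smoothing derivative of the
cumulative angle channel (window 131 samples, polynomial order 1 by
default, i.e. a sliding local-slope estimator ~0.55 s wide at 240 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .errors import CoverageError
from .io import KINETIC_CHANNELS, WheelGeometry, WheelTimeSeries


@dataclass
class ChannelOffsets:
    """Per-channel offset model ``c0 + a*sin(theta) + b*cos(theta)``.

    ``coefficients`` maps each of the six kinetic channels to its
    ``(c0, a, b)`` triple; ``residual_rms`` reports the fit residual per
    channel (same units as the channel).
    """

    coefficients: Dict[str, Tuple[float, float, float]]
    residual_rms: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.coefficients) - set(KINETIC_CHANNELS)
        missing = set(KINETIC_CHANNELS) - set(self.coefficients)
        if extra or missing:
            raise ValueError(
                f"offsets must cover exactly {KINETIC_CHANNELS}; "
                f"extra={sorted(extra)} missing={sorted(missing)}"
            )
        for ch, coef in self.coefficients.items():
            if len(coef) != 3 or not np.all(np.isfinite(coef)):
                raise ValueError(f"non-finite offset coefficients for {ch!r}")

    @classmethod
    def zero(cls) -> "ChannelOffsets":
        return cls({ch: (0.0, 0.0, 0.0) for ch in KINETIC_CHANNELS})

    def evaluate(self, channel: str, theta: np.ndarray) -> np.ndarray:
        c0, a, b = self.coefficients[channel]
        return c0 + a * np.sin(theta) + b * np.cos(theta)


@dataclass
class VelocitySeries:
    """Wheel angular velocity and the linear velocity it implies."""

    omega: np.ndarray  # rad/s
    v: np.ndarray  # m/s

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.omega.shape != self.v.shape:
            raise ValueError("omega and v must have identical length")


def angular_velocity(
    theta: np.ndarray,
    fs: float,
    window: int = 131,
    polyorder: int = 1,
) -> np.ndarray:
    """First time-derivative of the wheel angle by Savitzky-Golay filtering.

    Edges use scipy's polynomial edge fit, which is exact for a linear
    angle (constant velocity) all the way to the boundary samples. Output
    length equals input length.
    """
    theta = np.asarray(theta, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if polyorder < 1:
        raise ValueError("polyorder must be >= 1")
    if theta.size < window:
        raise ValueError(
            f"series length {theta.size} shorter than window {window}"
        )
    return signal.savgol_filter(
        theta, window_length=window, polyorder=polyorder, deriv=1,
        delta=1.0 / fs, mode="interp",
    )


def linear_velocity(omega: np.ndarray, geometry: WheelGeometry) -> np.ndarray:
    """Linear velocity of the wheelchair implied by one wheel, v = omega * r."""
    return np.asarray(omega, dtype=float) * geometry.wheel_radius


def wheel_velocity(
    ts: WheelTimeSeries,
    geometry: WheelGeometry,
    window: int = 131,
    polyorder: int = 1,
) -> VelocitySeries:
    """Angular and linear velocity series for one wheel."""
    omega = angular_velocity(ts.theta, ts.fs, window=window, polyorder=polyorder)
    return VelocitySeries(omega=omega, v=linear_velocity(omega, geometry))


def noncontact_mask(
    ts: WheelTimeSeries,
    threshold: float = 30.0,
    erode_s: float = 0.05,
) -> np.ndarray:
    """Boolean mask of samples safely away from hand contact.

    A provisional segmentation pass (raw total force below ``threshold``)
    is eroded by ``erode_s`` on each side, so offset estimation never sees
    samples adjacent to contact even when the uncorrected threshold pass
    slightly mislocates push boundaries.
    """
    ftot = np.sqrt(ts.fx**2 + ts.fy**2 + ts.fz**2)
    mask = ftot < threshold
    n_erode = int(round(erode_s * ts.fs))
    if n_erode > 0:
        mask = ndimage.binary_erosion(
            mask, structure=np.ones(2 * n_erode + 1, dtype=bool), border_value=1
        )
    return mask


def estimate_offsets(
    ts: WheelTimeSeries,
    mask: np.ndarray,
    model: str = "harmonic",
) -> ChannelOffsets:
    """Least-squares fit of the offset model over masked (non-contact) samples.

    Requires at least 100 masked samples spanning at least one full wheel
    revolution, so the sin/cos terms are identifiable.

    Raises
    ------
    CoverageError
        If the mask selects fewer than 100 samples or the masked angle
        span is below 2*pi.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(ts),):
        raise ValueError("mask length must match series length")
    n_sel = int(mask.sum())
    if n_sel < 100:
        raise CoverageError(
            f"offset mask selects {n_sel} samples; at least 100 required"
        )
    theta = ts.theta[mask]
    span = float(theta.max() - theta.min())
    if span < 2.0 * np.pi:
        raise CoverageError(
            f"masked angle span {span:.3f} rad covers less than one revolution"
        )
    if model == "none":
        return ChannelOffsets.zero()
    if model == "constant":
        design = np.ones((n_sel, 1))
    elif model == "harmonic":
        design = np.column_stack(
            [np.ones(n_sel), np.sin(theta), np.cos(theta)]
        )
    else:
        raise ValueError(f"unknown offset model {model!r}")

    coefficients: Dict[str, Tuple[float, float, float]] = {}
    residual_rms: Dict[str, float] = {}
    for ch in KINETIC_CHANNELS:
        y = ts.channel(ch)[mask]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        full = np.zeros(3)
        full[: beta.size] = beta
        coefficients[ch] = (float(full[0]), float(full[1]), float(full[2]))
        resid = y - design @ beta
        residual_rms[ch] = float(np.sqrt(np.mean(resid**2)))
    return ChannelOffsets(coefficients, residual_rms)


def remove_offsets(ts: WheelTimeSeries, offsets: ChannelOffsets) -> WheelTimeSeries:
    """Subtract the offset model (evaluated at each sample's angle).

    Note: not idempotent — applying the same non-zero offsets twice
    subtracts the model twice.
    """
    out = ts.copy()
    for ch in KINETIC_CHANNELS:
        corrected = out.channel(ch) - offsets.evaluate(ch, out.theta)
        setattr(out, ch, corrected)
    return out


def lowpass_kinetics(
    ts: WheelTimeSeries,
    cutoff_hz: Optional[float],
    order: int = 4,
) -> WheelTimeSeries:
    """Zero-phase Butterworth low-pass of the six force/moment channels.

    ``cutoff_hz=None`` returns an unmodified copy. Time and angle channels
    are never filtered.
    """
    out = ts.copy()
    if cutoff_hz is None:
        return out
    nyq = ts.fs / 2.0
    if not (0.0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=ts.fs, output="sos")
    for ch in KINETIC_CHANNELS:
        setattr(out, ch, signal.sosfiltfilt(sos, out.channel(ch)))
    return out
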