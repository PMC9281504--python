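"""Analysis configuration.

One dataclass collects every tunable of the pipeline so a run can be
reproduced from its logged configuration alone. Defaults follow common
practice for 240 Hz instrumented-wheel (SmartWheel-class) recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml

#: Methods for the per-push fraction of effective force summary.
FEF_METHODS = ("time_average", "ratio_of_means", "at_peak")
#: Methods for the rate of rise of total force.
ROR_METHODS = ("max_derivative", "peak_over_rise_time")
#: Dynamic offset models.
OFFSET_MODELS = ("none", "constant", "harmonic")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the propulsion analysis pipeline.

    Attributes
    ----------
    threshold_n:
        Total-force threshold (N) defining hand contact. Applied to the
        offset-corrected, low-passed total force.
    min_push_s, min_gap_s:
        Debouncing: candidate pushes shorter than ``min_push_s`` are
        discarded; below-threshold gaps shorter than ``min_gap_s`` are
        merged into the surrounding push.
    sg_window, sg_polyorder:
        Savitzky-Golay smoothing-differentiation window (samples, odd) and
        polynomial order used to derive wheel angular velocity from the
        angle channel. 131 samples is ~0.55 s at 240 Hz.
    lowpass_hz:
        Zero-phase Butterworth low-pass cutoff applied to the six
        force/moment channels before segmentation and the temporal /
        ratio metrics. ``None`` disables filtering (appropriate for
        noise-free synthetic data).
    amplitude_lowpass_hz:
        Additional, narrower zero-phase low-pass used only for the
        amplitude metrics (peak force, peak moment, peak power, rate of
        rise). Push waveforms live below ~6 Hz, so a 12 Hz band passes
        them undistorted while suppressing the upward bias that sensor
        noise adds to any max-over-interval estimate. ``None`` reuses the
        segmentation band.
    lowpass_order:
        Butterworth order (applied forward and backward, so the effective
        attenuation is doubled).
    ror_window:
        Window (samples, odd) of the order-2 Savitzky-Golay derivative
        used for the rate of rise of total force (computed in the
        amplitude band).
    offset_model:
        Dynamic sensor-offset model removed before analysis: ``none``,
        ``constant`` (per-channel mean during non-contact), or
        ``harmonic`` (constant + first harmonic in wheel angle).
    fef_method, ror_method:
        Alternative definitions of FEF and RoR kept for sensitivity
        analyses; the first entry of each tuple is the primary definition.
    d_method:
        ``pooled`` divides the mean difference by sqrt((s0^2+s1^2)/2);
        ``reference_sd`` divides by s.d. of the first group.
    bonferroni_m:
        Family size for the Bonferroni adjustment of post-hoc contrasts
        (per parameter). Default 2: dominant vs non-dominant within each
        of the two conditions.
    alpha:
        Significance level for reporting.
    pace_target_ms, pace_tolerance_ms:
        Target mean propulsion velocity and allowed deviation used by the
        pace check (m/s).
    """

    threshold_n: float = 30.0
    min_push_s: float = 0.10
    min_gap_s: float = 0.05
    sg_window: int = 131
    sg_polyorder: int = 1
    lowpass_hz: Optional[float] = 20.0
    amplitude_lowpass_hz: Optional[float] = 12.0
    lowpass_order: int = 4
    ror_window: int = 15
    offset_model: str = "harmonic"
    fef_method: str = "time_average"
    ror_method: str = "max_derivative"
    d_method: str = "pooled"
    bonferroni_m: int = 2
    alpha: float = 0.05
    pace_target_ms: float = 1.4
    pace_tolerance_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold_n <= 0:
            raise ValueError("threshold_n must be positive")
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ValueError("sg_window must be odd and >= 3")
        if self.ror_window % 2 == 0 or self.ror_window < 5:
            raise ValueError("ror_window must be odd and >= 5")
        if self.sg_polyorder < 1:
            raise ValueError("sg_polyorder must be >= 1")
        if self.offset_model not in OFFSET_MODELS:
            raise ValueError(f"offset_model must be one of {OFFSET_MODELS}")
        if self.fef_method not in FEF_METHODS:
            raise ValueError(f"fef_method must be one of {FEF_METHODS}")
        if self.ror_method not in ROR_METHODS:
            raise ValueError(f"ror_method must be one of {ROR_METHODS}")
        if self.lowpass_hz is not None and self.lowpass_hz <= 0:
            raise ValueError("lowpass_hz must be positive or None")
        if self.amplitude_lowpass_hz is not None and self.amplitude_lowpass_hz <= 0:
            raise ValueError("amplitude_lowpass_hz must be positive or None")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
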