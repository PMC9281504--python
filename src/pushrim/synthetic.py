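"""Synthetic instrumented-wheel trials with analytic ground truth.

The generator emulates SmartWheel-class recordings of paced straight-line
propulsion: half-sine total-force pushes at ~0.8 Hz cadence, a tangential
fraction of 25-45%, ~1.4 m/s on a 26-inch wheel, additive Gaussian sensor
noise and optional angle-dependent offsets. Every outcome parameter of a
generated push has a closed form, so the full pipeline can be scored
against exact ground truth:

- ``Ftot(t) = F * sin(pi (t - t0) / PT)`` within a push, 0 between pushes;
- ``Mz = tf * Ftot * r_rim`` (tangential fraction ``tf``);
- the non-tangential force is split 80/20 (by squared magnitude) between
  the in-plane radial and out-of-plane components, so the three force
  channels reconstruct ``Ftot`` exactly;
- wheel angle integrates ``omega(t) = v/r_wheel + A*sin(pi (t-t0)/PT)``
  (an in-push ripple of amplitude ``A``, analytically integrated).

Because detection uses a force threshold, the *operational* push interval
is the above-threshold part of the half-sine; the ground-truth forms take
the threshold as an argument (``threshold=0`` recovers the ideal forms,
e.g. ``RoR = pi F / PT`` and ``AI = (2/pi) F tf r PT``).

Push-to-push, participant and trial variability are multiplicative
(lognormal, median-preserving), matching the log-transformed analysis the
statistics layer applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import METRIC_COLUMNS, WheelGeometry, WheelTimeSeries, write_trial
from .preprocessing import ChannelOffsets
from .pipeline import StudyManifest, TrialFiles

PROFILE_FIELDS = (
    "peak_force",
    "tangential_fraction",
    "push_duration",
    "cycle_duration",
    "mean_speed",
)

#: Fraction of the squared non-tangential force assigned to the in-plane
#: radial component (the rest is out-of-plane). Arbitrary but fixed: only
#: the resultant and Mz enter any outcome parameter.
RADIAL_SHARE = 0.8

#: Floor on the realized per-cell peak force (N). Subject random effects
#: are truncated here so every simulated wheel stays detectable at the
#: 30 N contact threshold — participants who cannot clear the threshold
#: would contribute no analyzable pushes in a real study either.
MIN_PEAK_FORCE = 45.0


@dataclass
class PushProfile:
    """Median push characteristics of one wheel in one trial.

    Defaults sit in the middle of the regime reported for paced 1.4 m/s
    court-wheelchair propulsion: ~95 N peak resultant force, 33%
    tangential fraction, 0.35 s pushes at a 1.2 s cycle.
    """

    peak_force: float = 95.0
    tangential_fraction: float = 0.33
    push_duration: float = 0.35
    cycle_duration: float = 1.2
    mean_speed: float = 1.4

    def __post_init__(self) -> None:
        if not (0.0 < self.tangential_fraction <= 1.0):
            raise ValueError("tangential_fraction must be in (0, 1]")
        if self.push_duration >= self.cycle_duration:
            raise ValueError("push_duration must be < cycle_duration")
        if self.peak_force <= 30.0:
            raise ValueError("peak_force must exceed 30 N to be detectable")
        if self.mean_speed <= 0 or self.push_duration <= 0:
            raise ValueError("speeds and durations must be positive")


@dataclass
class TrialRecipe:
    """Everything needed to synthesize one wheel's trial deterministically."""

    n_pushes: int = 12
    profile: PushProfile = field(default_factory=PushProfile)
    push_cv: Dict[str, float] = field(
        default_factory=lambda: {
            "peak_force": 0.05,
            "tangential_fraction": 0.05,
            "push_duration": 0.05,
            "cycle_duration": 0.05,
        }
    )
    noise_sd: float = 2.0
    offsets: Optional[ChannelOffsets] = None
    geometry: WheelGeometry = field(default_factory=WheelGeometry)
    fs: float = 240.0
    seed: int = 0
    ripple_amp: float = 0.1
    lead_in_s: float = 1.0
    tail_s: float = 1.0
    side: str = "right"

    def __post_init__(self) -> None:
        if self.n_pushes < 4:
            raise ValueError(
                "n_pushes must be >= 4 so at least one push survives "
                "transitional exclusion"
            )
        if any(v < 0 for v in self.push_cv.values()):
            raise ValueError("push-level CVs must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        unknown = set(self.push_cv) - set(PROFILE_FIELDS)
        if unknown:
            raise ValueError(f"unknown push_cv fields: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Analytic per-push truth for a generated trial.

    Arrays are indexed in detection order. ``metrics(threshold)`` returns
    the nine outcome parameters as the pipeline should measure them when
    it segments at the given total-force threshold.
    """

    t_start: np.ndarray  # half-sine onset time per push (s)
    peak_force: np.ndarray
    tangential_fraction: np.ndarray
    push_duration: np.ndarray
    omega_base: float
    ripple_amp: float
    fs: float
    geometry: WheelGeometry

    @property
    def n_pushes(self) -> int:
        return self.t_start.size

    @property
    def analyzed_indices(self) -> np.ndarray:
        return np.arange(2, self.n_pushes - 1)

    def metrics(
        self, threshold: float = 0.0, analyzed_only: bool = True
    ) -> pd.DataFrame:
        """Closed-form outcome parameters at a detection threshold.

        With ``threshold=0`` these are the ideal half-sine forms
        (``RoR = pi F/PT``, ``AI = (2/pi) F tf r PT``, ``PT`` the full
        half-sine duration, ...). With a positive threshold the interval
        is the above-threshold portion: onset shifts by
        ``(PT/pi) * asin(thr/F)`` and RoR/AI/PA acquire the matching
        ``sqrt(1 - (thr/F)^2)`` factor.
        """
        F = self.peak_force
        tf = self.tangential_fraction
        pt_full = self.push_duration
        r = self.geometry.handrim_radius
        if threshold < 0 or np.any(threshold >= F):
            raise ValueError("threshold must satisfy 0 <= threshold < peak force")
        phi = np.arcsin(threshold / F)  # onset phase of the detected interval
        cos_phi = np.sqrt(1.0 - (threshold / F) ** 2)
        t_on = self.t_start + pt_full * phi / math.pi
        pt = pt_full * (1.0 - 2.0 * phi / math.pi)
        ct = np.full_like(pt, np.nan)
        ct[:-1] = np.diff(t_on)
        omega_pk = self.omega_base + self.ripple_amp
        pa = (
            self.omega_base * pt
            + self.ripple_amp * (2.0 * pt_full / math.pi) * cos_phi
        ) * (180.0 / math.pi)
        df = pd.DataFrame(
            {
                "push": np.arange(self.n_pushes),
                "ftot_peak": F,
                "mz_peak": tf * F * r,
                "ror": (math.pi * F / pt_full) * cos_phi,
                "fef": 100.0 * tf,
                "po_peak": omega_pk * tf * F * r,
                "ai": (2.0 / math.pi) * tf * F * r * pt_full * cos_phi,
                "pt": pt,
                "ct": ct,
                "pa": pa,
            }
        )
        if analyzed_only:
            df = df.iloc[self.analyzed_indices].reset_index(drop=True)
            df.loc[df.index[-1], "ct"] = np.nan  # undefined for last analyzed
        return df


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size
) -> np.ndarray:
    """Median-preserving multiplicative noise with coefficient ~cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=size))


def generate_trial(recipe: TrialRecipe) -> Tuple[WheelTimeSeries, GroundTruth]:
    """Synthesize one wheel's trial; deterministic given ``recipe.seed``."""
    rng = np.random.default_rng(recipe.seed)
    prof = recipe.profile
    n = recipe.n_pushes
    cv = recipe.push_cv

    F = prof.peak_force * _lognormal_factors(rng, cv.get("peak_force", 0.0), n)
    tf = np.clip(
        prof.tangential_fraction
        * _lognormal_factors(rng, cv.get("tangential_fraction", 0.0), n),
        1e-3,
        1.0,
    )
    pt = prof.push_duration * _lognormal_factors(
        rng, cv.get("push_duration", 0.0), n
    )
    ct = prof.cycle_duration * _lognormal_factors(
        rng, cv.get("cycle_duration", 0.0), n
    )
    pt = np.minimum(pt, 0.9 * ct)  # keep pushes inside their cycles

    t_start = recipe.lead_in_s + np.concatenate([[0.0], np.cumsum(ct[:-1])])
    duration = t_start[-1] + pt[-1] + recipe.tail_s
    n_samples = int(round(duration * recipe.fs))
    time = np.arange(n_samples) / recipe.fs

    ftot = np.zeros(n_samples)
    ftan = np.zeros(n_samples)
    omega_base = prof.mean_speed / recipe.geometry.wheel_radius
    ripple_int = np.zeros(n_samples)  # integral of the in-push omega ripple
    ripple_done = 0.0
    for k in range(n):
        i0 = int(np.searchsorted(time, t_start[k]))
        i1 = int(np.searchsorted(time, t_start[k] + pt[k], side="right"))
        phase = math.pi * (time[i0:i1] - t_start[k]) / pt[k]
        shape = np.sin(np.clip(phase, 0.0, math.pi))
        ftot[i0:i1] = F[k] * shape
        ftan[i0:i1] = tf[k] * F[k] * shape
        ripple_int[i0:i1] = ripple_done + recipe.ripple_amp * (
            pt[k] / math.pi
        ) * (1.0 - np.cos(np.clip(phase, 0.0, math.pi)))
        ripple_done += recipe.ripple_amp * 2.0 * pt[k] / math.pi
        ripple_int[i1:] = ripple_done

    theta = omega_base * time + ripple_int

    # decompose the resultant into the three measured force channels
    f_nontan = np.sqrt(np.maximum(ftot**2 - ftan**2, 0.0))
    f_radial = math.sqrt(RADIAL_SHARE) * f_nontan
    fz = math.sqrt(1.0 - RADIAL_SHARE) * f_nontan
    f_inplane = np.sqrt(ftan**2 + f_radial**2)
    fx = f_inplane * np.cos(theta)
    fy = f_inplane * np.sin(theta)
    mz = ftan * recipe.geometry.handrim_radius
    mx = np.zeros(n_samples)
    my = np.zeros(n_samples)

    channels = {"fx": fx, "fy": fy, "fz": fz, "mx": mx, "my": my, "mz": mz}
    if recipe.offsets is not None:
        for ch in channels:
            channels[ch] = channels[ch] + recipe.offsets.evaluate(ch, theta)
    if recipe.noise_sd > 0:
        m_sd = recipe.noise_sd * recipe.geometry.handrim_radius
        for ch, sd in zip(
            ("fx", "fy", "fz", "mx", "my", "mz"),
            (recipe.noise_sd,) * 3 + (m_sd,) * 3,
        ):
            channels[ch] = channels[ch] + rng.normal(0.0, sd, n_samples)

    ts = WheelTimeSeries(
        time=time,
        theta=theta,
        side=recipe.side,
        fs=recipe.fs,
        **channels,
    )
    truth = GroundTruth(
        t_start=t_start,
        peak_force=F,
        tangential_fraction=tf,
        push_duration=pt,
        omega_base=omega_base,
        ripple_amp=recipe.ripple_amp,
        fs=recipe.fs,
        geometry=recipe.geometry,
    )
    return ts, truth


# ---------------------------------------------------------------------------
# study-level generation


@dataclass
class FieldEffect:
    """Multiplicative design effects on one profile field.

    The cell multiplier is ``condition^c * side^s * interaction^(c*s)``
    with ``c = 1`` for the with-racket condition and ``s = 1`` for the
    dominant side.
    """

    condition: float = 1.0
    side: float = 1.0
    interaction: float = 1.0

    def cell(self, with_racket: bool, dominant: bool) -> float:
        c = 1 if with_racket else 0
        s = 1 if dominant else 0
        return self.condition**c * self.side**s * self.interaction ** (c * s)


EffectSpec = Dict[str, FieldEffect]


def null_effects() -> EffectSpec:
    """No condition/side/interaction effects on any profile field."""
    return {f: FieldEffect() for f in PROFILE_FIELDS}


def racket_effects() -> EffectSpec:
    """Directional preset mimicking the reported with-racket pattern.

    Holding the racket raises the peak force markedly on the dominant
    (racket) side, lowers the tangential fraction there, and shortens
    pushes and cycles; the dominant side is stronger and less effective
    in both conditions. On the dominant side this yields higher
    Ftot_peak, Mz_peak, PO and RoR, and lower FEF, PT, CT and PA with
    the racket — the qualitative pattern the analysis should recover.
    """
    # The push_duration multiplier is calibrated for the *measured* push
    # time: raising the peak force shrinks the sub-threshold tails of the
    # half-sine, which lengthens the detected (30 N thresholded) push by
    # ~6% at these force levels, so the underlying push must shorten by
    # ~11% for the operational push time to drop by the observed ~6%.
    return {
        "peak_force": FieldEffect(condition=1.17, side=1.17, interaction=1.16),
        "tangential_fraction": FieldEffect(
            condition=0.99, side=0.87, interaction=0.83
        ),
        "push_duration": FieldEffect(condition=0.89),
        "cycle_duration": FieldEffect(condition=0.87),
        "mean_speed": FieldEffect(condition=1.01),
    }


DEFAULT_SUBJECT_CV: Dict[str, float] = {
    "peak_force": 0.35,
    "tangential_fraction": 0.20,
    "push_duration": 0.15,
    "cycle_duration": 0.25,
    "mean_speed": 0.03,
}


@dataclass
class SimulatedTrial:
    """In-memory trial of one participant in one condition (both wheels)."""

    participant: str
    condition: str
    dominant_side: str
    wheels: Dict[str, Tuple[WheelTimeSeries, GroundTruth]]

    def role_of(self, side: str) -> str:
        return "dominant" if side == self.dominant_side else "non_dominant"


@dataclass
class StudyResult:
    """Output of :func:`generate_study`."""

    trials: List[SimulatedTrial] = field(default_factory=list)
    manifest: Optional[StudyManifest] = None
    parameters: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None
    effects: EffectSpec = field(default_factory=null_effects)
    geometry: WheelGeometry = field(default_factory=WheelGeometry)


def _cell_profile(
    base: PushProfile,
    subj_mult: Dict[str, float],
    effects: EffectSpec,
    with_racket: bool,
    dominant: bool,
) -> PushProfile:
    values = {}
    for f in PROFILE_FIELDS:
        eff = effects.get(f, FieldEffect())
        values[f] = getattr(base, f) * subj_mult[f] * eff.cell(with_racket, dominant)
    values["peak_force"] = max(values["peak_force"], MIN_PEAK_FORCE)
    values["tangential_fraction"] = min(values["tangential_fraction"], 0.95)
    values["push_duration"] = min(
        values["push_duration"], 0.9 * values["cycle_duration"]
    )
    return PushProfile(**values)


def generate_study(
    n_participants: int = 16,
    effects: Optional[EffectSpec] = None,
    base_recipe: Optional[TrialRecipe] = None,
    seed: int = 0,
    out_dir=None,
    subject_cv: Optional[Dict[str, float]] = None,
) -> StudyResult:
    """Simulate a full 2x2 study at the waveform level.

    Per participant, lognormal random effects scale the base profile;
    condition/side/interaction effects multiply it per design cell; each
    of the four (condition x wheel) recordings is synthesized by
    :func:`generate_trial` with its own sub-seed. With ``out_dir`` set,
    trial CSVs and a YAML manifest are written and
    ``StudyResult.manifest`` can be fed to ``run_study``; otherwise the
    trials stay in memory (see :func:`run_simulated_study`).
    """
    if n_participants < 2:
        raise ValueError("a study needs at least 2 participants")
    effects = effects if effects is not None else null_effects()
    base_recipe = base_recipe or TrialRecipe()
    subject_cv = subject_cv or DEFAULT_SUBJECT_CV
    rng = np.random.default_rng(seed)

    trials: List[SimulatedTrial] = []
    truth_rows = []
    for i in range(n_participants):
        pid = f"S{i + 1:02d}"
        dominant_side = "left" if i % 5 == 4 else "right"
        subj_mult = {
            f: float(_lognormal_factors(rng, subject_cv.get(f, 0.0), ())[()])
            if subject_cv.get(f, 0.0) > 0
            else 1.0
            for f in PROFILE_FIELDS
        }
        for condition in ("with_racket", "without_racket"):
            wheels = {}
            for side in ("left", "right"):
                dominant = side == dominant_side
                profile = _cell_profile(
                    base_recipe.profile,
                    subj_mult,
                    effects,
                    with_racket=condition == "with_racket",
                    dominant=dominant,
                )
                recipe = replace(
                    base_recipe,
                    profile=profile,
                    seed=int(rng.integers(2**31)),
                    side=side,
                )
                wheels[side] = generate_trial(recipe)
                truth_rows.append(
                    {
                        "participant": pid,
                        "condition": condition,
                        "side": "dominant" if dominant else "non_dominant",
                        **{f: getattr(profile, f) for f in PROFILE_FIELDS},
                    }
                )
            trials.append(
                SimulatedTrial(
                    participant=pid,
                    condition=condition,
                    dominant_side=dominant_side,
                    wheels=wheels,
                )
            )

    result = StudyResult(
        trials=trials,
        truth=pd.DataFrame(truth_rows),
        effects=effects,
        geometry=base_recipe.geometry,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for trial in trials:
            files = {}
            for side, (ts, _) in trial.wheels.items():
                fname = f"{trial.participant}_{trial.condition}_{side}.csv"
                write_trial(ts, out_dir / fname)
                files[side] = out_dir / fname
            entries.append(
                TrialFiles(
                    participant=trial.participant,
                    condition=trial.condition,
                    dominant_side=trial.dominant_side,
                    files=files,
                )
            )
        result.manifest = StudyManifest(
            trials=entries,
            geometry=base_recipe.geometry,
            fs=base_recipe.fs,
        )
        result.truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return result


def simulate_parameter_studies(
    n_replicates: int,
    n_participants: int = 16,
    effects: Optional[EffectSpec] = None,
    base_profile: Optional[PushProfile] = None,
    geometry: Optional[WheelGeometry] = None,
    subject_cv: Optional[Dict[str, float]] = None,
    trial_cv: float = 0.02,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Parameter-level study sampler for calibration experiments.

    Skips waveform synthesis: per replicate, participant and design cell,
    the five profile fields are drawn from the same multiplicative
    (lognormal) model used by :func:`generate_study` — subject random
    effect x design-cell effect x i.i.d. trial noise (``trial_cv``, the
    residual push-averaging variability) — and the nine outcome
    parameters follow from their ideal closed forms. Returns, per
    parameter, an array of shape ``(n_replicates, n_participants, 2, 2)``
    with axes (condition: with/without, side: dominant/non-dominant),
    ready for :func:`pushrim.stats.rm_anova_2x2_batch`.

    This is the fast path for type-I-error and power studies, where
    statistical behaviour — not signal processing — is under test.
    """
    effects = effects if effects is not None else null_effects()
    base = base_profile or PushProfile()
    geometry = geometry or WheelGeometry()
    subject_cv = subject_cv or DEFAULT_SUBJECT_CV
    rng = np.random.default_rng(seed)
    shape = (n_replicates, n_participants, 2, 2)

    cellmult = {
        f: np.array(
            [
                [effects.get(f, FieldEffect()).cell(w, d) for d in (True, False)]
                for w in (True, False)
            ]
        )
        for f in PROFILE_FIELDS
    }
    fields: Dict[str, np.ndarray] = {}
    for f in PROFILE_FIELDS:
        subj = _lognormal_factors(
            rng, subject_cv.get(f, 0.0), (n_replicates, n_participants, 1, 1)
        )
        noise = _lognormal_factors(rng, trial_cv, shape)
        fields[f] = getattr(base, f) * subj * cellmult[f] * noise

    F = np.maximum(fields["peak_force"], MIN_PEAK_FORCE)
    tf = np.minimum(fields["tangential_fraction"], 0.95)
    pt = np.minimum(fields["push_duration"], 0.9 * fields["cycle_duration"])
    ct = fields["cycle_duration"]
    omega = fields["mean_speed"] / geometry.wheel_radius
    r = geometry.handrim_radius
    return {
        "ftot_peak": F,
        "mz_peak": tf * F * r,
        "ror": math.pi * F / pt,
        "fef": 100.0 * tf,
        "po_peak": omega * tf * F * r,
        "ai": (2.0 / math.pi) * tf * F * r * pt,
        "pt": pt,
        "ct": ct,
        "pa": omega * pt * (180.0 / math.pi),
    }


def run_simulated_study(study: StudyResult, config=None) -> "pd.DataFrame":
    """Analyze an in-memory simulated study; returns the summaries table.

    Mirrors the per-trial loop of :func:`pushrim.pipeline.run_study`
    without the file round-trip, so large replicate counts stay cheap.
    Feed the result to :func:`pushrim.pipeline.compare_parameters` for
    the report tables.
    """
    from .config import AnalysisConfig
    from .pipeline import analyze_wheel

    config = config or AnalysisConfig()
    rows = []
    for trial in study.trials:
        for side, (ts, _) in sorted(trial.wheels.items()):
            summary, metrics, push_set, velocity = analyze_wheel(
                ts, study.geometry, config
            )
            rows.append(
                {
                    "participant": trial.participant,
                    "condition": trial.condition,
                    "side": side,
                    "role": trial.role_of(side),
                    "n_detected": push_set.n_detected,
                    "n_analyzed": push_set.n_analyzed,
                    "mean_velocity": summary.mean_velocity,
                    **summary.means,
                }
            )
    return pd.DataFrame(rows)
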