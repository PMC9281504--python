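"""Within-subject statistics for the 2x2 (condition x side) design.

The comparison protocol: positive outcome parameters are natural-log
transformed (they are right-skewed and vary multiplicatively), normality
is screened per cell with Shapiro-Wilk, a two-within-factor repeated
measures ANOVA tests condition (with vs without racket), side (dominant
vs non-dominant) and their interaction, and paired t tests compare the
dominant hand across conditions. Effect sizes are partial eta-squared
(``SS_effect / (SS_effect + SS_error)``) for ANOVA effects and a
pooled-SD standardized mean difference (``|m0 - m1| / sqrt((s0^2 +
s1^2)/2)``, reported on the untransformed scale) for pairwise contrasts.
Bonferroni adjustment handles the post-hoc contrast family.

Greenhouse-Geisser correction: with only two levels per factor, the
sphericity assumption is trivially satisfied and epsilon equals exactly 1,
so the corrected and uncorrected degrees of freedom coincide. The
correction is carried explicitly (``gg_epsilon`` field) rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError

EFFECTS = ("condition", "side", "interaction")

#: Cohen's thresholds for the standardized mean difference d.
D_THRESHOLDS = ((0.8, "large"), (0.5, "moderate"), (0.2, "small"))
#: Cohen's thresholds for partial eta-squared.
ETA2P_THRESHOLDS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))


@dataclass
class ParameterPanel:
    """One parameter's values in the four design cells, per participant.

    ``values`` has shape ``(n_participants, 2, 2)`` with axis 1 the
    condition (0 = with_racket, 1 = without_racket) and axis 2 the side
    (0 = dominant, 1 = non-dominant). Complete cases only.
    """

    values: np.ndarray
    parameter: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (2, 2):
            raise ValueError("panel must have shape (n, 2, 2)")
        if self.values.shape[0] < 2:
            raise DegenerateDataError("panel needs at least 2 participants")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateDataError(
                f"panel {self.parameter!r} has incomplete cases (non-finite cells)"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        parameter: str,
        value_col: str = "value",
    ) -> "ParameterPanel":
        """Build a panel from long-format rows (participant, condition, side).

        ``condition`` must be ``with_racket``/``without_racket`` and
        ``side`` ``dominant``/``non_dominant``.
        """
        sub = df[df["parameter"] == parameter] if "parameter" in df else df
        wide = sub.pivot_table(
            index="participant",
            columns=["condition", "side"],
            values=value_col,
            aggfunc="first",
        )
        cells = [
            ("with_racket", "dominant"),
            ("with_racket", "non_dominant"),
            ("without_racket", "dominant"),
            ("without_racket", "non_dominant"),
        ]
        missing = [c for c in cells if c not in wide.columns]
        if missing:
            raise DegenerateDataError(
                f"panel {parameter!r} missing design cells: {missing}"
            )
        arr = np.stack(
            [wide[c].to_numpy(dtype=float) for c in cells], axis=1
        ).reshape(-1, 2, 2)
        return cls(arr, parameter=parameter)


@dataclass
class ComparisonResult:
    """One effect's test statistic and effect size."""

    effect_name: str
    statistic: float
    dof: Tuple[float, float]
    p_raw: float
    effect_size: float
    effect_size_kind: str
    p_adjusted: Optional[float] = None
    gg_epsilon: float = 1.0
    sums_of_squares: Dict[str, float] = field(default_factory=dict)


def log_transform(x: Iterable[float], parameter: str = "") -> np.ndarray:
    """Natural logarithm, elementwise; rejects non-positive values."""
    arr = np.asarray(x, dtype=float)
    if np.any(~(arr > 0)):
        label = f" in {parameter!r}" if parameter else ""
        raise ValueError(f"log transform requires positive values{label}")
    return np.log(arr)


def shapiro_wilk(x: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation, via scipy)."""
    arr = np.asarray(x, dtype=float)
    if not (3 <= arr.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise DegenerateDataError("Shapiro-Wilk input is constant")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def paired_t(
    x0: Sequence[float], x1: Sequence[float]
) -> Tuple[float, int, float]:
    """Two-sided paired t test: t, degrees of freedom, p."""
    a = np.asarray(x0, dtype=float)
    b = np.asarray(x1, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t requires two equal-length vectors, n >= 2")
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    n = diff.size
    t = float(np.mean(diff) / (sd / np.sqrt(n)))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return t, n - 1, p


def cohens_d_pooled(
    m0: float, s0: float, m1: float, s1: float, method: str = "pooled"
) -> float:
    """Standardized mean difference between two summarized groups.

    ``pooled`` (primary): ``|m0 - m1| / sqrt((s0^2 + s1^2) / 2)`` — the
    form consistent with reporting d from printed group means and SDs.
    ``reference_sd`` divides by ``s0`` alone (the literal
    reference-group-SD form); it is kept behind this flag because it is
    not self-consistent with pooled-SD effect-size tables.
    """
    if s0 < 0 or s1 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s0 == 0 and s1 == 0:
        raise DegenerateDataError("both group SDs are zero")
    if method == "pooled":
        denom = np.sqrt((s0**2 + s1**2) / 2.0)
    elif method == "reference_sd":
        if s0 == 0:
            raise DegenerateDataError("reference group SD is zero")
        denom = s0
    else:
        raise ValueError(f"unknown d method {method!r}")
    return float(abs(m0 - m1) / denom)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta-squared, SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise DegenerateDataError("both sums of squares are zero")
    return float(ss_effect / (ss_effect + ss_error))


def bonferroni(p_values: Iterable[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m), order-preserving."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    arr = np.asarray(list(p_values), dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, arr * m)


def classify_effect_size(value: float, kind: str) -> str:
    """Cohen's verbal band for an effect size (thresholds inclusive)."""
    if value < 0:
        raise ValueError("effect size must be non-negative")
    if kind == "d":
        thresholds = D_THRESHOLDS
    elif kind == "eta2p":
        thresholds = ETA2P_THRESHOLDS
    else:
        raise ValueError(f"unknown effect size kind {kind!r}")
    for cut, label in thresholds:
        if value >= cut:
            return label
    return "negligible"


def _rm_anova_ss(y: np.ndarray) -> Dict[str, np.ndarray]:
    """Sums of squares of the two-within-factor ANOVA, batched.

    ``y`` has shape ``(..., n, 2, 2)``; leading axes are independent
    panels. Returns per-stratum SS arrays of shape ``(...,)``.
    """
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    subj = y.mean(axis=(-2, -1), keepdims=True)  # (..., n, 1, 1)
    a_m = y.mean(axis=(-3, -1), keepdims=True)  # condition means
    b_m = y.mean(axis=(-3, -2), keepdims=True)  # side means
    ab_m = y.mean(axis=-3, keepdims=True)  # cell means
    as_m = y.mean(axis=-1, keepdims=True)  # subject x condition
    bs_m = y.mean(axis=-2, keepdims=True)  # subject x side

    n = y.shape[-3]
    ss = {}
    ss["condition"] = (2 * n) * np.sum((a_m - grand) ** 2, axis=(-3, -2, -1))
    ss["side"] = (2 * n) * np.sum((b_m - grand) ** 2, axis=(-3, -2, -1))
    ss["interaction"] = n * np.sum(
        (ab_m - a_m - b_m + grand) ** 2, axis=(-3, -2, -1)
    )
    ss["err_condition"] = 2 * np.sum(
        (as_m - subj - a_m + grand) ** 2, axis=(-3, -2, -1)
    )
    ss["err_side"] = 2 * np.sum(
        (bs_m - subj - b_m + grand) ** 2, axis=(-3, -2, -1)
    )
    ss["err_interaction"] = np.sum(
        (y - as_m - bs_m - ab_m + a_m + b_m + subj - grand) ** 2,
        axis=(-3, -2, -1),
    )
    ss["subject"] = 4 * np.sum((subj - grand) ** 2, axis=(-3, -2, -1))
    return ss


def rm_anova_2x2_batch(
    y: np.ndarray,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Vectorized 2x2 within-subject ANOVA over a batch of panels.

    ``y``: shape ``(..., n, 2, 2)``. Returns, per effect, arrays ``F``,
    ``p`` and ``eta2p`` with the leading batch shape. Used for simulation
    studies (type-I calibration, power) where per-panel object overhead
    would dominate.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-3]
    if n < 2:
        raise DegenerateDataError("ANOVA needs at least 2 participants")
    ss = _rm_anova_ss(y)
    dof_err = n - 1
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for effect in EFFECTS:
        ms_eff = ss[effect] / 1.0
        ms_err = ss[f"err_{effect}"] / dof_err
        with np.errstate(divide="ignore", invalid="ignore"):
            f_val = ms_eff / ms_err
            f_val = np.where(ms_err == 0, np.where(ms_eff == 0, 0.0, np.inf), f_val)
        p = sps.f.sf(f_val, 1, dof_err)
        denom = ss[effect] + ss[f"err_{effect}"]
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = np.where(denom == 0, 0.0, ss[effect] / denom)
        out[effect] = {"F": f_val, "p": p, "eta2p": eta}
    return out


def rm_anova_2x2(panel: ParameterPanel) -> List[ComparisonResult]:
    """Two-within-factor repeated measures ANOVA on one parameter panel.

    Returns results for the condition, side, and interaction effects.
    Each F is ``MS_effect / MS_(effect x subject)``; partial eta-squared
    is ``SS_effect / (SS_effect + SS_error)``; the Greenhouse-Geisser
    epsilon is exactly 1 for 2-level factors and is recorded as such.
    """
    y = panel.values
    n = panel.n
    ss = _rm_anova_ss(y)
    batch = rm_anova_2x2_batch(y)
    results = []
    for effect in EFFECTS:
        ss_e = float(ss[effect])
        ss_err = float(ss[f"err_{effect}"])
        if ss_e == 0 and ss_err == 0:
            eta = 0.0
        else:
            eta = partial_eta_squared(ss_e, ss_err)
        results.append(
            ComparisonResult(
                effect_name=effect,
                statistic=float(batch[effect]["F"]),
                dof=(1.0, float(n - 1)),
                p_raw=float(batch[effect]["p"]),
                effect_size=eta,
                effect_size_kind="eta2p",
                gg_epsilon=1.0,
                sums_of_squares={"effect": ss_e, "error": ss_err},
            )
        )
    return results
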