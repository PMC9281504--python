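"""Study orchestration: load -> preprocess -> segment -> metrics -> compare.

A *study* is a 2x2 within-subject design: every participant propels once
per condition (with / without racket), and each pass is recorded by two
instrumented wheels, one under the dominant and one under the
non-dominant hand. :func:`run_study` turns a manifest of trial files into

- a *bilateral* report table: per parameter, the four cell means (SD),
  dominant-vs-non-dominant standardized differences per condition, and
  the repeated-measures ANOVA (condition, side, interaction) on
  log-transformed values, with partial eta-squared effect sizes;
- a *unilateral* report table: per parameter, the dominant hand with vs
  without racket — paired t on log values, Bonferroni-adjusted p, and the
  pooled-SD standardized difference on the raw scale;
- per-trial-side summaries and a plain-text run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .errors import CompletenessError, InsufficientPushesError
from .io import (
    CONDITIONS,
    METRIC_COLUMNS,
    SIDES,
    TrialMeta,
    WheelGeometry,
    WheelTimeSeries,
    read_trial,
)
from .kinetics import TrialSummary, compute_push_metrics, summarize_trial
from .preprocessing import (
    estimate_offsets,
    lowpass_kinetics,
    noncontact_mask,
    remove_offsets,
    wheel_velocity,
)
from .segmentation import detect_pushes, exclude_transitional, total_force
from .stats import (
    ParameterPanel,
    bonferroni,
    cohens_d_pooled,
    log_transform,
    paired_t,
    rm_anova_2x2,
)

ROLES = ("dominant", "non_dominant")


@dataclass
class TrialFiles:
    """One pass of the course: metadata plus one file per wheel."""

    participant: str
    condition: str
    dominant_side: str
    files: Dict[str, Path]  # side -> path
    invert: Dict[str, bool] = field(default_factory=dict)

    def role_of(self, side: str) -> str:
        return "dominant" if side == self.dominant_side else "non_dominant"


@dataclass
class StudyManifest:
    """All trials of a study plus shared geometry and config overrides."""

    trials: List[TrialFiles]
    geometry: WheelGeometry = field(default_factory=WheelGeometry)
    fs: float = 240.0
    config_overrides: Dict = field(default_factory=dict)

    def validate_design(self) -> None:
        """Check each participant contributes one complete 2x2 cell set."""
        seen: Dict[Tuple[str, str], TrialFiles] = {}
        for t in self.trials:
            key = (t.participant, t.condition)
            if key in seen:
                raise CompletenessError(
                    f"duplicate trial for participant {t.participant!r}, "
                    f"condition {t.condition!r}"
                )
            seen[key] = t
        missing = []
        participants = {t.participant for t in self.trials}
        for p in sorted(participants):
            for cond in CONDITIONS:
                if (p, cond) not in seen:
                    missing.append((p, cond))
                else:
                    for side in SIDES:
                        if side not in seen[(p, cond)].files:
                            missing.append((p, cond, side))
        if missing:
            raise CompletenessError(f"incomplete design cells: {missing}")


def load_manifest(path) -> StudyManifest:
    """Read a YAML study manifest; file paths resolve relative to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    geometry = WheelGeometry(**raw.get("geometry", {}))
    trials = []
    for entry in raw["trials"]:
        meta = TrialMeta(
            participant_id=str(entry["participant"]),
            condition=entry["condition"],
            dominant_side=entry["dominant_side"],
        )
        files = {
            side: (base / entry[side]).resolve()
            for side in SIDES
            if side in entry
        }
        invert = {side: bool(entry.get(f"invert_{side}", False)) for side in SIDES}
        trials.append(
            TrialFiles(
                participant=meta.participant_id,
                condition=meta.condition,
                dominant_side=meta.dominant_side,
                files=files,
                invert=invert,
            )
        )
    return StudyManifest(
        trials=trials,
        geometry=geometry,
        fs=float(raw.get("fs", 240.0)),
        config_overrides=raw.get("config", {}) or {},
    )


def save_manifest(manifest: StudyManifest, path) -> Path:
    """Write a manifest as YAML with paths relative to the output file."""
    path = Path(path)
    base = path.parent
    entries = []
    for t in manifest.trials:
        entry = {
            "participant": t.participant,
            "condition": t.condition,
            "dominant_side": t.dominant_side,
        }
        for side, p in t.files.items():
            try:
                entry[side] = str(Path(p).relative_to(base))
            except ValueError:
                entry[side] = str(p)
        entries.append(entry)
    doc = {
        "geometry": {
            "wheel_radius": manifest.geometry.wheel_radius,
            "handrim_radius": manifest.geometry.handrim_radius,
            "camber_deg": manifest.geometry.camber_deg,
        },
        "fs": manifest.fs,
        "trials": entries,
    }
    if manifest.config_overrides:
        doc["config"] = manifest.config_overrides
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def analyze_wheel(
    ts: WheelTimeSeries,
    geometry: WheelGeometry,
    config: AnalysisConfig,
):
    """Full single-wheel pipeline: offsets, filtering, segmentation, metrics.

    Returns ``(summary, metrics, push_set, velocity)``.
    """
    if config.offset_model != "none":
        mask = noncontact_mask(ts, threshold=config.threshold_n)
        offsets = estimate_offsets(ts, mask, model=config.offset_model)
        ts = remove_offsets(ts, offsets)
    filtered = lowpass_kinetics(ts, config.lowpass_hz, order=config.lowpass_order)
    ftot = total_force(filtered)
    if config.amplitude_lowpass_hz is not None:
        amplitude = lowpass_kinetics(
            filtered, config.amplitude_lowpass_hz, order=config.lowpass_order
        )
        ftot_amp, mz_amp = total_force(amplitude), amplitude.mz
    else:
        ftot_amp, mz_amp = ftot, filtered.mz
    push_set = exclude_transitional(
        detect_pushes(
            ftot,
            ts.fs,
            threshold=config.threshold_n,
            min_push=config.min_push_s,
            min_gap=config.min_gap_s,
            side=ts.side,
        )
    )
    velocity = wheel_velocity(
        ts, geometry, window=config.sg_window, polyorder=config.sg_polyorder
    )
    metrics = compute_push_metrics(
        ftot,
        filtered.mz,
        ts.theta,
        velocity,
        push_set,
        ts.fs,
        geometry,
        ror_window=config.ror_window,
        ror_method=config.ror_method,
        fef_method=config.fef_method,
        ftot_amplitude=ftot_amp,
        mz_amplitude=mz_amp,
    )
    summary = summarize_trial(metrics, velocity)
    return summary, metrics, push_set, velocity


@dataclass
class StudyReport:
    """Output of :func:`run_study`."""

    bilateral: pd.DataFrame
    unilateral: pd.DataFrame
    summaries: pd.DataFrame
    log: List[str]


def summaries_to_long(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-trial-side summary rows -> long (participant, condition, side,
    parameter, value) format used by the stats layer."""
    rows = []
    for _, r in summaries.iterrows():
        for name in METRIC_COLUMNS:
            rows.append(
                {
                    "participant": r["participant"],
                    "condition": r["condition"],
                    "side": r["role"],
                    "parameter": name,
                    "value": r[name],
                }
            )
    return pd.DataFrame(rows)


def _cell_stats(long: pd.DataFrame, parameter: str) -> Dict[Tuple[str, str], Tuple[float, float]]:
    out = {}
    sub = long[long["parameter"] == parameter]
    for cond in CONDITIONS:
        for role in ROLES:
            v = sub[(sub["condition"] == cond) & (sub["side"] == role)]["value"]
            out[(cond, role)] = (float(v.mean()), float(v.std(ddof=1)))
    return out


def compare_parameters(
    summaries: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Build the bilateral and unilateral comparison tables.

    ``summaries`` is the per-trial-side table produced by
    :func:`run_study` (or assembled by the caller). Tests run on
    log-transformed values; means, SDs and standardized differences d are
    reported on the raw scale, so every printed d is reproducible from
    the printed means and SDs alone.
    """
    config = config or AnalysisConfig()
    long = summaries_to_long(summaries)
    bilateral_rows = []
    unilateral_rows = []
    for name in METRIC_COLUMNS:
        cells = _cell_stats(long, name)
        sub = long[long["parameter"] == name].copy()
        sub["value"] = log_transform(sub["value"].to_numpy(), parameter=name)
        panel = ParameterPanel.from_long(sub, name)
        anova = {r.effect_name: r for r in rm_anova_2x2(panel)}
        row = {"parameter": name}
        for cond, tag in (("with_racket", "with"), ("without_racket", "without")):
            m_d, s_d = cells[(cond, "dominant")]
            m_n, s_n = cells[(cond, "non_dominant")]
            row[f"{tag}_dom_mean"], row[f"{tag}_dom_sd"] = m_d, s_d
            row[f"{tag}_nondom_mean"], row[f"{tag}_nondom_sd"] = m_n, s_n
            row[f"d_{tag}"] = cohens_d_pooled(m_d, s_d, m_n, s_n, config.d_method)
        for effect in ("condition", "side", "interaction"):
            r = anova[effect]
            row[f"F_{effect}"] = r.statistic
            row[f"p_{effect}"] = r.p_raw
            row[f"eta2p_{effect}"] = r.effect_size
        bilateral_rows.append(row)

        # unilateral: dominant hand, with vs without racket
        dom = sub[sub["side"] == "dominant"]
        pivot = dom.pivot_table(
            index="participant", columns="condition", values="value"
        )
        x_with = pivot["with_racket"].to_numpy()
        x_without = pivot["without_racket"].to_numpy()
        t, dof, p = paired_t(x_with, x_without)
        m_w, s_w = cells[("with_racket", "dominant")]
        m_wo, s_wo = cells[("without_racket", "dominant")]
        unilateral_rows.append(
            {
                "parameter": name,
                "with_mean": m_w,
                "with_sd": s_w,
                "without_mean": m_wo,
                "without_sd": s_wo,
                "t": t,
                "dof": dof,
                "p": p,
                "p_adjusted": float(bonferroni([p], config.bonferroni_m)[0]),
                "d": cohens_d_pooled(m_w, s_w, m_wo, s_wo, config.d_method),
            }
        )
    return pd.DataFrame(bilateral_rows), pd.DataFrame(unilateral_rows)


def run_study(
    manifest: StudyManifest,
    config: Optional[AnalysisConfig] = None,
) -> StudyReport:
    """Execute the full pipeline on every trial and compare parameters.

    Raises
    ------
    CompletenessError
        If any 2x2 design cell is missing.
    InsufficientPushesError
        Naming the trial, if any wheel yields fewer than one analyzable
        push.
    """
    config = config or AnalysisConfig()
    if manifest.config_overrides:
        merged = config.to_dict()
        merged.update(manifest.config_overrides)
        config = AnalysisConfig.from_dict(merged)
    manifest.validate_design()
    log: List[str] = [f"config: {config.to_dict()}"]
    rows = []
    for trial in manifest.trials:
        for side, path in sorted(trial.files.items()):
            ts = read_trial(
                path, side=side, fs=manifest.fs,
                invert=trial.invert.get(side, False),
            )
            try:
                summary, metrics, push_set, velocity = analyze_wheel(
                    ts, manifest.geometry, config
                )
            except InsufficientPushesError as exc:
                raise InsufficientPushesError(
                    f"trial {trial.participant}/{trial.condition}/{side}: {exc}"
                ) from exc
            excluded = push_set.n_detected - push_set.n_analyzed
            log.append(
                f"{trial.participant}/{trial.condition}/{side}: "
                f"{push_set.n_detected} pushes detected, {excluded} excluded, "
                f"{push_set.n_analyzed} analyzed; "
                f"mean v = {summary.mean_velocity:.3f} m/s"
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
    summaries = pd.DataFrame(rows)
    bilateral, unilateral = compare_parameters(summaries, config)
    return StudyReport(
        bilateral=bilateral, unilateral=unilateral, summaries=summaries, log=log
    )


def verify_pace(
    summaries: pd.DataFrame,
    target: float = 1.4,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Flag trials whose mean velocity misses the paced target.

    The trial velocity is the mean of the two wheels' mean linear
    velocities. Returns one row per (participant, condition) with the
    velocity and a boolean ``ok``.
    """
    grouped = (
        summaries.groupby(["participant", "condition"])["mean_velocity"]
        .mean()
        .reset_index()
    )
    grouped["ok"] = (grouped["mean_velocity"] - target).abs() <= tolerance
    return grouped


def round_report(df: pd.DataFrame) -> pd.DataFrame:
    """Printed-precision view: means/SDs to 2 decimals, d/eta2p to 3.

    Machine-readable outputs keep full precision; this formatting is for
    human-facing report tables only.
    """
    out = df.copy()
    for col in out.columns:
        if col.startswith(("d_", "eta2p_")) or col in ("d",):
            out[col] = out[col].round(3)
        elif col.endswith(("_mean", "_sd")):
            out[col] = out[col].round(2)
        elif col.startswith(("F_", "p_")) or col in ("t", "p", "p_adjusted"):
            out[col] = out[col].round(3)
    return out
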