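"""Bundled reference summary statistics.

``reference_cells.csv`` holds per-cell group means and standard
deviations of the nine outcome parameters from a published 16-participant
with/without-racket propulsion experiment (2x2 within-subject design,
20 m at 1.4 m/s on a 26-inch court-sports wheelchair). They serve two
purposes:

- verifying the standardized effect-size computation: every reported
  pooled-SD d for this design must be reproducible from its two (mean,
  SD) cells;
- anchoring the synthetic generator's default signal regime so simulated
  report tables are magnitude-comparable to real studies.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd

from .stats import cohens_d_pooled


def load_reference_cells() -> pd.DataFrame:
    """Per-cell (parameter, condition, side) means and SDs."""
    path = resources.files("pushrim").joinpath("data/reference_cells.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def cell(df: pd.DataFrame, parameter: str, condition: str, side: str) -> Tuple[float, float]:
    """(mean, sd) of one design cell."""
    row = df[
        (df["parameter"] == parameter)
        & (df["condition"] == condition)
        & (df["side"] == side)
    ]
    if len(row) != 1:
        raise KeyError((parameter, condition, side))
    return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


def reference_effect_sizes(method: str = "pooled") -> Dict[str, float]:
    """Standardized differences recomputed from the reference cells.

    Keys: ``unilateral_<param>`` (dominant hand, with vs without racket)
    and ``bilateral_<cond>_<param>`` (dominant vs non-dominant within a
    condition).
    """
    df = load_reference_cells()
    out: Dict[str, float] = {}
    for parameter in df["parameter"].unique():
        m_w, s_w = cell(df, parameter, "with_racket", "dominant")
        m_wo, s_wo = cell(df, parameter, "without_racket", "dominant")
        out[f"unilateral_{parameter}"] = cohens_d_pooled(m_w, s_w, m_wo, s_wo, method)
        for cond, tag in (("with_racket", "with"), ("without_racket", "without")):
            m_d, s_d = cell(df, parameter, cond, "dominant")
            m_n, s_n = cell(df, parameter, cond, "non_dominant")
            out[f"bilateral_{tag}_{parameter}"] = cohens_d_pooled(
                m_d, s_d, m_n, s_n, method
            )
    return out
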