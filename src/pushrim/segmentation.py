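"""Push-phase detection from total handrim force.

A push (hand-contact phase) is a maximal run of samples whose total force
``sqrt(fx^2 + fy^2 + fz^2)`` stays at or above a threshold (30 N by
default). Two debouncing rules clean up sensor chatter: below-threshold
gaps shorter than ``min_gap`` are merged into the surrounding push, and
merged runs shorter than ``min_push`` are discarded. The first two and
the last detected pushes of a trial are treated as transitional
(acceleration from standstill / final coast) and excluded from analysis.

Automated segmentation can be amended through an explicit edit-directive
API (:func:`review_segmentation`) which records an audit log entry per
directive, replacing an interactive manual check with a reproducible one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .errors import InsufficientPushesError, OverlapError
from .io import WheelTimeSeries

#: Number of leading pushes excluded as transitional.
N_EXCLUDE_HEAD = 2
#: Number of trailing pushes excluded as transitional.
N_EXCLUDE_TAIL = 1


@dataclass(frozen=True)
class Push:
    """One contact phase: inclusive sample-index interval on one wheel."""

    start_index: int
    end_index: int
    side: str = "right"

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class PushSet:
    """Detected pushes of one wheel plus the transitional-exclusion bookkeeping.

    ``pushes`` holds all detected pushes in time order. ``analyzed``
    (available after :func:`exclude_transitional`) is the contiguous slice
    that survives exclusion of the first two and last pushes.
    """

    pushes: List[Push]
    n_detected: int
    n_analyzed: int = 0
    analyzed_slice: slice = field(default_factory=lambda: slice(0, 0))
    audit_log: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_disjoint_ordered(self.pushes)
        if self.n_detected != len(self.pushes):
            raise ValueError("n_detected must equal the number of pushes")

    @property
    def analyzed(self) -> List[Push]:
        return self.pushes[self.analyzed_slice]


def _check_disjoint_ordered(pushes: Sequence[Push]) -> None:
    for prev, cur in zip(pushes, pushes[1:]):
        if cur.start_index <= prev.end_index:
            raise OverlapError(
                f"pushes [{prev.start_index}, {prev.end_index}] and "
                f"[{cur.start_index}, {cur.end_index}] overlap or are misordered"
            )


def total_force(ts: WheelTimeSeries) -> np.ndarray:
    """Resultant of the three orthogonal force components, elementwise."""
    return np.sqrt(ts.fx**2 + ts.fy**2 + ts.fz**2)


def detect_pushes(
    ftot: np.ndarray,
    fs: float,
    threshold: float = 30.0,
    min_push: float = 0.10,
    min_gap: float = 0.05,
    side: str = "right",
) -> PushSet:
    """Threshold detection of pushes on a total-force series.

    Returns all detected pushes; transitional exclusion is a separate,
    subsequent step (:func:`exclude_transitional`). An empty result is
    legal.
    """
    ftot = np.asarray(ftot, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if np.any(ftot < 0):
        raise ValueError("total force must be non-negative")
    above = ftot >= threshold
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        ends.append(above.size - 1)

    # merge runs separated by a short sub-threshold gap
    max_gap_samples = int(np.floor(min_gap * fs))
    merged: List[List[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] - 1 < max_gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_push_samples = int(np.ceil(min_push * fs))
    pushes = [
        Push(s, e, side=side)
        for s, e in merged
        if (e - s + 1) >= min_push_samples
    ]
    return PushSet(pushes=pushes, n_detected=len(pushes))


def exclude_transitional(ps: PushSet) -> PushSet:
    """Drop the first two and the last detected pushes (transitional).

    Raises
    ------
    InsufficientPushesError
        If fewer than 4 pushes were detected, so nothing analyzable
        remains.
    """
    needed = N_EXCLUDE_HEAD + N_EXCLUDE_TAIL + 1
    if ps.n_detected < needed:
        raise InsufficientPushesError(
            f"{ps.n_detected} pushes detected; at least {needed} required to "
            f"exclude {N_EXCLUDE_HEAD} leading and {N_EXCLUDE_TAIL} trailing "
            "transitional pushes"
        )
    sl = slice(N_EXCLUDE_HEAD, ps.n_detected - N_EXCLUDE_TAIL)
    return PushSet(
        pushes=list(ps.pushes),
        n_detected=ps.n_detected,
        n_analyzed=ps.n_detected - needed + 1,
        analyzed_slice=sl,
        audit_log=list(ps.audit_log),
    )


def review_segmentation(
    ps: PushSet,
    edits: Iterable[Mapping],
    n_samples: Optional[int] = None,
) -> PushSet:
    """Apply manual-review edit directives and re-validate the push set.

    Each directive is a mapping with an ``action`` key:

    - ``{"action": "remove", "push": i}`` — drop detected push ``i`` (0-based);
    - ``{"action": "add", "start": s, "end": e}`` — insert a push;
    - ``{"action": "adjust", "push": i, "start": s, "end": e}`` — move the
      boundaries of push ``i`` (either bound may be omitted).

    Transitional exclusion is re-applied after editing. Every directive is
    recorded in the audit log.
    """
    pushes = list(ps.pushes)
    log = list(ps.audit_log)
    side = pushes[0].side if pushes else "right"
    for edit in edits:
        action = edit.get("action")
        if action == "remove":
            i = int(edit["push"])
            if not (0 <= i < len(pushes)):
                raise IndexError(f"no push {i} to remove")
            removed = pushes.pop(i)
            log.append(
                f"remove push {i} [{removed.start_index}, {removed.end_index}]"
            )
        elif action == "add":
            s, e = int(edit["start"]), int(edit["end"])
            if s < 0 or (n_samples is not None and e >= n_samples):
                raise IndexError(f"push [{s}, {e}] outside series bounds")
            pushes.append(Push(s, e, side=side))
            pushes.sort(key=lambda p: p.start_index)
            log.append(f"add push [{s}, {e}]")
        elif action == "adjust":
            i = int(edit["push"])
            if not (0 <= i < len(pushes)):
                raise IndexError(f"no push {i} to adjust")
            old = pushes[i]
            s = int(edit.get("start", old.start_index))
            e = int(edit.get("end", old.end_index))
            if n_samples is not None and (s < 0 or e >= n_samples):
                raise IndexError(f"push [{s}, {e}] outside series bounds")
            pushes[i] = replace(old, start_index=s, end_index=e)
            log.append(
                f"adjust push {i} [{old.start_index}, {old.end_index}] "
                f"-> [{s}, {e}]"
            )
        else:
            raise ValueError(f"unknown edit action {action!r}")
        _check_disjoint_ordered(pushes)

    edited = PushSet(pushes=pushes, n_detected=len(pushes), audit_log=log)
    return exclude_transitional(edited)
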