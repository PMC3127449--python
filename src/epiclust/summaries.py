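"""Scalar and distributional summaries of epidemics and transmission trees.

Curve summaries are derived from the epidemic curve -- the number of
currently infected individuals (exposed plus infectious, by default) as a
function of time: final size, epidemic length (first infection to last
recovery), peak prevalence and peak time.  Prevalence is piecewise constant
and changes only at events, so the peak is computed exactly from the event
times rather than on a sampled grid; the daily grid is for output only.

Tree summaries collect the branch-length means, the secondary-infection and
infective-descendant distributions, and the cherry ratio (cherries over the
maximum possible ``floor(leaves / 2)`` for the outbreak size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seir import EventLog
from .transtree import (
    TransmissionTree,
    branch_length_summaries,
    count_cherries,
    infective_descendant_counts,
    max_cherries,
    secondary_infection_counts,
)

__all__ = [
    "CurveSummary",
    "TreeSummary",
    "prevalence_curve",
    "summarize_curve",
    "summarize_tree",
]


@dataclass(frozen=True)
class CurveSummary:
    final_size: int
    epidemic_length: float  # days
    peak_prevalence: int
    peak_time: float  # days; earliest time the maximum is attained


@dataclass(frozen=True)
class TreeSummary:
    mean_internal_branch: float  # nan when the tree has a single individual
    mean_external_branch: float
    secondary_counts: dict[int, int]
    descendant_counts: dict[int, int]
    n_cherries: int
    n_leaves: int
    cherry_ratio: float  # nan when max_cherries == 0

    @property
    def mean_secondary(self) -> float:
        return sum(self.secondary_counts.values()) / len(self.secondary_counts)


def _infection_intervals(log: EventLog, include_exposed: bool):
    starts = log.exposure_times() if include_exposed else {
        e.individual: e.time for e in log.events if e.kind == "onset"
    }
    ends = log.recovery_times()
    return starts, ends


def prevalence_curve(
    log: EventLog, step: float = 1.0, include_exposed: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Infected count on a regular time grid from 0 to the last recovery.

    An individual counts at grid time ``t`` when ``start <= t < recovery``,
    where ``start`` is the exposure (default) or, with
    ``include_exposed=False``, the onset of infectiousness.
    """
    if not step > 0:
        raise ValueError(f"step must be positive, got {step}")
    starts, ends = _infection_intervals(log, include_exposed)
    start_times = np.sort(np.fromiter(starts.values(), dtype=float))
    end_times = np.sort(np.fromiter(ends.values(), dtype=float))
    grid = np.arange(math.floor(log.last_recovery / step) + 1) * step
    counts = np.searchsorted(start_times, grid, side="right") - np.searchsorted(
        end_times, grid, side="right"
    )
    return grid, counts.astype(np.int64)


def summarize_curve(log: EventLog, include_exposed: bool = True) -> CurveSummary:
    """Exact curve summaries from the event times.

    The peak is the maximum of the piecewise-constant prevalence; ties are
    resolved to the earliest attaining time.  At a time where one infection
    ends exactly as another starts, the ending individual is no longer
    counted (intervals are closed on the left, open at recovery).
    """
    starts, ends = _infection_intervals(log, include_exposed)
    changes: list[tuple[float, int]] = [(t, +1) for t in starts.values()]
    changes += [(t, -1) for t in ends.values()]
    changes.sort(key=lambda c: (c[0], c[1]))  # -1 sorts before +1 at ties
    level = 0
    peak = 0
    peak_time = 0.0
    for t, delta in changes:
        level += delta
        if level > peak:
            peak = level
            peak_time = t
    index_exposure = log.exposure_times()[log.index_node]
    return CurveSummary(
        final_size=log.final_size,
        epidemic_length=log.last_recovery - index_exposure,
        peak_prevalence=peak,
        peak_time=peak_time,
    )


def summarize_tree(tree: TransmissionTree) -> TreeSummary:
    """Assemble all tree-derived summaries."""
    mean_internal, mean_external = branch_length_summaries(tree)
    cherries = count_cherries(tree)
    possible = max_cherries(tree.n_leaves)
    return TreeSummary(
        mean_internal_branch=mean_internal,
        mean_external_branch=mean_external,
        secondary_counts=secondary_infection_counts(tree),
        descendant_counts=infective_descendant_counts(tree),
        n_cherries=cherries,
        n_leaves=tree.n_leaves,
        cherry_ratio=cherries / possible if possible > 0 else math.nan,
    )
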