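"""Top-k% candidate selection, cross-condition comparison and categorization.

After propagation the highest-ranked k percent of network nodes (floor of
k/100 x N) are the candidate proteins for a condition.  Candidate sets
from different conditions are compared to find shared and
condition-unique proteins (the tabular twin of a Venn diagram), and
candidates are classified against a local protein -> category annotation
table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "PrioritizationResult",
    "CandidateComparison",
    "CategoryProfile",
    "select_top",
    "compare_conditions",
    "categorize",
]


@dataclass
class PrioritizationResult:
    """Ranked candidates for one condition with nested top-k% subsets."""

    condition: str
    ranking: list[tuple[str, float, int]]
    top_sets: dict[float, set[str]] = field(default_factory=dict)

    def top(self, k_percent: float) -> set[str]:
        if k_percent not in self.top_sets:
            self.top_sets[k_percent] = select_top(self.ranking, k_percent)
        return self.top_sets[k_percent]


@dataclass
class CandidateComparison:
    """Shared and per-condition-unique candidates at one k%."""

    conditions: list[str]
    k_percent: float
    shared: set[str]
    unique: dict[str, set[str]]


@dataclass
class CategoryProfile:
    """Candidate counts per annotation category."""

    counts: dict[str, int]
    unannotated: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unannotated


def select_top(
    ranking: list[tuple[str, float, int]],
    k_percent: float,
    exclude: set[str] | None = None,
) -> set[str]:
    """First ``floor(k_percent/100 * N)`` nodes of a deterministic ranking.

    ``exclude`` optionally removes given proteins (e.g. the stimuli) from
    the ranking before selection.  A selection of zero candidates is an
    error: the caller should use a larger k.
    """
    if not ranking:
        raise ValueError("ranking is empty")
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must be in (0, 100]")
    rows = ranking if not exclude else [r for r in ranking if r[0] not in exclude]
    n = math.floor(k_percent / 100.0 * len(rows))
    if n == 0:
        raise ValueError(
            f"top {k_percent}% of {len(rows)} nodes selects no candidate; use a larger k"
        )
    return {node for node, _, _ in rows[:n]}


def compare_conditions(
    results: list[PrioritizationResult], k_percent: float
) -> CandidateComparison:
    """Shared and unique candidates across >= 2 conditions at one k%.

    ``shared`` is the intersection of all top sets; each condition's
    ``unique`` set is its top set minus the union of all the others.
    Every result must already carry a top set for ``k_percent``.
    """
    if len(results) < 2:
        raise ValueError("need at least two prioritization results to compare")
    tops = []
    for r in results:
        if k_percent not in r.top_sets:
            raise ValueError(
                f"condition {r.condition!r} has no top set at k={k_percent}; "
                "compute matching k for every condition"
            )
        tops.append(r.top_sets[k_percent])
    shared = set.intersection(*tops)
    unique = {}
    for i, r in enumerate(results):
        others = set().union(*(t for j, t in enumerate(tops) if j != i))
        unique[r.condition] = tops[i] - others
    return CandidateComparison(
        conditions=[r.condition for r in results],
        k_percent=k_percent,
        shared=shared,
        unique=unique,
    )


def categorize(candidates: set[str], annotation: dict[str, str]) -> CategoryProfile:
    """Count candidates per annotation category.

    The annotation may be partial; candidates without an entry are counted
    as unannotated.  The category vocabulary is whatever the annotation
    table supplies.
    """
    counts: Counter[str] = Counter()
    unannotated = 0
    for c in candidates:
        cat = annotation.get(c)
        if cat is None:
            unannotated += 1
        else:
            counts[cat] += 1
    return CategoryProfile(counts=dict(counts), unannotated=unannotated)
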