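"""Stage-membership Venn partitioning and summary distributions.

Given, for each protein, the set of developmental stages at which it was
identified, the three stage sets are partitioned into the seven disjoint
Venn cells (one triple cell, three pairwise-only cells, three single-only
cells). Per-stage totals, the union and the inclusion-exclusion identity
all follow from the cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "VennPartition",
    "venn_partition",
    "class_distribution",
    "stage_exclusive_counts",
]


@dataclass
class VennPartition:
    """Disjoint cell counts over three stage sets.

    ``cells`` maps a frozenset of stage labels (the exact membership
    pattern) to the number of proteins with that pattern.
    """

    stages: tuple[str, ...]
    cells: dict[frozenset, int]

    def cell(self, *stages: str) -> int:
        """Count of proteins identified at exactly the given stages."""
        return self.cells.get(frozenset(stages), 0)

    def set_total(self, stage: str) -> int:
        """All proteins identified at ``stage`` (any membership pattern)."""
        return sum(n for key, n in self.cells.items() if stage in key)

    @property
    def union(self) -> int:
        return sum(self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in (3, 2, 1):
            for combo in combinations(self.stages, r):
                rows.append({"stages": "&".join(combo),
                             "count": self.cell(*combo)})
        return pd.DataFrame(rows, columns=["stages", "count"])


def venn_partition(membership: dict[str, frozenset | set],
                   stages: tuple[str, ...] | list[str]) -> VennPartition:
    """Partition proteins into the 7 disjoint Venn cells of 3 stage sets.

    ``membership`` maps each protein to the set of stages at which it was
    identified; every protein lands in exactly one cell. A protein with an
    empty stage set, or a stage outside ``stages``, is an error.
    """
    stages = tuple(stages)
    allowed = set(stages)
    cells: dict[frozenset, int] = {}
    for prot, stage_set in membership.items():
        key = frozenset(stage_set)
        if not key:
            raise ValueError(f"protein {prot!r} has an empty stage set")
        if not key <= allowed:
            raise ValueError(
                f"protein {prot!r} has stages outside {stages}: "
                f"{sorted(key - allowed)}")
        cells[key] = cells.get(key, 0) + 1
    return VennPartition(stages=stages, cells=cells)


def stage_exclusive_counts(partition: VennPartition) -> tuple[int, int]:
    """(single-stage total, two-stage total) over the partition cells."""
    single = sum(partition.cell(s) for s in partition.stages)
    double = sum(partition.cell(a, b)
                 for a, b in combinations(partition.stages, 2))
    return single, double


def class_distribution(classes: pd.Series | dict,
                       decimals: int = 0) -> pd.DataFrame:
    """Counts and percentages of proteins per functional class.

    ``classes`` maps accession -> functional class. Percentages are of the
    total protein count, rounded to the nearest integer by default or to
    ``decimals`` decimal places on request. Classes are ordered by
    decreasing count (ties alphabetically).
    """
    s = pd.Series(classes, dtype=object)
    counts = s.value_counts().sort_index().sort_values(
        ascending=False, kind="mergesort")
    total = int(counts.sum())
    pct = (100.0 * counts / total).round(decimals) if total else counts * 0.0
    if decimals == 0:
        pct = pct.astype(int)
    return pd.DataFrame({"class": counts.index, "count": counts.to_numpy(),
                         "percent": pct.to_numpy()})


def share_percent(part: int, whole: int, decimals: int = 1) -> float:
    """Percentage of ``part`` in ``whole`` at the requested precision."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, decimals)
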