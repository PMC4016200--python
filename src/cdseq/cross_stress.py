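"""Cross-stress comparison of responsive gene sets.

Responsive sets from different treatments (Cd, drought, salt, cold — from
any platform, keyed by a shared gene id) are defined by inclusive
fold-change thresholds (up: FC >= 2, down: FC <= 0.5) and compared by
n-way Venn partitioning and overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class ResponsiveSet:
    """Up- and down-responsive gene ids for one treatment/tissue."""

    treatment: str
    tissue: str
    up: frozenset[str] = field(default_factory=frozenset)
    down: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-responsive")

    def direction(self, which: str) -> frozenset[str]:
        if which not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        return self.up if which == "up" else self.down


def threshold_responsive(
    fold_changes: Mapping[str, float],
    treatment: str,
    tissue: str,
    up_cut: float = 2.0,
    down_cut: float = 0.5,
) -> ResponsiveSet:
    """Partition genes into up (FC >= up_cut) / down (FC <= down_cut)."""
    if up_cut <= down_cut:
        raise ValueError("up_cut must exceed down_cut")
    bad = [g for g, fc in fold_changes.items() if fc <= 0]
    if bad:
        raise ValueError(f"fold changes must be positive, offending ids: {bad[:3]}")
    up = frozenset(g for g, fc in fold_changes.items() if fc >= up_cut)
    down = frozenset(g for g, fc in fold_changes.items() if fc <= down_cut)
    return ResponsiveSet(treatment=treatment, tissue=tissue, up=up, down=down)


def venn_partition(
    sets: Sequence[ResponsiveSet], direction: str
) -> dict[frozenset[str], int]:
    """Exclusive Venn region sizes for 2-4 responsive sets.

    Returns a mapping from each non-empty combination of treatment labels
    (2^n - 1 regions) to the number of ids belonging to exactly those
    treatments; region counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("Venn partitioning supports 2 to 4 sets")
    labels = [s.treatment for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("treatment labels must be unique")
    members = {s.treatment: s.direction(direction) for s in sets}
    regions = {
        frozenset(combo): 0
        for r in range(1, len(labels) + 1)
        for combo in combinations(labels, r)
    }
    for gene in set().union(*members.values()):
        region = frozenset(l for l in labels if gene in members[l])
        regions[region] += 1
    return regions


def overlap_fraction(
    reference: Iterable[str], others: Sequence[Iterable[str]]
) -> tuple[float, float]:
    """Percentage of the reference set shared with other stresses.

    Returns (any, common): the one-decimal percentages of reference ids
    found in the union, respectively the intersection, of the other sets.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference set is empty; fractions undefined")
    if not others:
        raise ValueError("need at least one comparison set")
    other_sets = [set(o) for o in others]
    union = set().union(*other_sets)
    common = set.intersection(*other_sets)
    any_pct = round(100.0 * len(ref & union) / len(ref), 1)
    common_pct = round(100.0 * len(ref & common) / len(ref), 1)
    return any_pct, common_pct
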