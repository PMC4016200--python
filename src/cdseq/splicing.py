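"""Alternative-splicing pattern changes from splice-site read counts.

A splice site is "active" in a condition when its RPM (reads per million
mapped reads) strictly exceeds 1. The splicing pattern of a locus in a
condition is its set of active sites; a locus shows a pattern change
between two conditions when those sets differ. A locus is AS-capable when
it has at least two active sites in either condition (evidence for more
than one isoform).
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .models import SpliceSiteTable

ACTIVE_RPM_THRESHOLD = 1.0


def site_rpm(count: Union[int, float, np.ndarray], n_total: Union[int, float]) -> Union[float, np.ndarray]:
    """Reads per million mapped reads: 1e6 * count / n_total."""
    if n_total <= 0:
        raise ValueError("total mapped reads must be positive")
    out = 1e6 * np.asarray(count, dtype=float) / float(n_total)
    return float(out) if out.ndim == 0 else out


def active_sites(table: SpliceSiteTable, condition: str) -> set[int]:
    """Coordinates whose RPM strictly exceeds 1 in ``condition``."""
    if condition not in table.libsizes:
        raise KeyError(f"condition {condition!r} not in table for {table.locus_id}")
    n = table.libsizes[condition]
    return {
        coord
        for coord, counts in table.sites.items()
        if site_rpm(counts.get(condition, 0), n) > ACTIVE_RPM_THRESHOLD
    }


def detect_pattern_changes(
    tables: Sequence[SpliceSiteTable],
    cond_a: str,
    cond_b: str,
    total_loci: int | None = None,
) -> tuple[set[str], dict]:
    """Loci whose active-site sets differ between two conditions.

    The summary reports, over ``total_loci`` (defaults to the number of
    tables supplied), the count and one-decimal percentage of AS-capable
    loci and of pattern-changed loci. Symmetric in (cond_a, cond_b).
    """
    changed: set[str] = set()
    as_capable = 0
    for table in tables:
        sa = active_sites(table, cond_a)
        sb = active_sites(table, cond_b)
        if len(sa) >= 2 or len(sb) >= 2:
            as_capable += 1
        if sa != sb:
            changed.add(table.locus_id)
    denom = len(tables) if total_loci is None else total_loci
    return changed, pattern_summary(as_capable, len(changed), denom)


def pattern_summary(n_as_capable: int, n_changed: int, n_loci: int) -> dict:
    """Counts and one-decimal percentages of AS-capable and
    pattern-changed loci over the representative-locus denominator."""
    if n_loci <= 0:
        raise ValueError("denominator locus count must be positive")
    return {
        "n_loci": n_loci,
        "as_capable": n_as_capable,
        "as_capable_pct": round(100.0 * n_as_capable / n_loci, 1),
        "changed": n_changed,
        "changed_pct": round(100.0 * n_changed / n_loci, 1),
    }
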