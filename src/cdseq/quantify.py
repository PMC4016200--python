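"""Expression quantification: RPKM, replicate QC and replicate merging.

RPKM (reads per kilobase of exon model per million mapped reads) for a
transcript with C uniquely mapped reads, exonic length L nucleotides, in a
library of N total mapped reads is

    RPKM = 1e9 * C / (N * L)

A transcript is "detected" when RPKM > 0, i.e. when at least one read
mapped to it. Replicates of the same tissue/condition are checked for
correlation and then merged by summing raw counts (pooling reads), not by
averaging expression values.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .models import CountLibrary, TranscriptModel

log = logging.getLogger(__name__)

#: Replicates correlating below this on log2(RPKM+1) trigger a QC warning.
CORRELATION_QC_THRESHOLD = 0.92

ArrayLike = Union[float, int, np.ndarray]


def compute_rpkm(count: ArrayLike, length: ArrayLike, n_total: ArrayLike) -> ArrayLike:
    """RPKM of ``count`` reads on a transcript of exonic ``length`` nt in a
    library of ``n_total`` mapped reads. Accepts scalars or arrays."""
    length = np.asarray(length, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    count = np.asarray(count, dtype=float)
    if np.any(length <= 0):
        raise ValueError("exonic length must be positive")
    if np.any(n_total <= 0):
        raise ValueError("total mapped reads must be positive")
    if np.any(count < 0):
        raise ValueError("read count must be non-negative")
    out = 1e9 * count / (n_total * length)
    return float(out) if out.ndim == 0 else out


def rpkm_matrix(
    libraries: Sequence[CountLibrary], models: Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Transcript x library RPKM matrix (columns labelled tissue_condition[_rep]).

    Transcripts absent from a library's count map are zero-count.
    """
    ids = [m.transcript_id for m in models]
    lengths = np.array([m.length for m in models], dtype=float)
    data = {}
    for lib in libraries:
        counts = np.array([lib.get(t) for t in ids], dtype=float)
        data[lib.label] = compute_rpkm(counts, lengths, lib.n_total)
    return pd.DataFrame(data, index=pd.Index(ids, name="transcript_id"))


def detected(rpkm: pd.DataFrame) -> pd.DataFrame:
    """Boolean detection mask: RPKM strictly positive."""
    return rpkm > 0


def replicate_correlation(
    a: CountLibrary, b: CountLibrary, models: Sequence[TranscriptModel]
) -> float:
    """Pearson correlation of log2(RPKM+1) between two replicate libraries.

    Warns (but does not fail) when the coefficient falls below the QC
    threshold used to admit replicates for merging.
    """
    if (a.tissue, a.condition) != (b.tissue, b.condition):
        raise ValueError("replicate correlation requires matching tissue/condition")
    if len(models) < 3:
        raise ValueError("need at least 3 shared transcripts")
    ids = [m.transcript_id for m in models]
    lengths = np.array([m.length for m in models], dtype=float)
    x = np.log2(compute_rpkm(np.array([a.get(t) for t in ids]), lengths, a.n_total) + 1.0)
    y = np.log2(compute_rpkm(np.array([b.get(t) for t in ids]), lengths, b.n_total) + 1.0)
    r = float(np.corrcoef(x, y)[0, 1])
    if r < CORRELATION_QC_THRESHOLD:
        log.warning(
            "replicates %s / %s correlate at %.3f (< %.2f)",
            a.label, b.label, r, CORRELATION_QC_THRESHOLD,
        )
    return r


def merge_replicates(libraries: Iterable[CountLibrary]) -> CountLibrary:
    """Pool replicate libraries by summing counts and total mapped reads.

    Pooling reads is not the same as averaging per-replicate RPKMs: the
    merged RPKM is the count-weighted value 1e9 * sum(C_i) / (sum(N_i) * L).
    """
    libs = list(libraries)
    if not libs:
        raise ValueError("no libraries to merge")
    key = (libs[0].tissue, libs[0].condition)
    if any((l.tissue, l.condition) != key for l in libs):
        raise ValueError("cannot merge libraries from different tissue/condition")
    if len(libs) == 1:
        return libs[0].without_replicate()
    counts: dict[str, int] = {}
    for lib in libs:
        for t, c in lib.counts.items():
            counts[t] = counts.get(t, 0) + c
    return CountLibrary(
        tissue=key[0],
        condition=key[1],
        counts=counts,
        n_total=sum(l.n_total for l in libs),
        replicate=None,
    )


def merge_by_condition(
    libraries: Sequence[CountLibrary],
) -> dict[tuple[str, str], CountLibrary]:
    """Group libraries by (tissue, condition) and merge each group."""
    groups: dict[tuple[str, str], list[CountLibrary]] = {}
    for lib in libraries:
        groups.setdefault((lib.tissue, lib.condition), []).append(lib)
    return {key: merge_replicates(libs) for key, libs in sorted(groups.items())}
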