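"""Core data containers shared by the pipeline stages.

The experimental design mirrors a bulk RNA-Seq time course: two tissues
(root, shoot) sampled at 0 h (control), 1 h and 24 h after 50 uM Cd
exposure, with 2-3 biological replicates per condition that are merged
after a correlation check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

TISSUES = ("root", "shoot")
CONDITIONS = ("0h", "1h", "24h")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: identity, parent locus, exonic length and annotation.

    ``length`` is the exon-model length in nucleotides (union of exon
    intervals), the L in RPKM.
    """

    transcript_id: str
    locus_id: str
    length: int
    go_terms: frozenset[str] = field(default_factory=frozenset)
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"exonic length must be >= 1, got {self.length}")


@dataclass
class CountLibrary:
    """One sequenced library: uniquely-mapped read counts per transcript.

    ``n_total`` is the library's total number of uniquely mapped reads
    (the M in RPKM / RPM); it may exceed the sum of per-transcript counts
    because reads mapping outside annotated exons still count as mapped.
    """

    tissue: str
    condition: str
    counts: dict[str, int]
    n_total: int
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("total mapped reads must be positive")
        neg = [t for t, c in self.counts.items() if c < 0]
        if neg:
            raise ValueError(f"negative counts for {neg[:3]}")
        if self.counts and self.n_total < max(self.counts.values()):
            raise ValueError("n_total smaller than a single transcript count")

    @property
    def label(self) -> str:
        rep = f"_r{self.replicate}" if self.replicate is not None else ""
        return f"{self.tissue}_{self.condition}{rep}"

    def get(self, transcript_id: str) -> int:
        """Count for a transcript; absent transcripts are zero-count."""
        return self.counts.get(transcript_id, 0)

    def without_replicate(self) -> "CountLibrary":
        return replace(self, replicate=None)


@dataclass(frozen=True)
class Contrast:
    """A baseline-vs-treatment comparison within one tissue."""

    tissue: str
    baseline: str
    treatment: str

    def __post_init__(self) -> None:
        if self.baseline == self.treatment:
            raise ValueError("baseline and treatment must differ")

    @property
    def label(self) -> str:
        return f"{self.tissue}_{self.treatment}_vs_{self.baseline}"


def default_contrasts() -> list[Contrast]:
    """The four tissue/timepoint contrasts of the Cd time course."""
    return [
        Contrast(tissue, "0h", trt) for tissue in TISSUES for trt in ("1h", "24h")
    ]


@dataclass
class SpliceSiteTable:
    """Splice-site read counts for one representative locus.

    ``sites`` maps a 1-based genomic coordinate to per-condition read
    counts; ``libsizes`` holds the total mapped reads per condition used
    for RPM normalisation.
    """

    locus_id: str
    sites: dict[int, dict[str, int]]
    libsizes: Mapping[str, int]

    def conditions(self) -> set[str]:
        return set(self.libsizes)


@dataclass
class TreatmentProfile:
    """Relative expression of one transcript across the metal-ion panel.

    Values are 2^-ddCt ratios relative to the water control (control == 1
    by construction), keyed by (treatment, tissue).
    """

    transcript_id: str
    rel_expr: dict[tuple[str, str], float]
    group: Optional[object] = None
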