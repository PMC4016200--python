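"""Synthetic data with known ground truth, emulating the Cd time course.

The generator mimics the study design — 2 tissues x {0 h, 1 h, 24 h} x
2-3 replicates — at desk scale. Per-transcript read counts are negative
binomial around a mean proportional to library size x transcript
abundance x planted fold change; baseline abundances are log-normal so
RPKM spans several orders of magnitude as in real libraries. Planted
effects (differentially expressed transcripts, enriched GO terms,
splice-pattern changes, qPCR response groups) are recorded as ground
truth for recovery testing.

All randomness flows from ``SimulationConfig.seed`` through independent
named substreams, so the same config yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .family_panel import GENERAL_QUORUM, PANEL_TREATMENTS
from .models import (
    CONDITIONS,
    TISSUES,
    Contrast,
    CountLibrary,
    SpliceSiteTable,
    TranscriptModel,
    default_contrasts,
)

_TREATED_CONDITIONS = ("1h", "24h")
# substream tags: structure, count noise, GO annotation, splicing, qPCR
_S_STRUCT, _S_NOISE, _S_GO, _S_SPLICE, _S_QPCR = 1, 2, 3, 4, 5


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic Cd-stress experiment.

    Defaults are desk-scale stand-ins for the study design: ~2 M mapped
    reads per library (the real libraries are ~48 M), 2 biological
    replicates, a 10% planted-DE fraction with log2 fold changes around
    2.5, and mild negative-binomial overdispersion (0.05) typical of
    biological replicates.
    """

    n_transcripts: int = 2000
    exon_length_range: tuple[int, int] = (200, 5000)
    library_size_mean: int = 2_000_000
    n_replicates: int = 2
    de_fraction: float = 0.1
    log2fc_distribution: tuple[float, float] = (2.5, 0.5)
    dispersion: float = 0.05
    n_go_terms: int = 50
    go_base_rate: float = 0.05
    enriched_terms: tuple[tuple[str, tuple[str, str, str], float], ...] = ()
    n_splice_loci: int = 200
    splice_sites_per_locus: tuple[int, int] = (2, 6)
    pattern_change_fraction: float = 0.1
    qpcr_group_sizes: tuple[int, int, int, int] = (3, 3, 2, 4)
    qpcr_up_fold: float = 4.0
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if not (1 <= self.exon_length_range[0] <= self.exon_length_range[1]):
            raise ValueError("exon_length_range must be increasing and positive")
        for name in ("de_fraction", "pattern_change_fraction", "go_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_splice_loci < 0 or self.n_go_terms < 0:
            raise ValueError("counts must be non-negative")
        if self.splice_sites_per_locus[0] < 1:
            raise ValueError("loci need at least one splice site")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted effects: what a perfect analysis should recover."""

    de_transcripts: frozenset[tuple[str, Contrast, float]] = frozenset()
    enriched_terms: frozenset[tuple[str, tuple[str, str, str]]] = frozenset()
    changed_loci: frozenset[str] = frozenset()
    group_labels: dict[str, int] = field(default_factory=dict)

    def de_ids(self, contrast: Optional[Contrast] = None) -> set[str]:
        return {
            t for (t, c, _) in self.de_transcripts if contrast is None or c == contrast
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _transcript_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"T{i:0{width}d}" for i in range(1, n + 1)]


def _structure(config: SimulationConfig):
    """Transcript lengths, abundances and planted effects (one substream)."""
    rng = _rng(config, _S_STRUCT)
    n = config.n_transcripts
    lo, hi = config.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n)  # per-nt rate
    weights = abundance * lengths

    n_de = _round_half_up(config.de_fraction * n)
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    mu, sd = config.log2fc_distribution
    magnitude = np.abs(rng.normal(mu, sd, size=n_de))
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(n)
    log2fc[de_idx] = sign * magnitude
    return lengths, weights, de_idx, log2fc


def expected_mean_counts(config: SimulationConfig) -> pd.DataFrame:
    """Expected count per transcript and condition under the config.

    Columns are the six tissue/condition combinations; treated conditions
    share the planted fold changes. Means are renormalised so each
    library's expected total equals ``library_size_mean`` (planting an
    effect reshuffles the read share of every transcript, as in real
    compositional sequencing data).
    """
    lengths, weights, _, log2fc = _structure(config)
    ids = _transcript_ids(config.n_transcripts)
    out = {}
    for tissue in TISSUES:
        for cond in CONDITIONS:
            w = weights * np.where(
                cond in _TREATED_CONDITIONS, 2.0 ** log2fc, 1.0
            )
            out[f"{tissue}_{cond}"] = config.library_size_mean * w / w.sum()
    return pd.DataFrame(out, index=pd.Index(ids, name="transcript_id"))


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) counts; dispersion 0 degenerates to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[list[CountLibrary], list[TranscriptModel], GroundTruth]:
    """Count libraries + transcript models + planted truth.

    Planted log2 fold changes apply at both treated timepoints in both
    tissues, so the truth lists every (transcript, contrast, log2FC)
    triple across the four tissue/timepoint contrasts.
    """
    lengths, weights, de_idx, log2fc = _structure(config)
    ids = _transcript_ids(config.n_transcripts)
    means = expected_mean_counts(config)

    noise = _rng(config, _S_NOISE)
    libraries: list[CountLibrary] = []
    for tissue in TISSUES:
        for cond in CONDITIONS:
            m = means[f"{tissue}_{cond}"].to_numpy()
            for rep in range(1, config.n_replicates + 1):
                counts = _draw_counts(noise, m, config.dispersion)
                libraries.append(
                    CountLibrary(
                        tissue=tissue,
                        condition=cond,
                        counts=dict(zip(ids, (int(c) for c in counts))),
                        n_total=max(int(counts.sum()), 1),
                        replicate=rep,
                    )
                )

    go_terms = _simulate_go_annotation(config, de_idx, log2fc)
    models = [
        TranscriptModel(
            transcript_id=ids[i],
            locus_id=f"L{ids[i][1:]}",
            length=int(lengths[i]),
            go_terms=frozenset(go_terms[i]),
        )
        for i in range(config.n_transcripts)
    ]

    de_truth = {
        (ids[i], contrast, float(log2fc[i]))
        for i in de_idx
        for contrast in default_contrasts()
    }
    truth = GroundTruth(
        de_transcripts=frozenset(de_truth),
        enriched_terms=frozenset(
            (term, cluster) for term, cluster, _ in config.enriched_terms
        ),
    )
    return libraries, models, truth


def _simulate_go_annotation(
    config: SimulationConfig, de_idx: np.ndarray, log2fc: np.ndarray
) -> list[set[str]]:
    """Per-transcript GO term sets with planted over-representation.

    Every term annotates transcripts at the base rate; for a planted
    (term, cluster, odds) triple, transcripts in the cluster (up- or
    down-regulated planted DE set of the named tissue/timepoint) are
    annotated at the rate whose odds are ``odds`` times the base odds.
    """
    rng = _rng(config, _S_GO)
    n = config.n_transcripts
    p0 = config.go_base_rate
    terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    annot: list[set[str]] = [set() for _ in range(n)]
    planted = {term: (cluster, odds) for term, cluster, odds in config.enriched_terms}
    up_idx = set(int(i) for i in de_idx if log2fc[i] > 0)
    down_idx = set(int(i) for i in de_idx if log2fc[i] < 0)
    for term in terms:
        prob = np.full(n, p0)
        if term in planted:
            (direction, _tissue, _cond), odds = planted[term]
            members = up_idx if direction == "up" else down_idx
            base_odds = p0 / (1 - p0)
            p1 = odds * base_odds / (1 + odds * base_odds)
            prob[list(members)] = p1
        hits = rng.random(n) < prob
        for i in np.flatnonzero(hits):
            annot[i].add(term)
    return annot


def simulate_splice_tables(
    config: SimulationConfig, conditions: tuple[str, str] = ("control", "cd")
) -> tuple[list[SpliceSiteTable], GroundTruth]:
    """Splice-site count tables with planted pattern changes.

    Active sites are drawn with RPM in (1.5, 50), inactive sites with RPM
    in [0, 0.5), so the RPM > 1 activity rule is unambiguous. For each
    planted changed locus the activity of one site is toggled in the
    second condition; all other loci keep identical active-site sets
    (counts still vary between conditions).
    """
    rng = _rng(config, _S_SPLICE)
    cond_a, cond_b = conditions
    n_loci = config.n_splice_loci
    n_changed = _round_half_up(config.pattern_change_fraction * n_loci)
    changed_pick = set(rng.choice(n_loci, size=n_changed, replace=False).tolist())
    libsizes = {cond_a: config.library_size_mean, cond_b: config.library_size_mean}
    smin, smax = config.splice_sites_per_locus

    def draw_count(active: bool) -> int:
        n = config.library_size_mean
        if active:
            return max(int(math.ceil(rng.uniform(1.5, 50.0) * n / 1e6)), 2)
        return int(math.floor(rng.uniform(0.0, 0.5) * n / 1e6))

    tables: list[SpliceSiteTable] = []
    changed_ids: set[str] = set()
    width = max(4, len(str(n_loci)))
    for li in range(n_loci):
        locus_id = f"SL{li + 1:0{width}d}"
        k = int(rng.integers(smin, smax + 1))
        coords = sorted(int(c) + 1 for c in rng.choice(200_000, size=k, replace=False))
        n_active = int(rng.integers(min(2, k), k + 1))
        active_a = set(rng.choice(coords, size=n_active, replace=False).tolist())
        active_b = set(active_a)
        if li in changed_pick:
            toggle = int(rng.choice(coords))
            active_b.symmetric_difference_update({toggle})
            changed_ids.add(locus_id)
        sites = {
            coord: {
                cond_a: draw_count(coord in active_a),
                cond_b: draw_count(coord in active_b),
            }
            for coord in coords
        }
        tables.append(SpliceSiteTable(locus_id=locus_id, sites=sites, libsizes=libsizes))
    return tables, GroundTruth(changed_loci=frozenset(changed_ids))


def simulate_qpcr_panel(
    config: SimulationConfig, reference_gene: str = "Ubiquitin1"
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format Ct table for the 12-medium panel with planted groups.

    Each target gene is planted into one of the four response groups by
    choosing the set of treatments under which it is upregulated
    (``qpcr_up_fold``-fold): group 1 Cd only; group 2 Cd plus 1-3
    others; group 3 1-3 others without Cd; group 4 a general-stress
    quorum of treatments. Three technical replicates per measurement with
    Gaussian Ct noise of sd ``ct_noise_sd``.
    """
    rng = _rng(config, _S_QPCR)
    others = [t for t in PANEL_TREATMENTS if t != "Cd"]
    group_of: dict[str, int] = {}
    up_sets: dict[str, set[str]] = {}
    gene_no = 0
    for group, size in zip((1, 2, 3, 4), config.qpcr_group_sizes):
        for _ in range(size):
            gene_no += 1
            gene = f"Q{gene_no:02d}"
            if group == 1:
                up = {"Cd"}
            elif group == 2:
                extra = rng.choice(others, size=int(rng.integers(1, 4)), replace=False)
                up = {"Cd", *extra.tolist()}
            elif group == 3:
                up = set(
                    rng.choice(others, size=int(rng.integers(1, 4)), replace=False).tolist()
                )
            else:
                size4 = int(rng.integers(GENERAL_QUORUM, len(PANEL_TREATMENTS) + 1))
                up = set(rng.choice(PANEL_TREATMENTS, size=size4, replace=False).tolist())
            group_of[gene] = group
            up_sets[gene] = up

    treatments = list(PANEL_TREATMENTS) + ["control"]
    rows = []
    for gene in list(group_of) + [reference_gene]:
        for tissue in TISSUES:
            base_ct = 20.0 if gene == reference_gene else float(rng.uniform(22.0, 28.0))
            for trt in treatments:
                if gene == reference_gene or trt == "control":
                    true_ct = base_ct
                else:
                    rel = config.qpcr_up_fold if trt in up_sets[gene] else 1.0
                    true_ct = base_ct - math.log2(rel)
                for rep in (1, 2, 3):
                    noise = float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "treatment": trt,
                            "tissue": tissue,
                            "replicate": rep,
                            "ct": true_ct + noise,
                        }
                    )
    ct_table = pd.DataFrame(rows)
    return ct_table, GroundTruth(group_labels=group_of)
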