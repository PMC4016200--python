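# cdseq

Analysis pipeline for the early transcriptional response of rice
(*Oryza sativa* cv. Nipponbare) to cadmium stress, built around bulk
RNA-Seq read counts from roots and shoots sampled at 0 h, 1 h and 24 h
after 50 µM Cd exposure. The package reimplements the study's complete
downstream analysis as a tested library with a synthetic-data generator,
so every statistical step can be validated against planted ground truth
before being applied to real count tables.

## What it computes

**Expression.** Per-transcript expression as RPKM (reads per kilobase of
exon model per million uniquely mapped reads),

    RPKM = 10^9 · C / (N · L)

with C the transcript's uniquely mapped reads, L its exonic length
(union of exon intervals from a GTF) and N the library's total mapped
reads. Replicates are admitted by a Pearson-correlation QC on
log2(RPKM+1) (threshold 0.92) and merged by pooling reads.

**Differential expression.** For each tissue/timepoint contrast a 2×2
contingency table — (reads on the transcript, all other mapped reads) ×
(control, treated) — is tested with the likelihood-ratio G-test,

    G = 2 Σ O ln(O/E),   G ~ χ²(1 df),

Benjamini–Hochberg adjusted within the contrast; a transcript is
*responsive* at q < 0.01. Fold changes are pseudocounted RPKM ratios
(x+1)/(y+1).

**GO enrichment.** One-tailed Fisher exact (hypergeometric upper-tail)
tests per GO term within each responsive cluster, BH-FDR at 5%, with a
−log10(q) term × cluster heatmap matrix.

**Alternative splicing.** A locus's splicing pattern in a condition is
its set of splice sites with RPM = 10⁶·count/N strictly above 1; a
pattern change is a difference in those sets between control and Cd.

**Cross-stress comparison.** Responsive sets (fold change ≥ 2 or
≤ 0.5) from different treatments are Venn-partitioned (2–4 way) and
summarised as overlap percentages.

**Transporter families.** Pfam-domain-based family assignment (HMA,
MatE, Zip, Cation_efflux, Nramp, PDR_assoc, LCT1), family composition
percentages, the >5-fold reporting filter, qPCR relative expression by
2^−ΔΔCt (Ubiquitin1 reference, water control) and a four-group
classifier of response patterns across a 12-medium metal-ion panel.

## Worked example

```python
from cdseq import (SimulationConfig, simulate_counts, default_contrasts,
                   call_responsive)
from cdseq.quantify import merge_by_condition

cfg = SimulationConfig(n_transcripts=2000, de_fraction=0.1,
                       log2fc_distribution=(3.0, 0.0), dispersion=0.0, seed=11)
libraries, models, truth = simulate_counts(cfg)
results = call_responsive(merge_by_condition(libraries), models,
                          default_contrasts())
contrast = default_contrasts()[0]          # root, 1 h vs 0 h
table = results[contrast]
planted = truth.de_ids(contrast)
called = set(table.index[table.responsive])
print(len(planted & called) / len(planted))
```

prints `1.0`: every one of the 200 planted 8-fold effects is recovered
at FDR < 0.01 at this depth (~2 M reads/library). On matched null data
(`de_fraction=0`) the same caller flags essentially nothing
(mean responsive fraction 5 × 10⁻⁶ over 10 seeds × 4 contrasts).

The numbered scripts under `analysis/` run the full narrative on a
simulated time course — `python analysis/01_simulate.py` through
`07_transporter_families.py` — writing tables under `results/`. The
`cdseq` console command exposes the same stages
(`cdseq simulate|quantify|de|enrich|splice|venn|families|all`).

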