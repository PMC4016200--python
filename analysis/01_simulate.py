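#!/usr/bin/env python
"""Generate the synthetic Cd-exposure dataset used by the later steps.

Emulates the study design (root + shoot at 0 h / 1 h / 24 h, two
replicates each) at desk scale and writes count tables, transcript
models, GO annotation, splice-site tables, the qPCR Ct panel and every
planted ground truth under results/data/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cdseq import io as cio
from cdseq.synthetic import (
    SimulationConfig,
    simulate_counts,
    simulate_qpcr_panel,
    simulate_splice_tables,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = SimulationConfig(
    n_transcripts=3000,
    n_splice_loci=300,
    enriched_terms=(
        ("GO:0000001", ("up", "root", "24h"), 10.0),
        ("GO:0000002", ("down", "root", "24h"), 8.0),
    ),
    seed=args.seed,
)
args.out.mkdir(parents=True, exist_ok=True)

libraries, models, truth = simulate_counts(cfg)
cio.write_count_table(libraries, args.out / "counts.tsv")
cio.write_gtf(models, args.out / "models.gtf")
cio.write_go_annotation(models, args.out / "go.tsv")

tables, splice_truth = simulate_splice_tables(cfg)
cio.write_splice_tables(tables, args.out / "splice.tsv")

ct, qpcr_truth = simulate_qpcr_panel(cfg)
cio.write_tsv(ct, args.out / "ct.tsv", index=False)

de_rows = sorted(
    ({"transcript_id": t, "contrast": c.label, "log2fc": f} for t, c, f in truth.de_transcripts),
    key=lambda r: (r["transcript_id"], r["contrast"]),
)
cio.write_tsv(pd.DataFrame(de_rows), args.out / "truth_de.tsv", index=False)
cio.write_tsv(
    pd.DataFrame({"locus_id": sorted(splice_truth.changed_loci)}),
    args.out / "truth_changed_loci.tsv",
    index=False,
)
cio.write_tsv(
    pd.Series(qpcr_truth.group_labels, name="group").rename_axis("gene").to_frame(),
    args.out / "truth_groups.tsv",
)

print(f"simulated {len(libraries)} libraries x {cfg.n_transcripts} transcripts (seed {args.seed})")
print(f"planted DE transcripts: {len(truth.de_ids())}")
print(f"planted splice-pattern changes: {len(splice_truth.changed_loci)} of {cfg.n_splice_loci} loci")
print(f"qPCR panel genes: {len(qpcr_truth.group_labels)} across groups 1-4")
print(f"dataset written to {args.out}/")
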