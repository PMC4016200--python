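#!/usr/bin/env python
"""Call Cd-responsive transcripts per tissue/timepoint contrast.

G-test on mapped/unmapped read contingency tables, BH-FDR within each
contrast at q < 0.01, pseudocounted RPKM fold changes; reports the
up/down counts per contrast and the recall of the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from cdseq import io as cio
from cdseq.diffexpr import call_responsive, rank_top_upregulated, responsive_summary
from cdseq.models import TranscriptModel, default_contrasts
from cdseq.quantify import merge_by_condition

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/diffexpr"))
parser.add_argument("--alpha", type=float, default=0.01)
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

libraries = cio.read_count_table(args.data / "counts.tsv")
lengths = cio.exonic_lengths_from_gtf(args.data / "models.gtf")
models = [TranscriptModel(t, t, lengths[t]) for t in sorted(lengths)]
merged = merge_by_condition(libraries)
contrasts = default_contrasts()

results = call_responsive(merged, models, contrasts, alpha=args.alpha)
for contrast, table in results.items():
    cio.write_tsv(table, args.out / f"de_{contrast.label}.tsv")
summary = responsive_summary(results)
cio.write_tsv(summary, args.out / "responsive_summary.tsv", index=False)
print(summary.to_string(index=False))

truth = pd.read_csv(args.data / "truth_de.tsv", sep="\t")
for contrast in contrasts:
    planted = set(truth.loc[truth["contrast"] == contrast.label, "transcript_id"])
    table = results[contrast]
    called = set(table.index[table["responsive"]])
    recall = len(planted & called) / len(planted) if planted else float("nan")
    print(f"{contrast.label}: recall of planted DE = {recall:.3f}")

top = rank_top_upregulated(results[contrasts[1]].reset_index(), k=20)
cio.write_tsv(top, args.out / "top20_up_root_24h.tsv", index=False)
print(f"strongest root-24h upregulation: {top['transcript_id'].iloc[0]} "
      f"(fold change {top['fold_change'].iloc[0]:.2f})")
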