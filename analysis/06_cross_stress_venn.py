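#!/usr/bin/env python
"""Cross-condition comparison of responsive sets by Venn partitioning.

Thresholds the per-contrast fold changes (up >= 2, down <= 0.5), Venn-
partitions the four tissue/timepoint responsive sets and reports overlap
fractions of the root-24h set with the others (the cross-talk statistic).
"""

import argparse
from pathlib import Path

import pandas as pd

from cdseq import io as cio
from cdseq.cross_stress import overlap_fraction, threshold_responsive, venn_partition

parser = argparse.ArgumentParser()
parser.add_argument("--de", type=Path, default=Path("results/diffexpr"))
parser.add_argument("--out", type=Path, default=Path("results/cross_stress"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

labels = ["root_1h_vs_0h", "root_24h_vs_0h", "shoot_1h_vs_0h", "shoot_24h_vs_0h"]
sets = []
for label in labels:
    df = pd.read_csv(args.de / f"de_{label}.tsv", sep="\t")
    fc = dict(zip(df["transcript_id"], df["fold_change"]))
    sets.append(threshold_responsive(fc, treatment=label, tissue=label.split("_")[0]))

for direction in ("up", "down"):
    regions = venn_partition(sets, direction)
    out = pd.DataFrame(
        [
            {"region": "&".join(sorted(k)), "count": v}
            for k, v in sorted(regions.items(), key=lambda kv: sorted(kv[0]))
        ]
    )
    cio.write_tsv(out, args.out / f"venn_{direction}.tsv", index=False)
    union = sum(regions.values())
    core = regions[frozenset(labels)]
    print(f"{direction}: union {union} ids, all-four core {core}")

reference = sets[1]  # root 24 h
others = [s.up for s in sets if s.treatment != reference.treatment]
any_pct, common_pct = overlap_fraction(reference.up, others)
print(
    f"root-24h upregulated set: {any_pct}% shared with >=1 other contrast, "
    f"{common_pct}% common to all"
)
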