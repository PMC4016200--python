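"""Published summary tables from the rice Cd-exposure RNA-Seq study.

These are desk-scale inputs: the raw reads behind them are archive-scale
and out of scope, but the printed fold-change tables and summary counts
are sufficient to exercise the ranking, filtering and reporting-arithmetic
operations of the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Representative loci on the IRGSP-1.0 rice genome assembly.
N_REPRESENTATIVE_LOCI = 44_519
#: Representative loci with confirmed alternative-splicing isoforms.
N_AS_LOCI = 5_222
#: Loci whose splice-site usage pattern changed under Cd exposure.
N_PATTERN_CHANGED_LOCI = 2_873

#: Cd-responsive metal-transporter transcripts per Pfam-defined family
#: (LCT1 including its BLASTP-identified homologues).
FAMILY_RESPONSIVE_COUNTS = {
    "HMA": 60,
    "MatE": 50,
    "Zip": 18,
    "Cation_efflux": 13,
    "Nramp": 13,
    "PDR_assoc": 10,
    "LCT1": 4,
}

#: Pfam accession -> transporter family, in the published priority order
#: used when a transcript carries more than one metal-binding domain.
PFAM_FAMILIES = {
    "PF01554": "MatE",
    "PF08370": "PDR_assoc",
    "PF01545": "Cation_efflux",
    "PF02535": "Zip",
    "PF00403": "HMA",
    "PF01566": "Nramp",
}

TABLE2_FC_COLUMNS = ["root_1h", "root_24h", "shoot_1h", "shoot_24h"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("cdseq.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_top20_novel_upregulated() -> pd.DataFrame:
    """Top-20 Cd-upregulated root transcripts (24 h) absent from the
    44K microarray platform: transcript_id, description, fold_change."""
    return _read("table1_root24h.tsv")


def load_transporter_fold_changes() -> pd.DataFrame:
    """Fold changes of the Cd-responsive metal-ion transporters across the
    four tissue/timepoint combinations, with the published >5-fold
    highlight flags (``*_bold`` columns)."""
    df = _read("table2_transporters.tsv")
    for col in TABLE2_FC_COLUMNS:
        df[f"{col}_bold"] = df[f"{col}_bold"].astype(bool)
    return df
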