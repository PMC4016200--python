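"""Transporter-family analysis and the metal-panel response classifier.

Covers: Pfam-domain-based family assignment, family composition of the
responsive transporter set, the >5-fold reporting filter, qPCR relative
expression by the 2^-ddCt method (Ubiquitin1 reference, water control),
and classification of transcripts into four response groups across the
12-medium metal-ion panel:

  group 1  upregulated under Cd only
  group 2  upregulated under Cd and some other treatments
  group 3  upregulated under other treatments but not Cd
  group 4  upregulated under general stress (a quorum of treatments)

The >= 2-fold upregulation cut and the group-4 quorum (>= 8 of the 11
non-control treatments) are configurable analysis choices, not measured
constants.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import TreatmentProfile
from .reference_tables import PFAM_FAMILIES, TABLE2_FC_COLUMNS

#: Non-control treatments of the metal-ion exposure panel.
PANEL_TREATMENTS = (
    "Cd", "Al", "Cu", "Fe", "Hg", "Mg", "Mn", "NaCl", "Ni", "Rb", "Zn",
)
CONTROL_TREATMENT = "control"

#: Family priority when a transcript carries several metal-binding
#: domains: first match in this published ordering wins.
FAMILY_PRIORITY = tuple(PFAM_FAMILIES.values()) + ("LCT1",)

UP_THRESHOLD = 2.0
GENERAL_QUORUM = 8
GROUPS = (1, 2, 3, 4, "unclassified")


def assign_families(domain_table: pd.DataFrame) -> dict[str, str]:
    """Map transcript -> family from a (transcript_id, family) table.

    Transcripts listed with several domains take the highest-priority
    family per ``FAMILY_PRIORITY``; unknown labels rank last and are kept
    only if no known family is present.
    """
    rank = {fam: i for i, fam in enumerate(FAMILY_PRIORITY)}
    best: dict[str, str] = {}
    for row in domain_table.itertuples(index=False):
        tid, fam = row.transcript_id, row.family
        if tid not in best or rank.get(fam, len(rank)) < rank.get(best[tid], len(rank)):
            best[tid] = fam
    return best


def family_composition(
    responsive_ids: Iterable[str], annotation: Mapping[str, str]
) -> pd.DataFrame:
    """Per-family counts and one-decimal percentages of the responsive set.

    Only annotated transcripts enter the denominator (the responsive
    transporter total).
    """
    families = [annotation[t] for t in responsive_ids if t in annotation]
    if not families:
        raise ValueError("no annotated responsive transcripts; percentages undefined")
    counts = pd.Series(families).value_counts()
    total = int(counts.sum())
    df = pd.DataFrame(
        {
            "family": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    ).reset_index(drop=True)
    df.attrs["total"] = total
    return df


def filter_fc_threshold(
    fc_table: pd.DataFrame,
    cut: float = 5.0,
    columns: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rows upregulated more than ``cut``-fold in >= 1 tissue/timepoint.

    Strict comparison (FC == cut is dropped). Returns the retained rows
    and a boolean flag frame marking the cells exceeding the cut (the
    printed tables typeset these in bold).
    """
    cols = list(columns) if columns is not None else [
        c for c in TABLE2_FC_COLUMNS if c in fc_table.columns
    ]
    if not cols:
        raise ValueError("no fold-change columns to filter on")
    flags = fc_table[cols] > cut
    keep = flags.any(axis=1)
    return fc_table[keep], flags[keep]


def column_max(
    fc_table: pd.DataFrame, column: str, id_column: str = "transcript_id"
) -> tuple[str, float]:
    """(transcript, FC) attaining the column maximum; ties break to the
    lexicographically smallest transcript id."""
    if fc_table.empty:
        raise ValueError("empty fold-change table")
    ordered = fc_table.sort_values(id_column, kind="stable")
    idx = ordered[column].to_numpy().argmax()  # argmax keeps first = smallest id
    row = ordered.iloc[idx]
    return str(row[id_column]), float(row[column])


def relative_expression(
    ct_target_trt: Union[float, Sequence[float]],
    ct_ref_trt: Union[float, Sequence[float]],
    ct_target_ctl: Union[float, Sequence[float]],
    ct_ref_ctl: Union[float, Sequence[float]],
) -> float:
    """2^-ddCt relative expression; technical replicates are averaged first.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control)
    """
    vals = []
    for v in (ct_target_trt, ct_ref_trt, ct_target_ctl, ct_ref_ctl):
        arr = np.asarray(v, dtype=float)
        if arr.size == 0 or not np.all(np.isfinite(arr)):
            raise ValueError("Ct values must be finite and non-empty")
        vals.append(float(arr.mean()))
    ddct = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return float(2.0 ** -ddct)


def profiles_from_ct_table(
    ct_table: pd.DataFrame, reference_gene: str = "Ubiquitin1"
) -> dict[str, TreatmentProfile]:
    """Build per-transcript treatment profiles from a long Ct table.

    Expected columns: gene, treatment, tissue, replicate, ct. Relative
    expression per (treatment, tissue) is 2^-ddCt against the reference
    gene, normalised to the water control of the same tissue.
    """
    required = {"gene", "treatment", "tissue", "replicate", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    mean_ct = ct_table.groupby(["gene", "treatment", "tissue"])["ct"].mean()
    if reference_gene not in ct_table["gene"].values:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    profiles: dict[str, TreatmentProfile] = {}
    targets = sorted(set(ct_table["gene"]) - {reference_gene})
    tissues = sorted(set(ct_table["tissue"]))
    for gene in targets:
        rel: dict[tuple[str, str], float] = {}
        for tissue in tissues:
            try:
                tgt_ctl = mean_ct[(gene, CONTROL_TREATMENT, tissue)]
                ref_ctl = mean_ct[(reference_gene, CONTROL_TREATMENT, tissue)]
            except KeyError:
                raise ValueError(f"missing control Ct for {gene}/{tissue}")
            for trt in sorted(set(ct_table["treatment"])):
                try:
                    tgt = mean_ct[(gene, trt, tissue)]
                    ref = mean_ct[(reference_gene, trt, tissue)]
                except KeyError:
                    raise ValueError(f"missing Ct for {gene}/{trt}/{tissue}")
                rel[(trt, tissue)] = relative_expression(tgt, ref, tgt_ctl, ref_ctl)
        profiles[gene] = TreatmentProfile(transcript_id=gene, rel_expr=rel)
    return profiles


def classify_response_group(
    profile: TreatmentProfile,
    up_threshold: float = UP_THRESHOLD,
    general_quorum: int = GENERAL_QUORUM,
    treatments: Sequence[str] = PANEL_TREATMENTS,
) -> Union[int, str]:
    """Assign a transcript to response group 1-4 (or 'unclassified').

    A treatment counts as upregulating when relative expression reaches
    ``up_threshold`` in at least one tissue. Group 4 (general stress)
    takes precedence at ``general_quorum`` upregulating treatments.
    """
    tissues = sorted({tissue for _, tissue in profile.rel_expr})
    missing = [
        t for t in treatments
        if not any((t, ts) in profile.rel_expr for ts in tissues)
    ]
    if missing:
        raise ValueError(f"incomplete treatment panel, missing {missing}")
    up = {
        t
        for t in treatments
        if any(profile.rel_expr.get((t, ts), 0.0) >= up_threshold for ts in tissues)
    }
    if len(up) >= general_quorum:
        return 4
    if up == {"Cd"}:
        return 1
    if "Cd" in up and len(up) >= 2:
        return 2
    if up and "Cd" not in up:
        return 3
    return "unclassified"


def classify_panel(
    profiles: Mapping[str, TreatmentProfile],
    up_threshold: float = UP_THRESHOLD,
    general_quorum: int = GENERAL_QUORUM,
) -> pd.Series:
    """Response group per transcript, as a Series indexed by id."""
    return pd.Series(
        {
            tid: classify_response_group(p, up_threshold, general_quorum)
            for tid, p in profiles.items()
        },
        name="group",
    )
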