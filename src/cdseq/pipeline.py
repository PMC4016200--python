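"""End-to-end orchestration: simulate/load -> quantify -> DE -> enrichment
-> splicing -> Venn -> families, writing a TSV report bundle plus a JSON
manifest.

Outputs are a pure function of (inputs, config, seed): files are written
with fixed formatting and no timestamps, so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as cio
from .cross_stress import threshold_responsive, venn_partition
from .diffexpr import call_responsive, responsive_summary
from .enrichment import fisher_enrichment, heatmap_matrix
from .family_panel import classify_panel, profiles_from_ct_table
from .models import CountLibrary, TranscriptModel, default_contrasts
from .quantify import merge_by_condition, replicate_correlation, rpkm_matrix
from .splicing import detect_pattern_changes
from .synthetic import (
    SimulationConfig,
    simulate_counts,
    simulate_qpcr_panel,
    simulate_splice_tables,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed driving one pipeline run.

    Leave the input paths unset to run on synthetic data generated from
    ``simulation`` (its seed is overridden by ``seed``).
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    alpha: float = 0.01
    enrichment_fdr: float = 0.05
    up_cut: float = 2.0
    down_cut: float = 0.5
    transporter_cut: float = 5.0
    counts_path: Optional[str] = None
    gtf_path: Optional[str] = None
    go_path: Optional[str] = None
    splice_path: Optional[str] = None
    ct_path: Optional[str] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("enrichment_fdr", "up_cut", "down_cut", "transporter_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("simulation", {}) or {}).items()
        })
        return cls(simulation=sim, **raw)


def _load_or_simulate(
    config: PipelineConfig,
) -> tuple[list[CountLibrary], list[TranscriptModel], dict[str, set[str]]]:
    if config.counts_path:
        if not config.gtf_path:
            raise ValueError("supplied counts require a GTF for exonic lengths")
        libraries = cio.read_count_table(config.counts_path)
        lengths = cio.exonic_lengths_from_gtf(config.gtf_path)
        annotation = (
            cio.read_go_annotation(config.go_path) if config.go_path else {}
        )
        models = [
            TranscriptModel(
                transcript_id=t,
                locus_id=t,
                length=lengths[t],
                go_terms=frozenset(annotation.get(t, ())),
            )
            for t in sorted(lengths)
        ]
        return libraries, models, annotation
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    libraries, models, _ = simulate_counts(sim)
    annotation = {
        m.transcript_id: set(m.go_terms) for m in models if m.go_terms
    }
    return libraries, models, annotation


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        cio.write_tsv(df, path, index=index)
        outputs.append(path)

    libraries, models, annotation = _load_or_simulate(config)

    # --- replicate QC and merging
    qc_rows = []
    by_cond: dict[tuple[str, str], list[CountLibrary]] = {}
    for lib in libraries:
        by_cond.setdefault((lib.tissue, lib.condition), []).append(lib)
    for (tissue, cond), libs in sorted(by_cond.items()):
        for i in range(len(libs)):
            for j in range(i + 1, len(libs)):
                r = replicate_correlation(libs[i], libs[j], models)
                qc_rows.append(
                    {
                        "tissue": tissue,
                        "condition": cond,
                        "pair": f"{libs[i].label}~{libs[j].label}",
                        "pearson_log2_rpkm": round(r, 4),
                    }
                )
    emit(pd.DataFrame(qc_rows), "replicate_qc.tsv", index=False)
    merged = merge_by_condition(libraries)

    # --- expression
    rpkm = rpkm_matrix(list(merged.values()), models)
    emit(rpkm, "rpkm.tsv")

    # --- differential expression
    contrasts = default_contrasts()
    de = call_responsive(merged, models, contrasts, alpha=config.alpha)
    for contrast, table in de.items():
        emit(table, f"de_{contrast.label}.tsv")
    emit(responsive_summary(de), "responsive_summary.tsv", index=False)

    # --- GO enrichment
    if annotation:
        universe = {
            m.transcript_id
            for m in models
            if m.go_terms and bool((rpkm.loc[m.transcript_id] > 0).any())
        }
        cells = {}
        for contrast, table in de.items():
            for direction in ("up", "down"):
                cluster = set(table.index[table["direction"] == direction]) & universe
                if not cluster:
                    continue
                label = f"{direction}_{contrast.tissue}_{contrast.treatment}"
                cells[label] = fisher_enrichment(
                    cluster, annotation, universe, alpha=config.enrichment_fdr
                )
        long = pd.concat(
            [df.assign(cluster=label) for label, df in cells.items()],
            ignore_index=True,
        ) if cells else pd.DataFrame()
        emit(long, "enrichment_long.tsv", index=False)
        emit(heatmap_matrix(cells), "enrichment_matrix.tsv")
    else:
        log.warning("no GO annotation available; enrichment stage skipped")

    # --- alternative splicing
    if config.splice_path:
        tables = cio.read_splice_tables(config.splice_path)
    else:
        tables, _ = simulate_splice_tables(
            dataclasses.replace(config.simulation, seed=config.seed)
        )
    conds = sorted(tables[0].libsizes) if tables else []
    if len(conds) >= 2:
        changed, summary = detect_pattern_changes(tables, conds[0], conds[1])
        emit(pd.DataFrame([summary]), "splice_summary.tsv", index=False)
        emit(
            pd.DataFrame({"locus_id": sorted(changed)}),
            "splice_changed_loci.tsv",
            index=False,
        )

    # --- cross-contrast Venn of responsive sets
    for direction in ("up", "down"):
        sets = [
            threshold_responsive(
                dict(table["fold_change"]),
                treatment=contrast.label,
                tissue=contrast.tissue,
                up_cut=config.up_cut,
                down_cut=config.down_cut,
            )
            for contrast, table in de.items()
        ]
        regions = venn_partition(sets, direction)
        emit(
            pd.DataFrame(
                [
                    {"region": "&".join(sorted(labels)), "count": count}
                    for labels, count in sorted(
                        regions.items(), key=lambda kv: sorted(kv[0])
                    )
                ]
            ),
            f"venn_{direction}.tsv",
            index=False,
        )

    # --- qPCR panel response groups
    if config.ct_path:
        ct_table = pd.read_csv(config.ct_path, sep="\t")
    else:
        ct_table, _ = simulate_qpcr_panel(
            dataclasses.replace(config.simulation, seed=config.seed)
        )
    profiles = profiles_from_ct_table(ct_table)
    groups = classify_panel(profiles)
    emit(groups.rename_axis("transcript_id").to_frame(), "response_groups.tsv")

    # --- manifest
    manifest = {
        "seed": config.seed,
        "alpha": config.alpha,
        "enrichment_fdr": config.enrichment_fdr,
        "up_cut": config.up_cut,
        "down_cut": config.down_cut,
        "transporter_cut": config.transporter_cut,
        "n_libraries": len(libraries),
        "n_transcripts": len(models),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(outputs)
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
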