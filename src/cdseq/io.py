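"""Reading and writing the pipeline's file formats.

Everything is plain text: GTF for transcript models (1-based inclusive
coordinates; exonic length is the union of a transcript's exon
intervals), TSV for count matrices, GO/family annotation, splice-site
counts and Ct tables.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence, Union

import gffutils
import pandas as pd

from .models import CountLibrary, SpliceSiteTable, TranscriptModel

PathLike = Union[str, Path]

_LIB_LABEL = re.compile(r"^(?P<tissue>[^_]+)_(?P<condition>[^_]+?)(?:_r(?P<rep>\d+))?$")


# ---------------------------------------------------------------- GTF

def write_gtf(models: Sequence[TranscriptModel], path: PathLike) -> None:
    """Write one single-exon GTF record per transcript (synthetic models
    carry total exonic length, not genomic structure)."""
    with open(path, "w") as fh:
        pos = 1
        for m in models:
            attrs = f'gene_id "{m.locus_id}"; transcript_id "{m.transcript_id}";'
            fh.write(
                f"chr1\tcdseq\texon\t{pos}\t{pos + m.length - 1}\t.\t+\t.\t{attrs}\n"
            )
            pos += m.length + 100

def exonic_lengths_from_gtf(path: PathLike) -> dict[str, int]:
    """Exon-model length per transcript: union of its exon intervals.

    Coordinates are 1-based inclusive, so an exon spans end - start + 1
    nucleotides; overlapping exons of the same transcript are merged.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    intervals: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        intervals.setdefault(tid, []).append((exon.start, exon.end))
    lengths: dict[str, int] = {}
    for tid, ivals in intervals.items():
        ivals.sort()
        total = 0
        cur_start, cur_end = ivals[0]
        for start, end in ivals[1:]:
            if start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        lengths[tid] = total + cur_end - cur_start + 1
    return lengths


# -------------------------------------------------------- count tables

def write_count_table(libraries: Sequence[CountLibrary], path: PathLike) -> None:
    """TSV: transcript_id, then one column per library (tissue_cond[_rN]);
    a leading comment line records each library's total mapped reads."""
    ids = sorted({t for lib in libraries for t in lib.counts})
    with open(path, "w") as fh:
        totals = " ".join(f"{lib.label}={lib.n_total}" for lib in libraries)
        fh.write(f"# n_total {totals}\n")
        fh.write("transcript_id\t" + "\t".join(lib.label for lib in libraries) + "\n")
        for t in ids:
            fh.write(t + "\t" + "\t".join(str(lib.get(t)) for lib in libraries) + "\n")


def read_count_table(path: PathLike) -> list[CountLibrary]:
    """Inverse of :func:`write_count_table`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# n_total"):
            raise ValueError(f"{path}:1: expected '# n_total ...' comment line")
        totals = dict(
            item.split("=") for item in header.removeprefix("# n_total").split()
        )
        df = pd.read_csv(fh, sep="\t", index_col="transcript_id")
    libraries = []
    for label in df.columns:
        m = _LIB_LABEL.match(label)
        if m is None:
            raise ValueError(f"{path}: cannot parse library label {label!r}")
        libraries.append(
            CountLibrary(
                tissue=m["tissue"],
                condition=m["condition"],
                counts={t: int(c) for t, c in df[label].items()},
                n_total=int(totals[label]),
                replicate=int(m["rep"]) if m["rep"] else None,
            )
        )
    return libraries


# ---------------------------------------------------------- annotation

def write_go_annotation(models: Sequence[TranscriptModel], path: PathLike) -> None:
    """Two-column TSV transcript_id <tab> GO id (one row per pair)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tgo_id\n")
        for m in models:
            for term in sorted(m.go_terms):
                fh.write(f"{m.transcript_id}\t{term}\n")


def read_go_annotation(path: PathLike) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    annot: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        annot.setdefault(row.transcript_id, set()).add(row.go_id)
    return annot


def read_family_annotation(path: PathLike) -> pd.DataFrame:
    """TSV with columns transcript_id, pfam (optional), family."""
    df = pd.read_csv(path, sep="\t")
    if not {"transcript_id", "family"} <= set(df.columns):
        raise ValueError(f"{path}: need columns transcript_id, family")
    return df


# ------------------------------------------------------- splice tables

def write_splice_tables(tables: Sequence[SpliceSiteTable], path: PathLike) -> None:
    """Long TSV (locus_id, coordinate, condition, count) with per-condition
    library sizes on a leading comment line."""
    conds = sorted(tables[0].libsizes) if tables else []
    with open(path, "w") as fh:
        sizes = " ".join(f"{c}={tables[0].libsizes[c]}" for c in conds)
        fh.write(f"# libsize {sizes}\n")
        fh.write("locus_id\tcoordinate\tcondition\tcount\n")
        for table in tables:
            for coord in sorted(table.sites):
                for cond in conds:
                    fh.write(
                        f"{table.locus_id}\t{coord}\t{cond}\t{table.sites[coord].get(cond, 0)}\n"
                    )


def read_splice_tables(path: PathLike) -> list[SpliceSiteTable]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# libsize"):
            raise ValueError(f"{path}:1: expected '# libsize ...' comment line")
        libsizes = {
            k: int(v)
            for k, v in (
                item.split("=") for item in header.removeprefix("# libsize").split()
            )
        }
        df = pd.read_csv(fh, sep="\t")
    tables = []
    for locus_id, group in df.groupby("locus_id", sort=True):
        sites: dict[int, dict[str, int]] = {}
        for coord, cond, count in zip(
            group["coordinate"], group["condition"], group["count"]
        ):
            sites.setdefault(int(coord), {})[cond] = int(count)
        tables.append(SpliceSiteTable(locus_id=str(locus_id), sites=sites, libsizes=libsizes))
    return tables


# ---------------------------------------------------------- generic TSV

def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = True) -> None:
    """Deterministic TSV output (fixed float format, no timestamps)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def read_fold_change_table(path: PathLike) -> pd.DataFrame:
    """TSV keyed by a gene/transcript id column with fold-change columns."""
    return pd.read_csv(path, sep="\t")
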