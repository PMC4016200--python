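"""Responsive-transcript calling by G-test on read-count proportions.

For each transcript and each tissue/timepoint contrast, a 2x2 contingency
table is formed from (reads mapped to the transcript, all other mapped
reads) in the baseline and treatment libraries. The likelihood-ratio
statistic

    G = 2 * sum_cells O * ln(O / E)

is referred to a chi-square distribution with 1 degree of freedom (this
tests equality of the transcript's mapped-read proportion between
conditions). P-values are adjusted per contrast by Benjamini-Hochberg, and
a transcript is "responsive" when its adjusted value falls below alpha
(default 0.01). Fold changes are pseudocounted RPKM ratios,
(RPKM_treatment + 1) / (RPKM_baseline + 1), so undetected transcripts
yield a defined ratio of 1.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .models import Contrast, CountLibrary, TranscriptModel
from .quantify import compute_rpkm

ArrayLike = Union[float, int, np.ndarray]

DE_COLUMNS = ["G", "p", "q", "fold_change", "direction", "responsive"]


def g_test_2x2(a: int, n1: int, b: int, n2: int) -> tuple[float, float]:
    """G statistic and chi-square(1 df) p-value for the 2x2 table
    [[a, n1-a], [b, n2-b]] (transcript reads vs other mapped reads in
    baseline and treatment). Zero cells contribute nothing to G."""
    G, p = g_test_vectorized(
        np.asarray([a]), np.asarray([n1]), np.asarray([b]), np.asarray([n2])
    )
    return float(G[0]), float(p[0])


def g_test_vectorized(
    a: np.ndarray, n1: ArrayLike, b: np.ndarray, n2: ArrayLike
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised G-test over parallel arrays of 2x2 tables."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), a.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), a.shape)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library totals must be positive")
    if np.any(a < 0) or np.any(b < 0) or np.any(a > n1) or np.any(b > n2):
        raise ValueError("counts must satisfy 0 <= count <= library total")

    obs = np.stack([a, n1 - a, b, n2 - b], axis=-1)
    total = n1 + n2
    row1 = a + b  # reads on the transcript
    row2 = total - row1
    exp = np.stack(
        [
            row1 * n1 / total,
            row2 * n1 / total,
            row1 * n2 / total,
            row2 * n2 / total,
        ],
        axis=-1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    G = np.maximum(2.0 * terms.sum(axis=-1), 0.0)  # clip float roundoff
    return G, chi2.sf(G, df=1)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    rpkm_treatment: ArrayLike, rpkm_baseline: ArrayLike, pseudocount: float = 1.0
) -> ArrayLike:
    """Pseudocounted expression ratio (treatment + 1) / (baseline + 1)."""
    t = np.asarray(rpkm_treatment, dtype=float)
    c = np.asarray(rpkm_baseline, dtype=float)
    if np.any(t < 0) or np.any(c < 0):
        raise ValueError("expression values must be non-negative")
    out = (t + pseudocount) / (c + pseudocount)
    return float(out) if out.ndim == 0 else out


def call_responsive(
    merged: dict[tuple[str, str], CountLibrary],
    models: Sequence[TranscriptModel],
    contrasts: Sequence[Contrast],
    alpha: float = 0.01,
    pseudocount: float = 1.0,
) -> dict[Contrast, pd.DataFrame]:
    """Per-contrast differential-expression tables.

    The tested universe per contrast is every transcript detected
    (RPKM > 0) in at least one of its two conditions; undetected
    transcripts are reported with G=0, p=q=1, fold change 1. BH
    adjustment is applied within each contrast separately.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ids = [m.transcript_id for m in models]
    lengths = np.array([m.length for m in models], dtype=float)
    results: dict[Contrast, pd.DataFrame] = {}
    for contrast in contrasts:
        try:
            base = merged[(contrast.tissue, contrast.baseline)]
            trt = merged[(contrast.tissue, contrast.treatment)]
        except KeyError as exc:
            raise ValueError(f"missing merged library for contrast {contrast.label}: {exc}")
        a = np.array([base.get(t) for t in ids], dtype=float)
        b = np.array([trt.get(t) for t in ids], dtype=float)
        rpkm_base = compute_rpkm(a, lengths, base.n_total)
        rpkm_trt = compute_rpkm(b, lengths, trt.n_total)
        fc = fold_change(rpkm_trt, rpkm_base, pseudocount)

        tested = (a > 0) | (b > 0)
        G = np.zeros(len(ids))
        p = np.ones(len(ids))
        q = np.ones(len(ids))
        if tested.any():
            G[tested], p[tested] = g_test_vectorized(
                a[tested], base.n_total, b[tested], trt.n_total
            )
            q[tested] = bh_fdr(p[tested])
        responsive = q < alpha
        direction = np.where(
            responsive & (fc > 1), "up", np.where(responsive & (fc < 1), "down", "none")
        )
        results[contrast] = pd.DataFrame(
            {
                "G": G,
                "p": p,
                "q": q,
                "fold_change": fc,
                "direction": direction,
                "responsive": responsive,
            },
            index=pd.Index(ids, name="transcript_id"),
        )
    return results


def responsive_summary(results: dict[Contrast, pd.DataFrame]) -> pd.DataFrame:
    """Up/down responsive-transcript counts per contrast (bar-chart style
    summary of the time course)."""
    rows = []
    for contrast, df in results.items():
        rows.append(
            {
                "tissue": contrast.tissue,
                "timepoint": contrast.treatment,
                "up": int((df["direction"] == "up").sum()),
                "down": int((df["direction"] == "down").sum()),
                "responsive": int(df["responsive"].sum()),
                "tested": int((df["p"] < 1).sum()),
            }
        )
    return pd.DataFrame(rows)


def rank_top_upregulated(
    table: pd.DataFrame,
    annotation_filter: Optional[Callable[[str], bool]] = None,
    k: int = 20,
    fc_column: str = "fold_change",
) -> pd.DataFrame:
    """Top-k rows by descending fold change, ties broken by transcript id.

    ``annotation_filter`` keeps only transcripts for which it returns True
    (e.g. "lacks a microarray probe"). Rows flagged non-responsive (when a
    ``responsive`` column is present) are excluded first.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    df = table
    if "responsive" in df.columns:
        df = df[df["responsive"] & (df[fc_column] > 1)]
    if annotation_filter is not None:
        keep = [annotation_filter(t) for t in df.index]
        df = df[keep]
    if "transcript_id" in df.columns:
        df = df.sort_values("transcript_id", kind="stable")
    else:
        df = df.sort_index(kind="stable")
    df = df.sort_values(fc_column, ascending=False, kind="stable")
    return df.head(k)
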