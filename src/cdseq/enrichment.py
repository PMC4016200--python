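"""GO-term over-representation in responsive-transcript clusters.

Each cluster (e.g. "upregulated, root, 24 h") is tested against the
detected-transcript universe with a one-tailed Fisher exact
(hypergeometric upper-tail) test per term, Benjamini-Hochberg adjusted
within the cluster; a term is enriched at q < 0.05. Scores for the
heatmap are -log10(q).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr

#: q-values are floored here before taking -log10 (overflow guard).
Q_FLOOR = 1e-300

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "M", "p", "q", "significant"]


def fisher_enrichment(
    cluster: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of ``cluster`` within ``universe``.

    ``annotation`` maps gene -> GO terms (annotations outside the
    universe are ignored). For a term annotating K of M universe genes
    and k of the n cluster genes, p = P(X >= k) under the hypergeometric
    null; only terms annotating at least one cluster gene are reported.
    """
    cluster_set = set(cluster)
    universe_set = set(universe)
    if not cluster_set <= universe_set:
        raise ValueError("cluster must be a subset of the universe")
    M = len(universe_set)
    n = len(cluster_set)

    term_universe: dict[str, int] = {}
    term_cluster: dict[str, int] = {}
    for gene in universe_set:
        for term in annotation.get(gene, ()):  # genes may be unannotated
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in cluster_set:
                term_cluster[term] = term_cluster.get(term, 0) + 1

    terms = sorted(term_cluster)
    if not terms:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    k = np.array([term_cluster[t] for t in terms])
    K = np.array([term_universe[t] for t in terms])
    p = hypergeom.sf(k - 1, M, K, n)
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "term": terms,
            "k": k,
            "K": K,
            "n": n,
            "M": M,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )


def heatmap_matrix(
    cells_by_cluster: Mapping[str, pd.DataFrame], q_floor: float = Q_FLOOR
) -> pd.DataFrame:
    """Term x cluster matrix of -log10(q) enrichment scores.

    Term/cluster pairs absent from a cluster's result table score 0;
    q-values are floored at ``q_floor`` so the score stays finite.
    """
    scores: dict[str, pd.Series] = {}
    for cluster, df in cells_by_cluster.items():
        if len(df):
            q = np.maximum(df["q"].to_numpy(dtype=float), q_floor)
            scores[cluster] = pd.Series(-np.log10(q), index=df["term"].to_numpy())
        else:
            scores[cluster] = pd.Series(dtype=float)
    matrix = pd.DataFrame(scores).fillna(0.0)
    matrix.index.name = "term"
    return matrix.sort_index()
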