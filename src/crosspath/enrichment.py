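"""Per-study pathway enrichment from gene-level differential-expression p-values.

Two over-representation flavours are provided.  The hypergeometric (Fisher
exact) route thresholds each study at its top-n most differentially expressed
genes and tests pathway over-representation of that list against the measured
background.  The Kolmogorov-Smirnov route is threshold-free: it asks whether
the DE p-values of the genes inside a pathway are stochastically smaller than
those outside.  Either way the result is a pathway x study matrix of raw
enrichment p-values, the input to the adaptively weighted meta-analysis.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .geneset_io import GeneSet, GeneSetCollection

__all__ = [
    "P_FLOOR",
    "select_top_de_genes",
    "fisher_enrichment",
    "ks_enrichment",
    "enrich_all",
]

# Exact zeros are replaced by this before any downstream log-transform.
P_FLOOR = 1e-300


def floor_pvalues(p: np.ndarray) -> np.ndarray:
    """Clip p-values into (0, 1]; exact zeros become P_FLOOR."""
    return np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)


def select_top_de_genes(study_pvals: Mapping[str, float] | pd.Series, n: int) -> frozenset[str]:
    """The n genes with smallest DE p-value.

    Ties at the rank-n boundary are broken by lexicographic gene id so the
    selection is reproducible across runs and platforms.
    """
    s = pd.Series(study_pvals, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(s):
        raise ValueError(f"requested top {n} genes but only {len(s)} measured")
    order = sorted(s.index, key=lambda g: (s[g], g))
    return frozenset(order[:n])


def fisher_enrichment(
    de_genes: frozenset[str] | set[str], pathway: GeneSet, universe: frozenset[str] | set[str]
) -> float:
    """One-sided over-representation p-value, P(X >= k).

    X ~ Hypergeometric(N = |universe|, K = |pathway ∩ universe|,
    n = |de_genes|) and k = |de_genes ∩ pathway|.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    de = frozenset(de_genes) & universe
    if not de:
        raise ValueError("empty DE gene list (after restriction to universe)")
    K = len(pathway.genes & universe)
    k = len(de & pathway.genes)
    # sf(k-1) = P(X >= k)
    p = stats.hypergeom.sf(k - 1, len(universe), K, len(de))
    return float(floor_pvalues(p))


def ks_enrichment(
    study_pvals: Mapping[str, float] | pd.Series,
    pathway: GeneSet,
    universe: frozenset[str] | set[str],
) -> float:
    """One-sided two-sample KS p-value: in-pathway DE p-values stochastically
    smaller than out-of-pathway ones.

    Uses the alternative that the in-pathway empirical CDF lies above the
    out-of-pathway CDF (mass shifted toward small p-values).
    """
    s = pd.Series(study_pvals, dtype=float)
    s = s[s.index.isin(universe)]
    inside = s[s.index.isin(pathway.genes)].to_numpy()
    outside = s[~s.index.isin(pathway.genes)].to_numpy()
    if inside.size == 0 or outside.size == 0:
        raise ValueError(
            f"pathway {pathway.id!r}: need >=1 gene inside and outside the pathway"
        )
    # 'greater': CDF of the first sample dominates -> first sample smaller values
    res = stats.ks_2samp(inside, outside, alternative="greater", method="auto")
    return float(floor_pvalues(res.pvalue))


def enrich_all(
    matrix: pd.DataFrame,
    coll: GeneSetCollection,
    method: str = "fisher",
    n_top: int = 400,
) -> pd.DataFrame:
    """Enrichment p-value for every (pathway, study) pair.

    ``matrix`` holds gene-level DE p-values (genes x studies).  The
    over-representation background for each study is the measured genes
    intersected with the collection universe; pathways that do not intersect
    it are reported as p = 1.  The collection is expected to be size-filtered
    already.

    Returns a pathways x studies DataFrame of raw enrichment p-values.
    """
    if method not in ("fisher", "ks"):
        raise ValueError(f"unknown enrichment method {method!r}")
    measured = frozenset(g.upper() for g in matrix.index)
    universe = measured & coll.universe
    if not universe:
        raise ValueError("no overlap between measured genes and collection universe")
    out = pd.DataFrame(
        np.ones((len(coll), matrix.shape[1])), index=coll.ids, columns=matrix.columns
    )
    upper_index = matrix.index.str.upper()
    for study in matrix.columns:
        pvals = pd.Series(matrix[study].to_numpy(), index=upper_index)
        pvals = pvals[pvals.index.isin(universe)]
        if method == "fisher":
            de = select_top_de_genes(pvals, min(n_top, len(pvals)))
            for s in coll.sets:
                if s.genes & universe:
                    out.loc[s.id, study] = fisher_enrichment(de, s, universe)
        else:
            for s in coll.sets:
                if s.genes & universe and len(s.genes & universe) < len(universe):
                    out.loc[s.id, study] = ks_enrichment(pvals, s, universe)
    return out
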