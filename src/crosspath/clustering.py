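"""Redundancy reduction of significant pathways by kappa-based tight clustering.

Public pathway databases overlap heavily, so the significant list from the
meta-analysis usually contains many near-duplicates.  Pairwise similarity of
two pathways is Cohen's kappa of their gene-membership indicator vectors over
a background universe — chance-corrected agreement of the 2x2 membership
table.  Consensus clustering (subsample, cluster, count co-membership) over
the 1 - kappa dissimilarity suggests the number of clusters K via the
consensus-CDF delta-area elbow; the final partition is average-linkage
hierarchical clustering cut at K.  Pathways that sit loosely in their cluster
(silhouette width below a cutoff, 0.1 by default) are then moved iteratively
to a "scattered" set that is kept for secondary inspection, never discarded —
the surviving clusters are tight by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .geneset_io import GeneSetCollection

__all__ = [
    "SCATTERED",
    "kappa",
    "kappa_matrix",
    "ConsensusResult",
    "consensus_cluster",
    "assign_clusters",
    "silhouette_widths",
    "silhouette_tighten",
    "ClusterAssignment",
]

logger = logging.getLogger(__name__)

#: Label used for pathways removed during silhouette tightening.
SCATTERED = "scattered"


def kappa(set_a: frozenset | set, set_b: frozenset | set, universe: frozenset | set) -> float:
    """Cohen's kappa of two gene sets' membership vectors over a universe.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|, d the genes in neither, and
    n = |universe|: observed agreement Po = (a+d)/n, chance agreement
    Pe = ((a+b)(a+c) + (c+d)(b+d)) / n**2, kappa = (Po - Pe) / (1 - Pe).
    """
    universe = frozenset(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    A, B = frozenset(set_a) & universe, frozenset(set_b) & universe
    n = len(universe)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        if A == B:
            return 1.0
        raise ValueError("chance agreement is 1 but sets differ (degenerate universe)")
    return (po - pe) / (1.0 - pe)


def kappa_matrix(
    coll: GeneSetCollection, universe: frozenset | set | None = None
) -> pd.DataFrame:
    """Pairwise kappa between all sets of a collection (unit diagonal).

    The default universe is the union of genes across the collection's sets
    (the genes actually informative about pathway overlap); pass the full
    collection universe to include never-annotated genes in the d cell.
    Dissimilarity for clustering is 1 - kappa.
    """
    if len(coll) < 2:
        raise ValueError("need at least 2 pathways")
    if universe is None:
        universe = frozenset().union(*(s.genes for s in coll.sets))
    genes = sorted(universe)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    m = np.zeros((len(coll), n), dtype=np.float64)
    for i, s in enumerate(coll.sets):
        for g in s.genes & frozenset(universe):
            m[i, gene_idx[g]] = 1.0
    a = m @ m.T
    sizes = m.sum(axis=1)
    b = sizes[:, None] - a
    c = sizes[None, :] - a
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (po - pe) / (1.0 - pe)
    k[pe >= 1.0] = 1.0  # only identical membership vectors reach pe = 1 here
    np.fill_diagonal(k, 1.0)
    return pd.DataFrame(k, index=coll.ids, columns=coll.ids)


def _hclust_labels(dissim: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of a square dissimilarity, cut at k."""
    condensed = squareform(dissim, checks=False)
    z = hierarchy.linkage(condensed, method="average")
    return hierarchy.fcluster(z, t=k, criterion="maxclust")


@dataclass
class ConsensusResult:
    """Consensus-clustering summary over a range of candidate K."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]  # per K: co-clustering proportions
    cdf_area: dict[int, float]  # area under the consensus CDF
    delta_area: dict[int, float]  # relative delta area (elbow statistic)
    chosen_k: int


def consensus_cluster(
    dissim: pd.DataFrame,
    k_range=range(2, 9),
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Resampling-based clustering stability over candidate cluster numbers.

    For each K, ``n_resamples`` subsamples of the items are clustered
    (average-linkage on the subsampled dissimilarity) and the consensus matrix
    is the fraction of co-clusterings among co-samplings.  The empirical CDF
    of off-diagonal consensus entries yields an area A(K); the relative delta
    area flattens once K exceeds the true cluster number, and the chosen K is
    the largest candidate whose delta area still exceeds 0.1 (override by
    passing K explicitly downstream).  Pairs never co-sampled are excluded
    from the CDF (and flagged via NaN in the consensus matrix).
    """
    n = dissim.shape[0]
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range must contain values in [2, n-1]")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    d = dissim.to_numpy()
    m = max(2, int(round(subsample_frac * n)))
    # one shared sequence of subsamples across K makes A(K) comparisons fair
    subsamples = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]

    consensus: dict[int, pd.DataFrame] = {}
    cdf_area: dict[int, float] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for idx in subsamples:
            labels = _hclust_labels(d[np.ix_(idx, idx)], k)
            same = labels[:, None] == labels[None, :]
            co_sample[np.ix_(idx, idx)] += 1
            co_cluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), np.nan)
        np.fill_diagonal(cons, 1.0)
        never = int(np.isnan(cons).sum())
        if never:
            logger.warning("consensus_cluster: %d pair entries never co-sampled at K=%d", never, k)
        consensus[k] = pd.DataFrame(cons, index=dissim.index, columns=dissim.columns)
        off = cons[np.triu_indices(n, k=1)]
        off = off[~np.isnan(off)]
        # area under the empirical CDF of consensus entries on [0, 1]
        xs = np.sort(off)
        cdf_area[k] = float(np.sum((1.0 + np.arange(len(xs))) / len(xs) * np.diff(np.append(xs, 1.0))))

    delta_area: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[k_range[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0
    # walk K upward while the CDF area still gains >10% relative; stop at the
    # first flat step (late re-increases are fragmentation artifacts)
    chosen = k_range[0]
    for k in k_range[1:]:
        if delta_area[k] > 0.1:
            chosen = k
        else:
            break
    return ConsensusResult(
        k_range=list(k_range),
        consensus=consensus,
        cdf_area=cdf_area,
        delta_area=delta_area,
        chosen_k=chosen,
    )


def assign_clusters(dissim: pd.DataFrame, k: int, seed: int | None = None) -> pd.Series:
    """Final partition: average-linkage hierarchical clustering cut into k groups.

    ``dissim`` is typically 1 - consensus (after consensus_cluster) or 1 - kappa
    directly.  Deterministic; ``seed`` is accepted for interface symmetry.
    """
    n = dissim.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < {n}")
    labels = _hclust_labels(dissim.to_numpy(), k)
    if len(np.unique(labels)) < k:
        raise ValueError(f"cut produced fewer than {k} non-empty clusters")
    return pd.Series(labels, index=dissim.index, name="cluster")


def silhouette_widths(dissim: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)) per item.

    a(i) is the mean dissimilarity to the item's own cluster (excluding
    itself; 0 for a singleton cluster), b(i) the smallest mean dissimilarity
    to any other cluster.
    """
    labels = labels.loc[dissim.index]
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    d = dissim.to_numpy()
    lab = labels.to_numpy()
    s = np.empty(len(lab))
    for i in range(len(lab)):
        own = lab == lab[i]
        n_own = own.sum() - 1
        a = d[i, own].sum() / n_own if n_own > 0 else 0.0
        b = min(d[i, lab == c].mean() for c in uniq if c != lab[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return pd.Series(s, index=dissim.index, name="silhouette")


@dataclass
class ClusterAssignment:
    """Tight clustering result: labels (cluster id or SCATTERED) + silhouettes."""

    labels: pd.Series
    silhouettes: pd.Series
    n_iterations: int = 0

    @property
    def clusters(self) -> dict:
        """Mapping cluster id -> list of member pathway ids (scattered excluded)."""
        out: dict = {}
        for pid, lab in self.labels.items():
            if lab != SCATTERED:
                out.setdefault(lab, []).append(pid)
        return out

    @property
    def scattered(self) -> list:
        return [pid for pid, lab in self.labels.items() if lab == SCATTERED]


def silhouette_tighten(
    dissim: pd.DataFrame, labels: pd.Series, cutoff: float = 0.1
) -> ClusterAssignment:
    """Iteratively move low-silhouette items to the scattered set.

    Each iteration recomputes silhouettes on the retained items and removes
    every item below the cutoff at once (order-independent).  A cluster that
    empties, or shrinks to a singleton (whose a(i) = 0 convention would pin
    its silhouette near 1), is dissolved into the scattered set.  Terminates
    in at most n iterations; at convergence every retained silhouette is
    >= cutoff.
    """
    if not -1 < cutoff < 1:
        raise ValueError("cutoff must lie in (-1, 1)")
    labels = labels.loc[dissim.index].copy().astype(object)
    final_sil = pd.Series(np.nan, index=dissim.index, name="silhouette")
    n_iter = 0
    while True:
        retained = labels.index[labels != SCATTERED]
        counts = labels.loc[retained].value_counts()
        singles = counts.index[counts == 1]
        if len(singles):
            labels[labels.isin(singles)] = SCATTERED
            retained = labels.index[labels != SCATTERED]
        if len(retained) == 0 or labels.loc[retained].nunique() < 2:
            warnings.warn("silhouette tightening scattered all items (or all but one cluster)")
            labels.loc[retained] = SCATTERED
            break
        sil = silhouette_widths(dissim.loc[retained, retained], labels.loc[retained])
        final_sil.loc[retained] = sil
        low = sil.index[sil < cutoff]
        n_iter += 1
        if len(low) == 0:
            break
        labels.loc[low] = SCATTERED
    assignment = ClusterAssignment(labels=labels, silhouettes=final_sil, n_iterations=n_iter)
    kept = assignment.labels.index[assignment.labels != SCATTERED]
    assert len(kept) == 0 or assignment.silhouettes.loc[kept].min() >= cutoff
    return assignment
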