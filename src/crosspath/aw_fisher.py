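"""Adaptively weighted Fisher combination of per-study enrichment p-values.

Classical Fisher meta-analysis sums -2 log p over all K studies.  The
adaptively weighted variant instead searches binary study weights
w in {0,1}^K \\ {0}: for each w it forms V(w) = -2 sum_k w_k log p_k, converts
it to an observed significance U(w) = P(chi^2_{2 sum w} >= V(w)), and reports
the weight vector minimizing U(w).  The minimized U is not a p-value (it is
the minimum of dependent p-values), so the combined p-value is calibrated
against the null distribution of min_w U(W) under K i.i.d. Uniform(0,1)
p-values, here by vectorized Monte Carlo (or deterministic numerical
integration for K <= 3, used as an oracle).

The selected weights are the biological payoff: all-ones means a pathway is
consensually enriched in every study, while zeros flag the studies that do
not contribute (differential enrichment).

Because U(w) for fixed weight-sum s is minimized by taking the s smallest
p-values, the 2^K - 1 search collapses to K nested candidates (the s smallest
p-values for s = 1..K), which is what makes the Monte-Carlo null cheap.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_statistic",
    "observed_significance",
    "weight_search",
    "aw_pvalue",
    "meta_analyze",
    "bh_adjust",
    "select_significant",
]

logger = logging.getLogger(__name__)


def _check_pvec(pvec: np.ndarray) -> np.ndarray:
    pvec = np.asarray(pvec, dtype=float)
    if pvec.ndim != 1 or pvec.size == 0:
        raise ValueError("pvec must be a non-empty 1-d array")
    if (pvec <= 0).any():
        raise ValueError("p-values must be > 0 (floor exact zeros upstream)")
    if (pvec > 1).any():
        raise ValueError("p-values must be <= 1")
    return pvec


def fisher_statistic(pvec, w) -> float:
    """Weighted Fisher statistic V(w) = -2 sum_k w_k log p_k."""
    pvec = _check_pvec(pvec)
    w = np.asarray(w)
    if w.shape != pvec.shape:
        raise ValueError("weight vector length must match p-vector length")
    return float(-2.0 * np.sum(w * np.log(pvec)))


def _chi2_sf(v: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Upper tail of chi-square with 2*s degrees of freedom at v."""
    return special.gammaincc(s, np.asarray(v) / 2.0)


def observed_significance(pvec, w) -> float:
    """U(w): upper-tail chi-square probability of V(w) with 2*sum(w) df.

    With a single selected study this is exactly that study's p-value.
    """
    w = np.asarray(w)
    s = int(np.sum(w))
    if s < 1:
        raise ValueError("weight vector must select at least one study")
    return float(_chi2_sf(fisher_statistic(pvec, w), np.array(s)))


def _min_u_sorted(p_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """min over s of U for rows of ascending-sorted p-values.

    Returns (min U, argmin s); ties broken toward the smaller s (a sparser
    set of contributing studies explains the signal equally well).
    """
    logp = np.log(p_sorted)
    v = -2.0 * np.cumsum(logp, axis=-1)
    s = np.arange(1, p_sorted.shape[-1] + 1, dtype=float)
    u = _chi2_sf(v, s)
    best = np.argmin(u, axis=-1)  # np.argmin returns the first (smallest s) minimum
    return np.take_along_axis(u, best[..., None], axis=-1)[..., 0], best + 1


def weight_search(pvec) -> tuple[np.ndarray, float]:
    """Best binary weight vector and the minimized observed significance.

    Only the K nested candidate subsets (the s smallest p-values, s = 1..K)
    need evaluation; this provably contains the argmin over all 2^K - 1
    nonzero binary vectors.  At the rank boundary, tied p-values are taken in
    index order (deterministic).
    """
    pvec = _check_pvec(pvec)
    order = np.argsort(pvec, kind="stable")
    u_min, s_best = _min_u_sorted(pvec[order][None, :])
    s = int(s_best[0])
    w = np.zeros(pvec.size, dtype=int)
    w[order[:s]] = 1
    return w, float(u_min[0])


def _null_min_u(B: int, K: int, rng: np.random.Generator, batch: int = 2_000_000) -> np.ndarray:
    """B draws of min_w U(W) under K i.i.d. Uniform(0,1) p-values."""
    out = np.empty(B)
    done = 0
    while done < B:
        b = min(batch, B - done)
        p = rng.random((b, K))
        p.sort(axis=1)
        np.clip(p, 1e-300, None, out=p)
        out[done : done + b] = _min_u_sorted(p)[0]
        done += b
    return out


def _exact_small_k(t_obs: float, K: int, rtol: float = 0.01) -> float:
    """P(min_w U(W) <= t_obs) by midpoint-grid integration over [0,1]^K.

    Deterministic; the grid is refined (doubling resolution) until two
    successive refinements agree to ``rtol`` relative.  Practical for K <= 3
    and moderate tail probabilities; serves as the oracle for the Monte-Carlo
    estimator.
    """
    if K > 3:
        raise ValueError("exact_smallK integration supports K <= 3")
    if K == 1:
        return float(t_obs)

    # The nested-subset reduction turns the event {min U <= t} into
    # union_s {prod of the s smallest p's <= c_s}, with c_s solving
    # chi2.sf(-2 log c_s, 2s) = t.  The complement is integrated over the
    # ordered simplex p(1) < ... < p(K) with the constraints folded into the
    # integration limits (continuous integrand), on a midpoint grid refined
    # until two successive refinements agree to ``rtol`` relative.
    c = [float(np.exp(-special.gammainccinv(s, t_obs))) for s in range(1, K + 1)]

    def complement(m: int) -> float:
        # outer variable x = p(1) in (c[0], 1)
        x = c[0] + (1.0 - c[0]) * (np.arange(m) + 0.5) / m
        if K == 2:
            inner = np.maximum(0.0, 1.0 - np.maximum(x, c[1] / x))
            return 2.0 * (1.0 - c[0]) * float(np.mean(inner))
        # K == 3: for each x, integrate y = p(2) over (max(x, c2/x), 1) of the
        # z-interval length max(0, 1 - max(y, c3/(x*y)))
        total = 0.0
        for xi in x:
            y0 = max(xi, c[1] / xi)
            if y0 >= 1.0:
                continue
            y = y0 + (1.0 - y0) * (np.arange(m) + 0.5) / m
            h = np.maximum(0.0, 1.0 - np.maximum(y, c[2] / (xi * y)))
            total += (1.0 - y0) * float(np.mean(h)) * (1.0 - c[0]) / m
        return 6.0 * total

    prev = None
    m = 64
    while m <= 8192:
        val = 1.0 - complement(m)
        if prev is not None and prev > 0 and abs(val - prev) <= rtol * prev:
            return val
        prev = val
        m *= 2
    warnings.warn("exact_smallK grid integration did not converge to 1%; returning finest grid")
    return float(prev)


def aw_pvalue(
    pvec,
    method: str = "montecarlo",
    B: int = 10_000,
    seed: int | None = None,
    batch: int = 2_000_000,
) -> float:
    """Combined p-value P(min_w U(W) <= T_obs) under the uniform null.

    Monte Carlo uses B null draws with the nested-subset search per draw and
    the +1-corrected estimator (1 + hits) / (B + 1), which never returns an
    exact zero.  ``exact_smallK`` (K <= 3) integrates the null event region on
    a deterministic grid.  With K = 1 both reduce to the p-value itself.
    """
    pvec = _check_pvec(pvec)
    _, t_obs = weight_search(pvec)
    if method == "exact_smallK":
        return _exact_small_k(t_obs, pvec.size)
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    if B < 10_000:
        raise ValueError("montecarlo requires B >= 1e4")
    rng = np.random.default_rng(seed)
    t_null = _null_min_u(B, pvec.size, rng, batch=batch)
    hits = int(np.sum(t_null <= t_obs))
    if hits < 10:
        warnings.warn(
            f"only {hits} Monte-Carlo hits at B={B}; the combined p-value is "
            "imprecise — increase B (or use stratified/importance sampling)"
        )
    return (1 + hits) / (B + 1)


def meta_analyze(
    pmatrix: pd.DataFrame, B: int = 10_000, seed: int | None = None
) -> pd.DataFrame:
    """AW-Fisher meta-analysis of a pathways x studies p-value matrix.

    Returns a table with the raw per-study p-values, the selected 0/1 weights,
    the Monte-Carlo combined p-value and its Benjamini-Hochberg q-value.  One
    shared set of B null draws (the null depends only on the number of
    studies) serves every pathway, so the cost is O(B*K + n log B).
    """
    studies = list(pmatrix.columns)
    K = len(studies)
    vals = pmatrix.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("p-value matrix contains non-positive entries; floor them first")
    order = np.argsort(vals, axis=1, kind="stable")
    u, s_best = _min_u_sorted(np.take_along_axis(vals, order, axis=1))
    weights = np.zeros_like(vals, dtype=int)
    for i in range(vals.shape[0]):
        weights[i, order[i, : int(s_best[i])]] = 1

    rng = np.random.default_rng(seed)
    t_null = np.sort(_null_min_u(B, K, rng))
    hits = np.searchsorted(t_null, u, side="right")
    p_comb = (1 + hits) / (B + 1)
    q = bh_adjust(p_comb)

    out = pd.DataFrame(index=pmatrix.index)
    for j, st in enumerate(studies):
        out[f"p_{st}"] = vals[:, j]
    for j, st in enumerate(studies):
        out[f"weight_{st}"] = weights[:, j]
    out["p_combined"] = p_comb
    out["q"] = q
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q in [p, 1])."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def select_significant(meta: pd.DataFrame, q_cutoff: float = 0.0005) -> pd.DataFrame:
    """Pathways with q < cutoff, tagged consensual vs differential.

    Consensual: every study weight is 1 (the pathway is enriched everywhere);
    differential: at least one study is down-weighted to 0.
    """
    if not 0 < q_cutoff < 1:
        raise ValueError("q_cutoff must lie in (0, 1)")
    sel = meta[meta["q"] < q_cutoff].copy()
    if sel.empty:
        raise ValueError(
            f"no pathway passes q < {q_cutoff}; consider a less stringent cutoff"
        )
    wcols = [c for c in meta.columns if c.startswith("weight_")]
    sel["pattern"] = np.where(sel[wcols].all(axis=1), "consensual", "differential")
    return sel.sort_values("p_combined")
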