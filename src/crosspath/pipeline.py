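"""End-to-end orchestration: enrichment -> meta-analysis -> clustering -> keywords.

A run is driven by a :class:`RunConfig` (loadable from YAML), executes the
three analysis steps in order, writes every intermediate table as TSV (so any
stage can be resumed or inspected), renders the diagnostic plot families and
records a manifest (parameters, seeds, shapes, versions) sufficient to
reproduce every table byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import __version__
from .aw_fisher import meta_analyze, select_significant
from .clustering import (
    SCATTERED,
    ClusterAssignment,
    ConsensusResult,
    assign_clusters,
    consensus_cluster,
    kappa_matrix,
    silhouette_tighten,
)
from .enrichment import enrich_all
from .geneset_io import (
    GeneSetCollection,
    attach_descriptions,
    filter_by_size,
    read_description_table,
    read_gmt,
    read_pvalue_matrix,
    write_pvalue_matrix,
)
from .text_mining import (
    annotate_clusters,
    build_phrase_matrices,
    load_default_resources,
    merge_synonyms,
    penalized_scores,
    prune_rare_phrases,
)

__all__ = ["RunConfig", "ResultsBundle", "run_cpi", "study_dendrograms", "render_outputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters of a full run.  Defaults follow the reference
    protocol: top 400 DE genes, pathway sizes in [15, 500], meta-analysis
    cutoff q < 0.0005, silhouette cutoff 0.1, penalty alpha = 0.05 and
    B = 10,000 permutations."""

    gmt: str = ""
    descriptions: str = ""
    gene_pvalues: str = ""  # input mode 1: gene-level DE p-values
    pathway_pvalues: str = ""  # input mode 2: precomputed enrichment p-values
    outdir: str = "crosspath_results"
    method: str = "fisher"  # fisher | ks
    top_n: int = 400
    min_size: int = 15
    max_size: int = 500
    q_cutoff: float = 0.0005
    k: str | int = "auto"
    k_range: tuple[int, int] = (2, 8)
    n_resamples: int = 500
    subsample_frac: float = 0.8
    silhouette_cutoff: float = 0.1
    alpha: float = 0.05
    b_meta: int = 10_000
    b_perm: int = 10_000
    q_keywords: float = 0.05
    seed: int = 0
    plots: bool = True

    def validate(self) -> None:
        if not self.gmt:
            raise ValueError("config requires a gmt path")
        if bool(self.gene_pvalues) == bool(self.pathway_pvalues):
            raise ValueError("exactly one of gene_pvalues / pathway_pvalues must be set")
        if self.method not in ("fisher", "ks"):
            raise ValueError(f"unknown enrichment method {self.method!r}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 1 <= self.min_size <= self.max_size:
            raise ValueError("size bounds must satisfy 1 <= min_size <= max_size")
        if not 0 < self.q_cutoff < 1:
            raise ValueError("q_cutoff must lie in (0, 1)")
        if not -1 < self.silhouette_cutoff < 1:
            raise ValueError("silhouette_cutoff must lie in (-1, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ValueError("k must be 'auto' or an integer >= 2")
        if min(self.b_meta, self.b_perm) < 100:
            raise ValueError("Monte-Carlo sizes must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        with Path(path).open("w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ResultsBundle:
    """Everything a run produced, plus the manifest that reproduces it."""

    config: RunConfig
    pmatrix: pd.DataFrame
    meta: pd.DataFrame
    significant: pd.DataFrame
    kappa: pd.DataFrame
    assignment: ClusterAssignment
    annotation: pd.DataFrame
    consensus: ConsensusResult | None
    dendrograms: dict[str, str]
    manifest: dict


def _stage(name: str, t0: float, **info) -> dict:
    entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **info}
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))
    return entry


def run_cpi(config: RunConfig, collection: GeneSetCollection | None = None) -> ResultsBundle:
    """Execute the full pipeline per config; write tables under config.outdir.

    ``collection`` may be passed in-memory (the demo does); otherwise it is
    read from config.gmt (+ descriptions).  With pathway-level p-values as
    input the enrichment stage is skipped.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in ("meta", "consensus", "annotate")}

    t0 = time.time()
    if collection is None:
        coll = read_gmt(config.gmt)
        if config.descriptions:
            coll = attach_descriptions(coll, read_description_table(config.descriptions))
    else:
        coll = collection
    full_coll = coll  # text mining uses the unfiltered corpus as background

    if config.gene_pvalues:
        gene_p = read_pvalue_matrix(config.gene_pvalues)
        coll = filter_by_size(coll, config.min_size, config.max_size)
        stages.append(_stage("load", t0, n_sets=len(coll), n_genes=gene_p.shape[0]))
        t0 = time.time()
        pmatrix = enrich_all(gene_p, coll, method=config.method, n_top=config.top_n)
        write_pvalue_matrix(pmatrix, outdir / "enrichment.tsv")
        stages.append(_stage("enrich", t0, shape=pmatrix.shape, method=config.method))
    else:
        pmatrix = read_pvalue_matrix(config.pathway_pvalues)
        known = set(coll.ids)
        stray = [p for p in pmatrix.index if p not in known]
        if stray:
            raise ValueError(f"pathway p-value matrix has ids missing from the GMT: {stray[:5]}")
        stages.append(_stage("load", t0, n_sets=len(coll), input="pathway_pvalues"))

    t0 = time.time()
    meta = meta_analyze(pmatrix, B=config.b_meta, seed=seeds["meta"])
    meta.to_csv(outdir / "meta.tsv", sep="\t")
    significant = select_significant(meta, config.q_cutoff)
    significant.to_csv(outdir / "significant.tsv", sep="\t")
    stages.append(_stage("meta", t0, n_significant=len(significant), B=config.b_meta))

    t0 = time.time()
    sig_coll = GeneSetCollection(
        sets=tuple(s for s in coll.sets if s.id in set(significant.index)),
        universe=coll.universe,
    )
    km = kappa_matrix(sig_coll)
    dissim = 1.0 - km
    consensus: ConsensusResult | None = None
    if config.k == "auto":
        consensus = consensus_cluster(
            dissim,
            k_range=range(config.k_range[0], min(config.k_range[1], len(km) - 1) + 1),
            n_resamples=config.n_resamples,
            subsample_frac=config.subsample_frac,
            seed=seeds["consensus"],
        )
        k = consensus.chosen_k
        cut_dissim = 1.0 - consensus.consensus[k].fillna(0.0)
    else:
        k = int(config.k)
        cut_dissim = dissim
    labels = assign_clusters(cut_dissim, k)
    assignment = silhouette_tighten(dissim, labels, config.silhouette_cutoff)
    pd.DataFrame(
        {"cluster": assignment.labels, "silhouette": assignment.silhouettes}
    ).to_csv(outdir / "clusters.tsv", sep="\t", index_label="pathway")
    stages.append(_stage("cluster", t0, k=k, n_scattered=len(assignment.scattered)))

    t0 = time.time()
    resources = load_default_resources()
    mats = build_phrase_matrices(full_coll, resources)
    if resources.synonyms:
        mats = merge_synonyms(mats, resources.synonyms)
    mats = prune_rare_phrases(mats)
    scores = penalized_scores(mats, config.alpha)
    annotation = annotate_clusters(
        scores, assignment, B=config.b_perm, q_cutoff=config.q_keywords, seed=seeds["annotate"]
    )
    annotation.to_csv(outdir / "keywords.tsv", sep="\t", index=False)
    keep = annotation[annotation["significant"]]
    summary = keep.groupby("cluster")["phrase"].apply(lambda s: ", ".join(s.head(10)))
    summary.to_csv(outdir / "cluster_keywords_summary.tsv", sep="\t", header=["keywords"])
    stages.append(_stage("annotate", t0, n_phrases=len(mats.phrases), B=config.b_perm))

    dendrograms = study_dendrograms(pmatrix, assignment)
    for cid, nwk in dendrograms.items():
        (outdir / f"cluster_{cid}_studies.nwk").write_text(nwk + "\n")

    manifest = {
        "package": "crosspath",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {**asdict(config), "k_range": list(config.k_range)},
        "chosen_k": int(k),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    bundle = ResultsBundle(
        config=config,
        pmatrix=pmatrix,
        meta=meta,
        significant=significant,
        kappa=km,
        assignment=assignment,
        annotation=annotation,
        consensus=consensus,
        dendrograms=dendrograms,
        manifest=manifest,
    )
    if config.plots:
        render_outputs(bundle, outdir)
    return bundle


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left, right = node.get_left(), node.get_right()
    bl_l = node.dist - left.dist
    bl_r = node.dist - right.dist
    return f"({_newick(left, labels)}:{bl_l:.6g},{_newick(right, labels)}:{bl_r:.6g})"


def study_dendrograms(pmatrix: pd.DataFrame, assignment: ClusterAssignment) -> dict[str, str]:
    """Per-cluster hierarchical clustering of studies, serialized as newick.

    Studies are points in pathway space: their log10 enrichment p-value
    vectors restricted to the cluster's pathways, compared by Euclidean
    distance under average linkage.  Clusters with a single pathway are
    skipped with a notice.
    """
    out: dict[str, str] = {}
    for cid, members in assignment.clusters.items():
        if len(members) < 2:
            logger.info("cluster %s has a single pathway; dendrogram skipped", cid)
            continue
        mat = np.log10(pmatrix.loc[members].to_numpy()).T  # studies x pathways
        z = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
        tree = hierarchy.to_tree(z)
        out[str(cid)] = _newick(tree, list(pmatrix.columns)) + ";"
    return out


def _classical_mds(dissim: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a dissimilarity matrix; deterministic
    coordinates (largest-magnitude entry of each axis made positive)."""
    d2 = dissim**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for c in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, c]))
        if coords[i, c] < 0:
            coords[:, c] *= -1
    return coords


def render_outputs(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Render the four plot families; tables are written by run_cpi regardless.

    (1) kappa heatmap ordered by cluster with the scattered set last,
    (2) -log10 enrichment p heatmap (pathways x studies, cluster-sorted,
    capped at 10 for readability), (3) classical MDS of 1 - kappa colored by
    cluster, (4) consensus CDF + delta-area diagnostics when consensus
    clustering ran.  Failures are logged, never fatal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    asg = bundle.assignment
    order = [p for c in sorted(asg.clusters, key=str) for p in asg.clusters[c]] + asg.scattered
    labels = asg.labels.loc[order]
    try:
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(bundle.kappa.loc[order, order], cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title("pairwise kappa (cluster-ordered; scattered last)")
        ax.set_xticks([])
        boundaries = np.cumsum([len(asg.clusters[c]) for c in sorted(asg.clusters, key=str)])
        for b in boundaries[:-1] if len(asg.scattered) == 0 else boundaries:
            ax.axhline(b - 0.5, color="k", lw=0.6)
            ax.axvline(b - 0.5, color="k", lw=0.6)
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels(order, fontsize=4)
        fig.colorbar(im, ax=ax, label="kappa")
        path = outdir / "kappa_heatmap.pdf"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    except Exception:  # pragma: no cover - plotting must never kill a run
        logger.exception("kappa heatmap failed")

    try:
        fig, ax = plt.subplots(figsize=(5, 7))
        neglog = np.minimum(-np.log10(bundle.pmatrix.loc[order]), 10.0)
        im = ax.imshow(neglog, aspect="auto", cmap="viridis", vmin=0, vmax=10)
        ax.set_xticks(range(bundle.pmatrix.shape[1]))
        ax.set_xticklabels(bundle.pmatrix.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels(order, fontsize=4)
        ax.set_title("-log10 enrichment p (capped at 10)")
        fig.colorbar(im, ax=ax)
        path = outdir / "pvalue_heatmap.pdf"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    except Exception:  # pragma: no cover
        logger.exception("p-value heatmap failed")

    try:
        coords = _classical_mds(1.0 - bundle.kappa.loc[order, order].to_numpy())
        fig, ax = plt.subplots(figsize=(6, 5))
        for cid in labels.unique():
            m = (labels == cid).to_numpy()
            ax.scatter(coords[m, 0], coords[m, 1], label=str(cid), s=18)
        ax.legend(title="cluster", fontsize=7)
        ax.set_title("classical MDS of 1 - kappa")
        path = outdir / "mds.pdf"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    except Exception:  # pragma: no cover
        logger.exception("MDS plot failed")

    if bundle.consensus is not None:
        try:
            cons = bundle.consensus
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
            for k in cons.k_range:
                vals = cons.consensus[k].to_numpy()
                off = vals[np.triu_indices(vals.shape[0], k=1)]
                off = np.sort(off[~np.isnan(off)])
                ax1.step(off, np.arange(1, len(off) + 1) / len(off), label=f"K={k}")
            ax1.set_title("consensus CDF")
            ax1.legend(fontsize=7)
            ax2.plot(cons.k_range, [cons.delta_area[k] for k in cons.k_range], "o-")
            ax2.axvline(cons.chosen_k, color="r", ls="--", lw=0.8)
            ax2.set_title("relative delta area (elbow)")
            ax2.set_xlabel("K")
            path = outdir / "consensus_diagnostics.pdf"
            fig.savefig(path, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
        except Exception:  # pragma: no cover
            logger.exception("consensus diagnostics failed")
    return written
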