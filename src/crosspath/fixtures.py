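"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator plants a known truth at every stage so that each step — and the
end-to-end run — can be validated without any external download:

* gene-set *families* with controlled within-family gene sharing (planted
  kappa-clustering truth), plus unrelated null pathways;
* per-study gene-level p-values where chosen families are enriched in chosen
  studies (planted AW-Fisher weight patterns: an all-studies family is
  consensual, a partial-studies family differential), DE p-values drawn from
  Beta(a, 1) with a < 1 and null genes i.i.d. Uniform(0, 1);
* names and descriptions carrying an injected keyword per family over
  background noise phrases (planted text-mining truth), description lengths
  drawn from a Poisson distribution.

Defaults emulate a six-study two-tissue/three-diagnosis design: 6 studies,
2,000 genes, 60 pathways (3 families of 10 plus 30 null sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geneset_io import GeneSet, GeneSetCollection

__all__ = ["FixtureSpec", "make_collection", "make_gene_pvalues", "worked_example_pvec"]

# vocabulary pools for background noise phrases (combined pairwise, they give
# ~900 distinct multi-word noun phrases that survive normalization)
_BG_ADJ = [
    "ribosomal", "cytosolic", "nuclear", "synaptic", "axonal", "dendritic",
    "glial", "cortical", "hepatic", "renal", "cardiac", "vascular",
    "epithelial", "mesenchymal", "embryonic", "catalytic", "enzymatic",
    "metabolic", "oxidative", "glycolytic", "lysosomal", "peroxisomal",
    "microtubule", "cytoskeletal", "chromosomal", "telomeric", "histone",
    "transcriptional", "translational", "posttranslational", "intracellular",
]
_BG_NOUN = [
    "phosphorylation", "dephosphorylation", "acetylation", "methylation",
    "glycosylation", "sumoylation", "translocation", "polymerization",
    "depolymerization", "biogenesis", "catabolism", "anabolism", "homeostasis",
    "exocytosis", "endocytosis", "autophagy", "chemotaxis", "adhesion",
    "proliferation", "differentiation", "senescence", "remodeling",
    "trafficking", "secretion", "oxidation", "reduction", "elongation",
    "initiation", "termination", "splicing",
]
_NAME_HEADS = [
    "regulation", "induction", "activation", "modulation", "suppression",
    "maintenance", "assembly", "disassembly", "stabilization", "attenuation",
]


@dataclass
class FixtureSpec:
    """Parameters of the planted-truth generator.

    ``enrichment_design`` maps family index -> tuple of enriched study
    indices; the default plants one consensual family (all six studies), one
    differential family matching the (0,0,1,1,1,1) motif, and one
    differential family with the complementary (1,1,0,0,0,0) motif.
    ``de_beta_a`` is the Beta(a, 1) shape for DE gene p-values (smaller =
    stronger signal); ``core_frac`` the fraction of each member pathway
    shared within its family (the planted effect size of enrichment, since
    core genes carry the DE signal).
    """

    n_studies: int = 6
    n_genes: int = 2000
    n_families: int = 3
    family_size: int = 10
    n_null_pathways: int = 30
    genes_per_pathway: int = 40
    core_frac: float = 0.6
    de_beta_a: float = 0.05
    mean_desc_phrases: int = 15
    keyword_name_frac: float = 0.8
    enrichment_design: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {0: (0, 1, 2, 3, 4, 5), 1: (2, 3, 4, 5), 2: (0, 1)}
    )
    keywords: tuple[str, ...] = (
        "apoptosis",
        "ubiquitin proteasome system",
        "electron transport chain",
    )
    seed: int = 0

    def validate(self) -> None:
        core = int(round(self.core_frac * self.genes_per_pathway))
        if not 0 < core <= self.genes_per_pathway:
            raise ValueError("core_frac must put at least one gene in the family core")
        if self.n_families * self.genes_per_pathway * 2 > self.n_genes:
            raise ValueError("gene universe too small for the requested families")
        if any(f >= self.n_families for f in self.enrichment_design):
            raise ValueError("enrichment_design references a nonexistent family")
        if any(s >= self.n_studies for ss in self.enrichment_design.values() for s in ss):
            raise ValueError("enrichment_design references a nonexistent study")
        if len(self.keywords) < self.n_families:
            raise ValueError("need one injected keyword per family")

    @property
    def study_labels(self) -> list[str]:
        return [f"study{j+1}" for j in range(self.n_studies)]

    def family_weight_pattern(self, fam: int) -> tuple[int, ...]:
        """The planted 0/1 study weight pattern for a family."""
        enriched = set(self.enrichment_design.get(fam, ()))
        return tuple(1 if j in enriched else 0 for j in range(self.n_studies))


def _background_phrases(rng: np.random.Generator, n: int) -> list[str]:
    adj = rng.choice(len(_BG_ADJ), size=n)
    noun = rng.choice(len(_BG_NOUN), size=n)
    return [f"{_BG_ADJ[a]} {_BG_NOUN[b]}" for a, b in zip(adj, noun)]


def _family_core_genes(spec: FixtureSpec) -> list[list[str]]:
    """Disjoint core gene blocks, one per family (deterministic layout)."""
    core = int(round(spec.core_frac * spec.genes_per_pathway))
    return [
        [f"G{f * core + i + 1:05d}" for i in range(core)]
        for f in range(spec.n_families)
    ]


def make_collection(spec: FixtureSpec | None = None) -> GeneSetCollection:
    """Gene-set families with controlled overlap, keyword-bearing text, nulls.

    Family members share a core gene block (fraction ``core_frac`` of each
    set) and draw the remainder at random, so within-family kappa exceeds
    between-family kappa by construction.  The family keyword is injected
    into ``keyword_name_frac`` of member names (as a standalone noun chunk)
    and into every member description; null pathways get background phrases
    only.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    universe = [f"G{i+1:05d}" for i in range(spec.n_genes)]
    cores = _family_core_genes(spec)
    reserved = {g for c in cores for g in c}
    free = [g for g in universe if g not in reserved]
    sets: list[GeneSet] = []

    for f in range(spec.n_families):
        keyword = spec.keywords[f]
        n_with_kw = int(np.ceil(spec.keyword_name_frac * spec.family_size))
        for m in range(spec.family_size):
            extra = rng.choice(len(free), size=spec.genes_per_pathway - len(cores[f]), replace=False)
            genes = frozenset(cores[f]) | {free[i] for i in extra}
            head = _NAME_HEADS[m % len(_NAME_HEADS)]
            if m < n_with_kw:
                name = f"{head} of {keyword}"
            else:
                name = f"{head} of {_background_phrases(rng, 1)[0]}"
            n_bg = 1 + rng.poisson(spec.mean_desc_phrases)
            phrases = _background_phrases(rng, n_bg) + [keyword]
            desc = "This pathway involves " + ", ".join(phrases) + "."
            sets.append(
                GeneSet(id=f"FAM{f+1}_{m+1:02d}", genes=genes, name=name, description=desc)
            )

    for k in range(spec.n_null_pathways):
        idx = rng.choice(len(universe), size=spec.genes_per_pathway, replace=False)
        genes = frozenset(universe[i] for i in idx)
        head = _NAME_HEADS[int(rng.integers(len(_NAME_HEADS)))]
        name = f"{head} of {_background_phrases(rng, 1)[0]}"
        n_bg = 1 + rng.poisson(spec.mean_desc_phrases)
        desc = "This pathway involves " + ", ".join(_background_phrases(rng, n_bg)) + "."
        sets.append(GeneSet(id=f"NULL_{k+1:02d}", genes=genes, name=name, description=desc))

    return GeneSetCollection(sets=tuple(sets), universe=frozenset(universe))


def make_gene_pvalues(spec: FixtureSpec | None = None) -> pd.DataFrame:
    """Per-study gene-level DE p-value matrix with planted enrichment.

    Null genes draw i.i.d. Uniform(0, 1); in each enriched (family, study)
    cell the family's core genes draw Beta(a, 1) (stochastically small), so
    member pathways are over-represented among the top DE genes exactly in
    the designed studies and the planted AW weight patterns are recoverable.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    universe = [f"G{i+1:05d}" for i in range(spec.n_genes)]
    vals = rng.random((spec.n_genes, spec.n_studies))
    gene_idx = {g: i for i, g in enumerate(universe)}
    cores = _family_core_genes(spec)
    for fam, studies in spec.enrichment_design.items():
        rows = [gene_idx[g] for g in cores[fam]]
        for s in studies:
            vals[rows, s] = rng.beta(spec.de_beta_a, 1.0, size=len(rows))
    vals = np.clip(vals, 1e-300, 1.0)
    df = pd.DataFrame(vals, index=pd.Index(universe, name="gene"), columns=spec.study_labels)
    return df


def worked_example_pvec() -> np.ndarray:
    """Six per-study enrichment p-values of the kinase-activity worked example,
    kept as a regression fixture for the weight search and the combined
    p-value."""
    return np.array([0.26922, 0.17773, 0.06485, 2.04e-5, 0.00449, 0.018922])


def write_demo_workspace(outdir, spec: FixtureSpec | None = None):
    """Materialize a demo workspace on disk: GMT, description table and
    gene-level p-value TSV, all regenerable from the spec's seed.

    Returns the three file paths (gmt, descriptions, gene_pvalues).
    """
    from pathlib import Path

    from .geneset_io import write_gmt

    spec = spec or FixtureSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coll = make_collection(spec)
    gmt = outdir / "collection.gmt"
    write_gmt(coll, gmt)
    desc = outdir / "descriptions.tsv"
    pd.DataFrame(
        {"id": coll.ids, "name": [s.name for s in coll.sets],
         "description": [s.description for s in coll.sets]}
    ).to_csv(desc, sep="\t", index=False)
    gp = outdir / "gene_pvalues.tsv"
    make_gene_pvalues(spec).to_csv(gp, sep="\t")
    return gmt, desc, gp
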