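"""Keyword annotation of pathway clusters by penalized permutation text mining.

Pathway names are concise and curated; descriptions are long and noisy.  The
annotation statistic therefore scores a noun phrase i in pathway j as

    x_ij = 1                     if the phrase occurs in the pathway NAME,
    x_ij = exp(-alpha * |w_j|)   if it occurs only in the DESCRIPTION, where
                                 |w_j| is the number of unique noun phrases in
                                 that description,
    x_ij = 0                     otherwise,

so a hit in a 200-phrase description is worth far less than a hit in a name.
The cluster statistic T_i(C) = sum_{j in C} x_ij is compared against
same-size random pathway subsets drawn from the whole collection (a
permutation null), with Benjamini-Hochberg correction within each cluster.
At alpha = 0 every hit scores 1 and the test collapses to a Fisher-exact
style count comparison.

Phrase matrices are binary per pathway (a phrase occurring six times across
three descriptions counts three, one per pathway).  The phrase vocabulary is
built by a deterministic rule-based noun-phrase chunker (an industrial
extractor can be plugged in), followed by stop-word removal, last-token
singularization, a common-English-word filter on single-word phrases,
optional synonym merging, and pruning of phrases supported by fewer than two
pathways.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .aw_fisher import bh_adjust
from .clustering import SCATTERED, ClusterAssignment
from .geneset_io import GeneSetCollection

__all__ = [
    "PhraseResources",
    "load_default_resources",
    "extract_noun_phrases",
    "normalize_phrase",
    "PhraseMatrices",
    "build_phrase_matrices",
    "merge_synonyms",
    "prune_rare_phrases",
    "PenalizedScores",
    "penalized_scores",
    "cluster_statistic",
    "permutation_test",
    "annotate_clusters",
]


# ---------------------------------------------------------------------------
# resources and the rule-based chunker

#: Tokens that terminate a noun chunk: pronouns, auxiliaries and common
#: (inflected) verbs, prepositions and conjunctions.  Determiners are NOT
#: boundaries — they stay inside the raw chunk and fall to stop-word removal.
_BOUNDARY_WORDS = frozenset(
    """
    i you he she it we they me him her us them my your his its our their
    this that these those who whom whose which what where when why how
    is are was were be been being am do does did done doing have has had
    having can could may might must shall should will would
    and or but nor so yet if than then because while although though
    of in on at to from by with for into onto through during between among
    under over across after before against along around toward towards
    upon via per within without despite unless until since as
    not also both either neither each very more most other another such
    catalyzes catalyze catalyzed catalyzing possesses possess possessed
    encodes encode encoded encoding regulates regulate regulated regulating
    mediates mediate mediated mediating involves involve involved involving
    requires require required requiring includes include included including
    contains contain contained containing comprises comprise comprising
    consists consist consisting occurs occur occurred occurring
    participates participate participating activates activate activated
    inhibits inhibit inhibited promotes promote promoted
    leads lead leading results resulting plays play played playing
    acts act acted acting binds bind bound binding represents represent
    represented belongs belong belonging depends depend depending
    generates generate generated produces produced
    functions functioning known called named together also
    """.split()
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'/+-]*")

#: Irregular plural -> singular exceptions applied before the suffix rules.
_PLURAL_EXCEPTIONS = {
    "mitochondria": "mitochondrion",
    "bacteria": "bacterium",
    "nuclei": "nucleus",
    "analyses": "analysis",
    "syntheses": "synthesis",
    "hypotheses": "hypothesis",
    "matrices": "matrix",
    "indices": "index",
    "vertices": "vertex",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "stimuli": "stimulus",
    "fungi": "fungus",
    "loci": "locus",
    "cilia": "cilium",
    "flagella": "flagellum",
    "ganglia": "ganglion",
    "mitoses": "mitosis",
    "apoptoses": "apoptosis",
    "axes": "axis",
    "taxa": "taxon",
    "genera": "genus",
    "viruses": "virus",
    "mice": "mouse",
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "species": "species",
    "data": "data",
}


def singularize(token: str) -> str:
    """Rule-based English plural -> singular for the head noun of a phrase."""
    t = token.lower()
    if t in _PLURAL_EXCEPTIONS:
        return _PLURAL_EXCEPTIONS[t]
    if len(t) > 3 and t.endswith("ies"):
        return t[:-3] + "y"
    if len(t) > 4 and (t.endswith("sses") or t.endswith("xes") or t.endswith("ches") or t.endswith("shes") or t.endswith("zes")):
        return t[:-2]
    if t.endswith("ss") or t.endswith("us") or t.endswith("is"):
        return t
    if len(t) > 2 and t.endswith("s") and not t.endswith("'s"):
        return t[:-1]
    return t


@dataclass
class PhraseResources:
    """Bundled text-mining resources: stop words, common-word filter, chunker.

    ``extractor`` maps raw text to a list of raw noun phrases; the default is
    the bundled deterministic chunker, and any callable with the same
    signature (e.g. an adapter over an industrial NLP pipeline) can be
    substituted.  ``synonyms`` yields unordered pairs of normalized phrases to
    merge.
    """

    stop_words: frozenset[str]
    common_words: frozenset[str]
    extractor: Callable[[str], list[str]] | None = None
    synonyms: Sequence[tuple[str, str]] = ()


def _load_wordlist(name: str) -> frozenset[str]:
    text = (importlib_resources.files("crosspath") / "resources" / name).read_text()
    return frozenset(
        line.strip().lower() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def load_default_resources(synonyms: Sequence[tuple[str, str]] = ()) -> PhraseResources:
    return PhraseResources(
        stop_words=_load_wordlist("stopwords.txt"),
        common_words=_load_wordlist("common_words.txt"),
        extractor=None,
        synonyms=tuple(synonyms),
    )


def extract_noun_phrases(text: str, extractor: Callable[[str], list[str]] | None = None) -> list[str]:
    """Unique raw noun phrases of a text, in order of first appearance.

    The default chunker splits the token stream at punctuation and at
    function-word/verb boundaries; each maximal run of remaining tokens is a
    raw noun chunk (determiners included — they are stripped later during
    normalization).
    """
    if extractor is not None:
        phrases = extractor(text)
    else:
        phrases = []
        for segment in re.split(r"[.,;:!?()\[\]{}\"]", text):
            chunk: list[str] = []
            for tok in _TOKEN_RE.findall(segment):
                if tok.lower() in _BOUNDARY_WORDS and not tok.isupper():
                    if chunk:
                        phrases.append(" ".join(chunk))
                    chunk = []
                else:
                    chunk.append(tok)
            if chunk:
                phrases.append(" ".join(chunk))
    seen: set[str] = set()
    out = []
    for ph in phrases:
        if ph and ph not in seen:
            seen.add(ph)
            out.append(ph)
    return out


def normalize_phrase(phrase: str, resources: PhraseResources) -> str | None:
    """Lowercase, strip stop words, singularize the head noun, filter commons.

    Returns the normalized phrase, or None (DROP) when nothing informative
    remains: all tokens were stop words, or a single-word phrase is on the
    common-English-word list.
    """
    tokens = [t.lower() for t in _TOKEN_RE.findall(phrase)]
    tokens = [t for t in tokens if t not in resources.stop_words]
    if not tokens:
        return None
    tokens[-1] = singularize(tokens[-1])
    if len(tokens) == 1 and tokens[0] in resources.common_words:
        return None
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# phrase-pathway matrices


@dataclass
class PhraseMatrices:
    """Binary phrase x pathway incidence for names (v) and descriptions (w).

    Entries record presence per pathway, never occurrence counts.  ``w``
    column sums give the description length |w_j| used by the penalty.
    """

    phrases: list[str]
    pathway_ids: list[str]
    v: np.ndarray  # names
    w: np.ndarray  # descriptions

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=bool)
        self.w = np.asarray(self.w, dtype=bool)
        expected = (len(self.phrases), len(self.pathway_ids))
        if self.v.shape != expected or self.w.shape != expected:
            raise ValueError("incidence matrices must be phrases x pathways")

    @property
    def description_lengths(self) -> np.ndarray:
        """|w_j|: unique noun phrases in each pathway's description."""
        return self.w.sum(axis=0)

    @property
    def support(self) -> np.ndarray:
        """Number of pathways in which each phrase occurs (name OR description)."""
        return (self.v | self.w).sum(axis=1)


def build_phrase_matrices(coll: GeneSetCollection, resources: PhraseResources) -> PhraseMatrices:
    """Normalized phrase incidence over pathway names and descriptions."""
    name_sets: list[set[str]] = []
    desc_sets: list[set[str]] = []
    for s in coll.sets:
        name_sets.append(
            {p for raw in extract_noun_phrases(s.name, resources.extractor)
             if (p := normalize_phrase(raw, resources)) is not None}
        )
        desc_sets.append(
            {p for raw in extract_noun_phrases(s.description, resources.extractor)
             if (p := normalize_phrase(raw, resources)) is not None}
        )
    vocab = sorted(set().union(*name_sets, *desc_sets)) if coll.sets else []
    idx = {p: i for i, p in enumerate(vocab)}
    v = np.zeros((len(vocab), len(coll)), dtype=bool)
    w = np.zeros_like(v)
    for j, (ns, ds) in enumerate(zip(name_sets, desc_sets)):
        for p in ns:
            v[idx[p], j] = True
        for p in ds:
            w[idx[p], j] = True
    return PhraseMatrices(phrases=vocab, pathway_ids=list(coll.ids), v=v, w=w)


def merge_synonyms(
    mats: PhraseMatrices, synonym_source: Iterable[tuple[str, str]]
) -> PhraseMatrices:
    """OR-merge synonym phrase rows, keeping the more frequent phrase.

    For each synonym pair present in the vocabulary, the row with lower total
    pathway occurrence is merged (elementwise OR, applied to both v and w)
    into the higher-occurrence row and deleted.  Equal occurrence keeps the
    lexicographically smaller phrase.  Pairs naming unknown (or already
    merged) phrases are ignored.
    """
    phrases = list(mats.phrases)
    v = mats.v.copy()
    w = mats.w.copy()
    alive = {p: i for i, p in enumerate(phrases)}
    for p1, p2 in sorted((tuple(sorted(pair)) for pair in synonym_source)):
        if p1 not in alive or p2 not in alive or p1 == p2:
            continue
        i1, i2 = alive[p1], alive[p2]
        occ1 = int((v[i1] | w[i1]).sum())
        occ2 = int((v[i2] | w[i2]).sum())
        # keep the more frequent phrase; ties keep the lexicographically
        # smaller one (p1 <= p2 by construction)
        keep, drop = (i2, i1) if occ2 > occ1 else (i1, i2)
        v[keep] |= v[drop]
        w[keep] |= w[drop]
        del alive[phrases[drop]]
    rows = sorted(alive.values())
    return PhraseMatrices(
        phrases=[phrases[i] for i in rows],
        pathway_ids=list(mats.pathway_ids),
        v=v[rows],
        w=w[rows],
    )


def prune_rare_phrases(mats: PhraseMatrices, min_support: int = 2) -> PhraseMatrices:
    """Drop phrases occurring (name OR description) in fewer than 2 pathways."""
    keep = mats.support >= min_support
    if not keep.any():
        raise ValueError("all phrases are rarer than the support threshold; corpus too small")
    rows = np.flatnonzero(keep)
    return PhraseMatrices(
        phrases=[mats.phrases[i] for i in rows],
        pathway_ids=list(mats.pathway_ids),
        v=mats.v[rows],
        w=mats.w[rows],
    )


# ---------------------------------------------------------------------------
# penalized scores and the permutation test


@dataclass
class PenalizedScores:
    """Length-penalized phrase scores x_ij in [0, 1] (phrases x pathways)."""

    phrases: list[str]
    pathway_ids: list[str]
    x: np.ndarray
    alpha: float

    def column_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.pathway_ids)}
        missing = [p for p in ids if p not in lookup]
        if missing:
            raise KeyError(f"pathways not in score matrix: {missing[:5]}")
        return np.array([lookup[p] for p in ids], dtype=int)


def penalized_scores(mats: PhraseMatrices, alpha: float = 0.05) -> PenalizedScores:
    """x_ij = 1 for a name hit, exp(-alpha |w_j|) for a description-only hit.

    alpha >= 0 controls the penalty on long descriptions; alpha = 0 scores
    every hit 1 (the plain-counting / Fisher-exact regime).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    decay = np.exp(-alpha * mats.description_lengths.astype(float))
    x = mats.v * 1.0 + (~mats.v & mats.w) * decay[None, :]
    return PenalizedScores(
        phrases=list(mats.phrases), pathway_ids=list(mats.pathway_ids), x=x, alpha=alpha
    )


def cluster_statistic(scores: PenalizedScores, cluster: Sequence[str]) -> pd.Series:
    """T_i(C) = sum of x_ij over cluster pathways, for every phrase i."""
    cluster = list(cluster)
    if not cluster:
        raise ValueError("empty cluster")
    cols = scores.column_index(cluster)
    return pd.Series(scores.x[:, cols].sum(axis=1), index=scores.phrases, name="T")


def permutation_test(
    scores: PenalizedScores,
    cluster: Sequence[str],
    B: int = 10_000,
    seed: int | None = None,
    background: Sequence[str] | None = None,
    batch: int = 500,
) -> pd.Series:
    """Upper-tail permutation p-value per phrase.

    B random same-size pathway subsets S_b are drawn (without replacement
    within a draw) from the background — all pathways of the score matrix by
    default — and p_i = (1 + #{b : T_i(S_b) >= T_i(C)}) / (B + 1).  One
    shared permutation stream serves all phrases.  Bit-for-bit reproducible
    given (seed, B, background order).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    cluster = list(cluster)
    bg_ids = list(background) if background is not None else list(scores.pathway_ids)
    if not set(cluster) <= set(bg_ids):
        raise ValueError("cluster must be a subset of the permutation background")
    if len(bg_ids) <= len(cluster):
        raise ValueError("background must be strictly larger than the cluster")
    bg_cols = scores.column_index(bg_ids)
    t_obs = cluster_statistic(scores, cluster).to_numpy()
    c = len(cluster)
    rng = np.random.default_rng(seed)
    x_bg = scores.x[:, bg_cols]
    exceed = np.zeros(len(scores.phrases), dtype=np.int64)
    done = 0
    while done < B:
        nb = min(batch, B - done)
        # nb independent subsets of size c, via argpartition of random keys
        keys = rng.random((nb, len(bg_ids)))
        subsets = np.argpartition(keys, c - 1, axis=1)[:, :c]
        t_null = x_bg[:, subsets].sum(axis=2)  # phrases x nb
        exceed += (t_null >= t_obs[:, None]).sum(axis=1)
        done += nb
    p = (1 + exceed) / (B + 1)
    return pd.Series(p, index=scores.phrases, name="p")


def annotate_clusters(
    scores: PenalizedScores,
    assignment: ClusterAssignment,
    B: int = 10_000,
    q_cutoff: float = 0.05,
    seed: int | None = None,
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Keyword annotation of every tight cluster (and the scattered set).

    Per cluster: permutation test over all phrases, BH correction within the
    cluster, ranking by (q ascending, T descending).  The scattered set is
    annotated too but flagged secondary.  Returns one row per
    (cluster, phrase) with columns T, p, q, support and significant.
    """
    clusters = dict(assignment.clusters)
    if not clusters:
        raise ValueError("assignment contains no tight cluster")
    if assignment.scattered:
        clusters[SCATTERED] = assignment.scattered
    support = pd.Series((scores.x > 0).sum(axis=1), index=scores.phrases)
    frames = []
    rng = np.random.default_rng(seed)
    for cid in sorted(clusters, key=str):
        members = clusters[cid]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        t = cluster_statistic(scores, members)
        p = permutation_test(scores, members, B=B, seed=sub_seed, background=background)
        df = pd.DataFrame(
            {
                "cluster": str(cid),
                "phrase": scores.phrases,
                "T": t.to_numpy(),
                "p": p.to_numpy(),
                "q": bh_adjust(p.to_numpy()),
                "support": support.to_numpy(),
                "secondary": cid == SCATTERED,
            }
        )
        df["significant"] = df["q"] < q_cutoff
        df = df.sort_values(["q", "T"], ascending=[True, False], kind="stable")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
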