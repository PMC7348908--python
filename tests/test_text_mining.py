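import numpy as np
import pytest
from scipy import stats

from crosspath.geneset_io import GeneSet, GeneSetCollection
from crosspath.text_mining import (
    PhraseMatrices,
    annotate_clusters,
    build_phrase_matrices,
    cluster_statistic,
    extract_noun_phrases,
    load_default_resources,
    merge_synonyms,
    normalize_phrase,
    penalized_scores,
    permutation_test,
    prune_rare_phrases,
    singularize,
)
from crosspath.clustering import ClusterAssignment

import pandas as pd


@pytest.fixture(scope="module")
def resources():
    return load_default_resources()


def make_text_collection(named, universe_size=10):
    """Collection from (id, name, description) triples; genes are dummies."""
    genes = [f"g{i}" for i in range(universe_size)]
    sets = tuple(
        GeneSet(id=i, genes=frozenset(genes[:3]), name=n, description=d) for i, n, d in named
    )
    return GeneSetCollection(sets=sets, universe=frozenset(genes))


class TestExtraction:
    def test_empty_text_gives_no_phrases(self):
        assert extract_noun_phrases("") == []

    def test_concise_name_is_one_phrase(self):
        assert extract_noun_phrases("NADH dehydrogenase complex") == [
            "NADH dehydrogenase complex"
        ]

    def test_verb_and_preposition_boundaries(self):
        phrases = extract_noun_phrases(
            "It catalyzes the transfer of a pair of electrons from NADH to a quinone"
        )
        assert phrases == ["the transfer", "a pair", "electrons", "NADH", "a quinone"]

    def test_punctuation_splits_chunks(self):
        assert extract_noun_phrases("electron transport, ATP synthesis") == [
            "electron transport",
            "ATP synthesis",
        ]

    def test_duplicates_within_text_collapsed(self):
        assert extract_noun_phrases("apoptosis, apoptosis, apoptosis") == ["apoptosis"]

    def test_custom_extractor_plugs_in(self):
        assert extract_noun_phrases("whatever", extractor=lambda t: ["x", "x", "y"]) == ["x", "y"]


class TestNormalization:
    def test_stopwords_removed_and_head_singularized(self, resources):
        assert normalize_phrase("the electron transport chains", resources) == (
            "electron transport chain"
        )

    def test_all_stopword_phrase_dropped(self, resources):
        assert normalize_phrase("a that", resources) is None

    def test_common_single_word_filter_consistent_with_bundled_list(self, resources):
        out = normalize_phrase("cells", resources)
        if "cell" in resources.common_words:
            assert out is None
        else:
            assert out == "cell"

    def test_multiword_phrases_escape_common_filter(self, resources):
        # "cell" alone is common, "T cell" is not
        assert normalize_phrase("T cells", resources) == "t cell"

    @pytest.mark.parametrize(
        "plural,singular",
        [
            ("mitochondria", "mitochondrion"),
            ("complexes", "complex"),
            ("processes", "process"),
            ("kinases", "kinase"),
            ("activities", "activity"),
            ("viruses", "virus"),
            ("apoptosis", "apoptosis"),
            ("analyses", "analysis"),
        ],
    )
    def test_singularization_rules(self, plural, singular):
        assert singularize(plural) == singular


class TestMatrices:
    def test_presence_counted_per_pathway_not_per_occurrence(self, resources):
        # phrase appears 3+2+1 times across three descriptions -> support 3
        coll = make_text_collection(
            [
                ("P1", "x1 y1", "T cells, T cells, T cells"),
                ("P2", "x2 y2", "T cells and T cells"),
                ("P3", "x3 y3", "T cells"),
                ("P4", "x4 y4", "nothing here"),
            ]
        )
        mats = build_phrase_matrices(coll, resources)
        i = mats.phrases.index("t cell")
        assert mats.w[i].sum() == 3

    def test_empty_description_gives_empty_column(self, resources):
        coll = make_text_collection([("P1", "alpha synuclein", ""), ("P2", "beta arrestin", "")])
        mats = build_phrase_matrices(coll, resources)
        assert mats.w.sum() == 0
        assert mats.v.sum() == 2

    def test_hand_built_golden_corpus(self, resources):
        coll = make_text_collection(
            [
                ("P1", "apoptosis regulation", "the caspase cascade"),
                ("P2", "apoptosis regulation", "a caspase cascade, apoptosis regulation"),
            ]
        )
        mats = build_phrase_matrices(coll, resources)
        assert sorted(mats.phrases) == ["apoptosis regulation", "caspase cascade"]
        v = {p: mats.v[mats.phrases.index(p)].tolist() for p in mats.phrases}
        w = {p: mats.w[mats.phrases.index(p)].tolist() for p in mats.phrases}
        assert v == {"apoptosis regulation": [True, True], "caspase cascade": [False, False]}
        assert w == {"apoptosis regulation": [False, True], "caspase cascade": [True, True]}


class TestSynonymsAndPruning:
    def _mats(self):
        phrases = ["tumor", "tumour", "other"]
        v = np.array([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0], [1, 1, 0, 0, 0]], dtype=bool)
        w = np.array([[0, 0, 0, 0, 0], [1, 1, 0, 0, 0], [0, 0, 0, 0, 0]], dtype=bool)
        return PhraseMatrices(phrases=phrases, pathway_ids=list("abcde"), v=v, w=w)

    def test_lower_occurrence_merged_into_higher(self):
        out = merge_synonyms(self._mats(), [("tumour", "tumor")])
        assert "tumour" not in out.phrases
        i = out.phrases.index("tumor")
        assert out.v[i].tolist() == [True] * 5
        assert out.w[i].tolist() == [True, True, False, False, False]

    def test_no_synonyms_is_identity(self):
        mats = self._mats()
        out = merge_synonyms(mats, [])
        assert out.phrases == mats.phrases
        assert (out.v == mats.v).all() and (out.w == mats.w).all()

    def test_equal_occurrence_keeps_lexicographically_smaller(self):
        phrases = ["beta", "alpha"]
        v = np.array([[1, 1], [1, 1]], dtype=bool)
        w = np.zeros_like(v)
        mats = PhraseMatrices(phrases=phrases, pathway_ids=["x", "y"], v=v, w=w)
        out = merge_synonyms(mats, [("beta", "alpha")])
        assert out.phrases == ["alpha"]

    def test_prune_uses_or_of_name_and_description_support(self):
        # phrase in P1's name AND description counts once -> support 1 -> pruned
        phrases = ["solo", "pair"]
        v = np.array([[1, 0], [1, 0]], dtype=bool)
        w = np.array([[1, 0], [0, 1]], dtype=bool)
        mats = PhraseMatrices(phrases=phrases, pathway_ids=["P1", "P2"], v=v, w=w)
        out = prune_rare_phrases(mats)
        assert out.phrases == ["pair"]

    def test_prune_empty_result_rejected(self):
        phrases = ["solo"]
        v = np.array([[1, 0]], dtype=bool)
        w = np.zeros_like(v)
        with pytest.raises(ValueError):
            prune_rare_phrases(PhraseMatrices(phrases, ["P1", "P2"], v, w))


class TestPenalizedScores:
    def _mats(self, desc_len):
        # one phrase in P1's name; one phrase only in P2's description of length desc_len
        phrases = [f"ph{i}" for i in range(desc_len)] + ["namehit"]
        v = np.zeros((desc_len + 1, 2), dtype=bool)
        w = np.zeros_like(v)
        v[-1, 0] = True
        w[:desc_len, 1] = True
        return PhraseMatrices(phrases, ["P1", "P2"], v, w)

    def test_name_hit_scores_one_regardless_of_description(self):
        sc = penalized_scores(self._mats(20), alpha=0.05)
        assert sc.x[-1, 0] == 1.0

    def test_description_hit_decays_with_length(self):
        sc = penalized_scores(self._mats(20), alpha=0.05)
        assert sc.x[0, 1] == pytest.approx(np.exp(-1.0))

    def test_alpha_zero_reduces_to_plain_counting(self):
        sc = penalized_scores(self._mats(20), alpha=0.0)
        assert set(np.unique(sc.x)) <= {0.0, 1.0}
        assert sc.x[0, 1] == 1.0

    def test_score_monotone_in_length_and_alpha_and_bounded(self):
        s_short = penalized_scores(self._mats(5), alpha=0.05).x[0, 1]
        s_long = penalized_scores(self._mats(50), alpha=0.05).x[0, 1]
        s_harsh = penalized_scores(self._mats(5), alpha=0.5).x[0, 1]
        assert s_long < s_short and s_harsh < s_short
        for mats in (self._mats(5), self._mats(50)):
            x = penalized_scores(mats, alpha=0.05).x
            assert (x >= 0).all() and (x <= 1).all()

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            penalized_scores(self._mats(5), alpha=-0.1)


def names_only_collection(n_paths=50, n_keyword=8, seed=0):
    """Corpus where phrases live in names only; keyword concentrated up front."""
    rng = np.random.default_rng(seed)
    vocab = [f"term{i} factor" for i in range(30)]
    triples = []
    for j in range(n_paths):
        extra = " , ".join(rng.choice(vocab, 3, replace=False))
        name = f"ubiquitin ligase , {extra}" if j < n_keyword else extra
        triples.append((f"P{j:02d}", name, ""))
    return make_text_collection(triples)


class TestPermutationTest:
    def test_constant_phrase_has_p_one(self, resources):
        coll = names_only_collection()
        mats = build_phrase_matrices(coll, resources)
        # add an everywhere-present phrase
        mats = PhraseMatrices(
            mats.phrases + ["everywhere"],
            mats.pathway_ids,
            np.vstack([mats.v, np.ones((1, len(mats.pathway_ids)), dtype=bool)]),
            np.vstack([mats.w, np.zeros((1, len(mats.pathway_ids)), dtype=bool)]),
        )
        sc = penalized_scores(mats, alpha=0.05)
        p = permutation_test(sc, mats.pathway_ids[:8], B=500, seed=0)
        assert p["everywhere"] == 1.0

    def test_cluster_exclusive_phrase_reaches_minimum_p(self, resources):
        coll = names_only_collection(n_paths=50, n_keyword=8)
        mats = build_phrase_matrices(coll, resources)
        sc = penalized_scores(mats, alpha=0.05)
        cluster = [f"P{j:02d}" for j in range(8)]
        B = 2000
        p = permutation_test(sc, cluster, B=B, seed=3)
        assert p["ubiquitin ligase"] == pytest.approx(1 / (B + 1))

    def test_reproducible_bit_for_bit(self, resources):
        coll = names_only_collection()
        mats = build_phrase_matrices(coll, resources)
        sc = penalized_scores(mats, alpha=0.05)
        cluster = [f"P{j:02d}" for j in range(8)]
        p1 = permutation_test(sc, cluster, B=1000, seed=11)
        p2 = permutation_test(sc, cluster, B=1000, seed=11)
        assert (p1 == p2).all()

    def test_alpha_zero_names_only_matches_hypergeometric(self, resources):
        """At alpha=0 on a names-only corpus the permutation null is sampling
        without replacement, so p-values match the hypergeometric tail."""
        coll = names_only_collection(n_paths=40, n_keyword=6, seed=5)
        mats = prune_rare_phrases(build_phrase_matrices(coll, resources))
        sc = penalized_scores(mats, alpha=0.0)
        cluster = [f"P{j:02d}" for j in range(6)]
        B = 10_000
        p = permutation_test(sc, cluster, B=B, seed=9)
        t_obs = cluster_statistic(sc, cluster)
        N, c = 40, 6
        for i, phrase in enumerate(sc.phrases):
            K = int((sc.x[i] > 0).sum())
            exact = stats.hypergeom.sf(int(round(t_obs[phrase])) - 1, N, K, c)
            se = np.sqrt(max(exact * (1 - exact), 1e-12) / B)
            assert abs(p[phrase] - exact) <= 3 * se + 2 / B, phrase


class TestRankInversion:
    def test_penalty_promotes_name_hits_over_long_description_hits(self, resources):
        """Phrase A sits in 5 names, phrase B in 5 very long descriptions:
        raw counting ties them, the penalized statistic ranks A first."""
        filler = ", ".join(f"filler term{i}" for i in range(120))
        triples = []
        for j in range(5):
            triples.append((f"A{j}", "golgi tethering", ""))
            triples.append((f"B{j}", f"name{j} thing{j}", f"distal osmolyte, {filler}"))
        for j in range(20):
            triples.append((f"N{j}", f"noise{j} unit{j}", ""))
        coll = make_text_collection(triples)
        mats = build_phrase_matrices(coll, resources)
        cluster = [f"A{j}" for j in range(5)] + [f"B{j}" for j in range(5)]
        t_raw = cluster_statistic(penalized_scores(mats, alpha=0.0), cluster)
        t_pen = cluster_statistic(penalized_scores(mats, alpha=0.05), cluster)
        assert t_raw["golgi tethering"] == pytest.approx(t_raw["distal osmolyte"])
        assert t_pen["golgi tethering"] > t_pen["distal osmolyte"] * 10


class TestAnnotateClusters:
    def test_injected_keyword_detected_with_fdr_control(self, resources):
        coll = names_only_collection(n_paths=50, n_keyword=8, seed=1)
        mats = prune_rare_phrases(build_phrase_matrices(coll, resources))
        sc = penalized_scores(mats, alpha=0.05)
        cluster_ids = [f"P{j:02d}" for j in range(10)]  # 8 keyword + 2 background
        labels = pd.Series(
            ["c1" if p in cluster_ids else "scattered" for p in mats.pathway_ids],
            index=mats.pathway_ids,
        )
        asg = ClusterAssignment(labels=labels, silhouettes=pd.Series(0.5, index=labels.index))
        ann = annotate_clusters(sc, asg, B=10_000, q_cutoff=0.05, seed=4)
        top = ann[(ann.cluster == "c1")].iloc[0]
        assert top.phrase == "ubiquitin ligase"
        assert top.q < 0.05
        assert (ann[ann.cluster == "scattered"]["secondary"]).all()

    def test_cluster_without_enriched_phrase_returns_empty_list(self, resources):
        coll = names_only_collection(n_paths=30, n_keyword=0, seed=2)
        mats = prune_rare_phrases(build_phrase_matrices(coll, resources))
        sc = penalized_scores(mats, alpha=0.05)
        labels = pd.Series(
            ["c1"] * 5 + ["c2"] * 25, index=mats.pathway_ids
        )
        asg = ClusterAssignment(labels=labels, silhouettes=pd.Series(0.5, index=labels.index))
        ann = annotate_clusters(sc, asg, B=1000, q_cutoff=0.05, seed=4)
        assert not ann[ann.cluster == "c1"]["significant"].any()
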