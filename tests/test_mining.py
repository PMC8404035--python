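import math

import pytest
from hypothesis import given, settings, strategies as st

from ontomine.mining import (
    CurationDecision,
    MiningConfig,
    MiningError,
    ReplayCurator,
    apply_decisions,
    build_documents,
    equal_frequency_bins,
    mine_synonyms,
    read_decisions,
    stratified_split,
    tfidf_rank,
    validate_split,
)
from ontomine.textprep import TokenStream
from tests.conftest import make_corpus


def brute_force_tfidf(docs, aggregate="max"):
    """Independent evaluation of smoothed, unnormalized tf-idf."""
    n = len(docs)
    vocab = sorted({t for d in docs for t in d})
    scores = {}
    for t in vocab:
        df = sum(1 for d in docs if t in d)
        idf = math.log((1 + n) / (1 + df)) + 1
        weights = [d.count(t) * idf for d in docs]
        scores[t] = max(weights) if aggregate == "max" else sum(weights)
    return scores


def streams(*token_lists):
    return [TokenStream(tuple(toks)) for toks in token_lists]


class TestTfidfRank:
    def test_single_document_double_occurrence_scores_two(self):
        ranked = tfidf_rank(streams(["pain", "pain"]))
        assert ranked.entries == (("pain", 2.0),)

    def test_term_once_in_every_document_scores_exactly_one(self):
        docs = streams(*[["uveitis", f"w{i}"] for i in range(7)])
        ranked = tfidf_rank(docs)
        assert ranked.score_of("uveitis") == pytest.approx(1.0)

    def test_equal_scores_ordered_alphabetically(self):
        ranked = tfidf_rank(streams(["zeta", "alpha"]))
        assert [t for t, _ in ranked.entries] == ["alpha", "zeta"]

    def test_all_empty_documents_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            ranked = tfidf_rank(streams([], []))
        assert len(ranked) == 0

    @settings(max_examples=150, deadline=None)
    @given(
        docs=st.lists(
            st.lists(st.sampled_from(["a", "b", "c", "d"]), max_size=10),
            min_size=1, max_size=5,
        ),
        aggregate=st.sampled_from(["max", "sum"]),
    )
    def test_agrees_with_brute_force(self, docs, aggregate):
        if all(not d for d in docs):
            return
        config = MiningConfig(aggregate=aggregate)
        ranked = tfidf_rank(streams(*docs), config)
        expected = brute_force_tfidf(docs, aggregate)
        got = dict(ranked.entries)
        assert set(got) == set(expected)
        for term, score in expected.items():
            assert got[term] == pytest.approx(score, abs=1e-9)
        # ordering: (score desc, term asc)
        keys = [(-s, t) for t, s in ranked.entries]
        assert keys == sorted(keys)


class TestStratifiedSplit:
    def _corpus(self, sizes, forum="F"):
        return make_corpus({forum: [["text"] * s for s in sizes]})

    def test_equal_frequency_bins_remainder_to_smallest(self):
        bins = equal_frequency_bins(list(range(1, 11)), 3)
        assert [len(b) for b in bins] == [4, 3, 3]
        # bins are contiguous in sorted-size order
        assert bins[0] == [0, 1, 2, 3]

    def test_uniform_100_threads_give_20_test(self):
        corpus = self._corpus([3] * 100)
        train, test = stratified_split(corpus, MiningConfig(seed=1))
        assert len(test.threads) == 20
        assert len(train.threads) == 80

    def test_union_is_input_and_disjoint(self):
        corpus = self._corpus(list(range(1, 31)))
        train, test = stratified_split(corpus, MiningConfig(seed=2))
        train_ids = {t.thread_id for t in train.threads}
        test_ids = {t.thread_id for t in test.threads}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {t.thread_id for t in corpus.threads}

    def test_each_bin_share_within_one_of_floor(self):
        sizes = list(range(1, 51))
        corpus = self._corpus(sizes)
        config = MiningConfig(n_bins=3, test_fraction=0.2, seed=7)
        _, test = stratified_split(corpus, config)
        test_sizes = sorted(t.size for t in test.threads)
        bins = equal_frequency_bins(sizes, 3)
        for b in bins:
            bin_sizes = {sizes[i] for i in b}
            got = sum(1 for s in test_sizes if s in bin_sizes)
            assert abs(got - math.floor(0.2 * len(b))) <= 1

    def test_deterministic_under_fixed_seed(self):
        corpus = self._corpus(list(range(1, 21)))
        config = MiningConfig(seed=42)
        split1 = stratified_split(corpus, config)
        split2 = stratified_split(corpus, config)
        assert split1 == split2

    def test_degenerate_small_corpus_falls_back_to_one_per_bin(self):
        corpus = self._corpus([1, 2, 3])
        config = MiningConfig(n_bins=1, test_fraction=0.2, seed=0)
        with pytest.warns(UserWarning, match="falling back"):
            _, test = stratified_split(corpus, config)
        assert len(test.threads) == 1

    def test_fewer_threads_than_bins_is_error(self):
        corpus = self._corpus([1, 2])
        with pytest.raises(MiningError, match="bins"):
            stratified_split(corpus, MiningConfig(n_bins=3, seed=0))


class TestBuildDocuments:
    def test_thread_unit_concatenates_posts(self, stopwords):
        corpus = make_corpus({"F": [["eye pain", "pains again"]]})
        docs = build_documents(corpus, MiningConfig(), stopwords)
        assert len(docs) == 1
        assert docs[0].tokens.count("pain") == 2

    def test_post_unit_one_document_per_post(self, stopwords):
        corpus = make_corpus({"F": [["a b", "c", "d", "e", "f"]]})
        docs = build_documents(corpus, MiningConfig(document_unit="post"), stopwords)
        assert len(docs) == 5

    def test_empty_corpus_gives_empty_list(self, stopwords):
        corpus = make_corpus({})
        assert build_documents(corpus, MiningConfig(), stopwords) == []


class TestApplyDecisions:
    def test_accept_removes_term_and_adds_synonym(self, toy_ontology):
        docs = streams(["humira", "eye"], ["humira"])
        decision = CurationDecision("humira", "synonym_of",
                                    target_class="OCIMIDO:00302",
                                    surface_forms=("humira",))
        onto, new_docs, rejects = apply_decisions(toy_ontology, docs, [decision])
        assert all("humira" not in d.tokens for d in new_docs)
        assert "humira" in [s.term for s in onto.classes["OCIMIDO:00302"].synonyms]
        assert rejects == set()
        # removal property: the accepted term vanishes from the next ranking
        nonempty = [d for d in new_docs if len(d)]
        if nonempty:
            assert tfidf_rank(nonempty).score_of("humira") is None

    def test_reject_keeps_documents_and_records_term(self, toy_ontology):
        docs = streams(["hospit", "eye"])
        onto, new_docs, rejects = apply_decisions(
            toy_ontology, docs, [CurationDecision("hospit", "reject")]
        )
        assert new_docs[0].tokens == docs[0].tokens
        assert rejects == {"hospit"}
        assert onto.classes == toy_ontology.classes

    def test_empty_decisions_is_identity(self, toy_ontology):
        docs = streams(["a"])
        onto, new_docs, rejects = apply_decisions(toy_ontology, docs, [])
        assert onto.classes == toy_ontology.classes
        assert [d.tokens for d in new_docs] == [d.tokens for d in docs]

    def test_new_class_creates_fresh_curie(self, toy_ontology):
        decision = CurationDecision("flare", "new_class", new_label="flare",
                                    surface_forms=("flare", "flares"))
        onto, _, _ = apply_decisions(toy_ontology, streams(["flare"]), [decision])
        new_ids = set(onto.classes) - set(toy_ontology.classes)
        assert len(new_ids) == 1
        cls = onto.classes[new_ids.pop()]
        assert cls.label == "flare"
        assert [s.term for s in cls.synonyms] == ["flares"]

    def test_unknown_target_class_raises_naming_decision(self, toy_ontology):
        decision = CurationDecision("x", "synonym_of", target_class="OCIMIDO:99999")
        with pytest.raises(KeyError, match="x"):
            apply_decisions(toy_ontology, streams(["x"]), [decision])


class TestMineSynonyms:
    def test_reject_everything_terminates_after_one_round(self, toy_ontology, stopwords):
        corpus = make_corpus(
            {"F": [["uveitis flare today"] * 2, ["drop drops dropped"],
                   ["pressure pressure"], ["steroid"], ["clinic visit"]]}
        )
        curator = ReplayCurator({})  # rejects everything
        config = MiningConfig(seed=1, n_bins=1, test_fraction=0.2)
        onto, log = mine_synonyms(corpus, toy_ontology, curator, config, stopwords)
        assert onto.classes == toy_ontology.classes
        assert log.rounds[0].n_accepted == 0
        assert log.termination_reason == "no-accepts"
        assert len([r for r in log.rounds if r.n_reviewed > 0]) == 1

    def test_threshold_above_max_score_reviews_nothing(self, toy_ontology, stopwords):
        corpus = make_corpus({"F": [["uveitis"], ["flare"], ["drop"]]})
        config = MiningConfig(seed=1, n_bins=1, score_threshold=1e6)
        onto, log = mine_synonyms(corpus, toy_ontology, ReplayCurator({}),
                                  config, stopwords)
        assert log.rounds[0].n_reviewed == 0
        assert log.termination_reason == "no-accepts"

    def test_curator_failure_returns_last_completed_state(self, toy_ontology, stopwords):
        corpus = make_corpus({"F": [["uveitis flare"], ["flare"], ["drop"]]})

        def broken_curator(review, round_no):
            raise RuntimeError("curator went home")

        config = MiningConfig(seed=1, n_bins=1)
        onto, log = mine_synonyms(corpus, toy_ontology, broken_curator,
                                  config, stopwords)
        assert onto.classes == toy_ontology.classes
        assert log.termination_reason.startswith("curator-error")

    def test_terminates_within_max_rounds_for_accept_all_curator(
        self, toy_ontology, stopwords
    ):
        corpus = make_corpus(
            {"F": [["uveitis eye flare", "drop pressure"],
                   ["flare flare steroid"], ["clinic uveitis drop"]]}
        )

        def accept_all(review, round_no):
            return [
                CurationDecision(t, "synonym_of", target_class="OCIMIDO:00213",
                                 surface_forms=(t,))
                for t, _ in review
            ]

        config = MiningConfig(seed=0, n_bins=1, max_rounds=4)
        _, log = mine_synonyms(corpus, toy_ontology, accept_all, config, stopwords)
        assert len(log.rounds) <= 4
        assert log.termination_reason in ("no-accepts", "max-rounds")


class TestValidateSplit:
    def test_identical_rankings_no_misses(self):
        ranked = tfidf_rank(streams(["uveitis", "uveitis"], ["flare"]))
        report = validate_split(ranked, ranked, accepted=set())
        assert report.candidate_misses == ()

    def test_novel_test_term_reported(self):
        train = tfidf_rank(streams(["uveitis", "uveitis"]))
        test = tfidf_rank(streams(["uveitis", "xibrom", "xibrom"]))
        report = validate_split(train, test, accepted={"uveiti"})
        assert "xibrom" in report.candidate_misses

    def test_empty_accepted_reports_all_novel_above_threshold(self):
        train = tfidf_rank(streams(["alpha"]))
        test = tfidf_rank(streams(["beta", "beta"], ["gamma", "gamma"]))
        report = validate_split(train, test, accepted=set())
        assert set(report.candidate_misses) == {"beta", "gamma"}


def test_decision_file_roundtrip(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text(
        "term\taction\ttarget_class\tsurface_forms\tscope\n"
        "humira\tsynonym_of\tOCIMIDO:00302\thumira\texact\n"
        "hospit\treject\t\t\t\n"
        "flare\tnew_class\tflare\tflare|flares\t\n"
    )
    decisions = read_decisions(p)
    assert decisions["humira"].target_class == "OCIMIDO:00302"
    assert decisions["humira"].scope == "exact"
    assert decisions["hospit"].action == "reject"
    assert decisions["flare"].new_label == "flare"
    assert decisions["flare"].surface_forms == ("flare", "flares")


def test_invalid_decision_contracts():
    with pytest.raises(MiningError):
        CurationDecision("x", "synonym_of")  # no target
    with pytest.raises(MiningError):
        CurationDecision("x", "new_class")  # no label
    with pytest.raises(MiningError):
        CurationDecision("x", "frobnicate")
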