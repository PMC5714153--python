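import math

import numpy as np
import pytest
from datamed_rank.expansion import (
    KEY_RELEVANT,
    RELEVANT,
    QueryTerm,
    WeightedQuery,
    classify_key_relevance,
)
from datamed_rank.index import InvertedIndex
from datamed_rank.ranking import (
    RtrlParams,
    bin_tiebreak,
    dfr_rank,
    doc_weight,
    key_weight,
    query_weight,
    rtrl_bin_score,
    rtrl_rank,
)

from oracles import brute_force_rank


def make_index(docs: dict[str, dict[str, int]]) -> InvertedIndex:
    idx = InvertedIndex()
    for doc_id, counts in docs.items():
        tokens = [t for t, c in counts.items() for _ in range(c)]
        idx.add_document(doc_id, tokens)
    return idx


def query_from_index(terms, idx, c=1.0) -> WeightedQuery:
    classes = classify_key_relevance(terms, idx)
    return WeightedQuery(
        [QueryTerm(t, 1.0, relevance_class=classes[t]) for t in terms],
        length=len(terms),
    )


def random_corpus(rng, max_docs=50, max_terms=30):
    vocab = [f"w{i}" for i in range(int(rng.integers(4, max_terms + 1)))]
    n_docs = int(rng.integers(2, max_docs + 1))
    docs = {}
    for i in range(n_docs):
        n_tok = int(rng.integers(1, 15))
        toks = rng.choice(vocab, size=n_tok)
        counts = {}
        for t in toks:
            counts[str(t)] = counts.get(str(t), 0) + 1
        docs[f"d{i:03d}"] = counts
    n_q = int(rng.integers(2, min(7, len(vocab) + 1)))
    q_terms = [str(t) for t in rng.choice(vocab, size=n_q, replace=False)]
    return docs, q_terms


class TestWeights:
    @pytest.mark.parametrize("L,c,expected", [(4, 1, 6), (2, 1, 2), (4, 2, 12), (3, 1, 4)])
    def test_key_weight_values(self, L, c, expected):
        assert key_weight(L, RtrlParams(c=c)) == expected

    def test_key_weight_satisfies_dominance_inequality(self):
        """With wd'=wq'=1, wd''=2 and k=ceil(L/2) key terms, a document with
        all key terms at low document relevance must tie-or-beat one with
        k-1 key terms and all the rest at high relevance."""
        for L in range(2, 21):
            wq2 = key_weight(L)
            k = math.ceil(L / 2)
            lhs = k * (1 + wq2)
            rhs = (k - 1) * (2 + wq2) + (L - k) * (2 + 1)
            assert lhs >= rhs
            if L % 2 == 0:  # the minimal solution is tight at k = L/2
                assert lhs == rhs

    def test_degenerate_single_term_query_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert key_weight(1, RtrlParams(c=2.0)) == 2.0
        assert caplog.records

    @pytest.mark.parametrize("ftd,expected", [(1, 1.0), (2, 2.0), (1000, 2.0)])
    def test_doc_weight_two_level_step(self, ftd, expected):
        assert doc_weight(ftd) == expected

    def test_doc_weight_rejects_absent_terms(self):
        with pytest.raises(ValueError):
            doc_weight(0)

    def test_query_weight_by_class(self):
        assert query_weight(RELEVANT, 4) == 1.0
        assert query_weight(KEY_RELEVANT, 4) == 6.0
        assert query_weight(KEY_RELEVANT, 3) == 4.0

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RtrlParams(c=0.5)
        with pytest.raises(ValueError):
            RtrlParams(wd_low=2.0, wd_high=1.0)


@pytest.fixture
def four_term_index():
    """10-doc corpus with dfs tcell=6, multipl=5, homeostasi=2, sclerosi=1
    (median 3.5, so homeostasi and sclerosi are key-relevant; wq''=6)."""
    docs = {
        "d1": {"homeostasi": 1, "sclerosi": 2},
        "d2": {"tcell": 2, "multipl": 1, "homeostasi": 1},
        "d3": {"tcell": 1},
    }
    # pad dfs with filler docs: tcell 6, multipl 5
    for i in range(4, 8):
        docs[f"d{i}"] = {"tcell": 1, "multipl": 1}
    docs["d8"] = {"filler": 1}
    docs["d9"] = {"filler": 1}
    docs["d0"] = {"filler": 1, "pad": 1}
    return make_index(docs)


class TestBinScore:
    def test_hand_derived_scores(self, four_term_index):
        idx = four_term_index
        terms = ["tcell", "multipl", "homeostasi", "sclerosi"]
        assert idx.document_frequency("tcell") == 6
        assert idx.document_frequency("multipl") == 5
        wq = query_from_index(terms, idx)
        assert rtrl_bin_score("d1", wq, idx) == pytest.approx(15.0)
        assert rtrl_bin_score("d2", wq, idx) == pytest.approx(12.0)
        assert rtrl_bin_score("d3", wq, idx) == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, four_term_index):
        idx = four_term_index
        terms = ["tcell", "multipl", "homeostasi", "sclerosi"]
        docs = {d: idx.doc_terms(d) for d in idx.doc_len}
        oracle = {d: b for d, b, _ in brute_force_rank(docs, terms)}
        wq = query_from_index(terms, idx)
        for doc_id, expected in oracle.items():
            assert rtrl_bin_score(doc_id, wq, idx) == pytest.approx(expected)

    def test_single_key_term_docs_share_a_bin(self):
        """Two documents each holding one occurrence of one distinct
        key-relevant term land in the same relevance bin."""
        docs = {
            "da": {"q3": 1},
            "db": {"q4": 1},
            "dc": {"q1": 1, "q2": 1},
            "dd": {"q1": 1, "q2": 1},
        }
        idx = make_index(docs)
        wq = WeightedQuery(
            [
                QueryTerm("q1", 1.0, relevance_class=RELEVANT),
                QueryTerm("q2", 1.0, relevance_class=RELEVANT),
                QueryTerm("q3", 1.0, relevance_class=KEY_RELEVANT),
                QueryTerm("q4", 1.0, relevance_class=KEY_RELEVANT),
            ],
            length=4,
        )
        assert rtrl_bin_score("da", wq, idx) == rtrl_bin_score("db", wq, idx)


class TestTieBreak:
    def test_augmented_tf_ratio(self):
        """tf = 0.5 + 0.5 f/max: a term at 1-of-4 scores 0.625 of a term at
        its document maximum, visible in the in-bin tie-break ratio."""
        docs = {
            "d1": {"a": 1, "pad": 4},
            "d2": {"a": 3, "pad": 3},
            "d3": {"other": 1},
            "d4": {"other": 1},
        }
        idx = make_index(docs)
        wq = WeightedQuery([QueryTerm("a", 1.0)], length=1)
        ties = bin_tiebreak(["d1", "d2"], wq, idx)
        assert ties["d1"] / ties["d2"] == pytest.approx(0.625)

    def test_idf_zero_for_ubiquitous_terms(self):
        docs = {f"d{i}": {"every": 1} for i in range(10)}
        idx = make_index(docs)
        wq = WeightedQuery([QueryTerm("every", 1.0)], length=1)
        ties = bin_tiebreak(list(docs), wq, idx)
        # idf = log(10/10) = 0 everywhere -> uniform epsilon fallback
        assert len(set(ties.values())) == 1
        assert 0 < next(iter(ties.values())) < 1

    def test_values_strictly_inside_unit_interval(self):
        docs = {
            "d1": {"a": 3, "b": 1},
            "d2": {"a": 1, "x": 5},
            "d3": {"b": 2},
            "d4": {"x": 1},
        }
        idx = make_index(docs)
        wq = WeightedQuery([QueryTerm("a", 1.0), QueryTerm("b", 1.0)], length=2)
        ties = bin_tiebreak(["d1", "d2", "d3"], wq, idx)
        for v in ties.values():
            assert 0 < v < 1


class TestRtrlRank:
    def test_three_doc_ordering(self, four_term_index):
        idx = four_term_index
        wq = query_from_index(["tcell", "multipl", "homeostasi", "sclerosi"], idx)
        ranked = rtrl_rank(wq, idx)
        top3 = [d.doc_id for d in ranked[:3]]
        assert top3 == ["d1", "d2", "d4"] or top3[:2] == ["d1", "d2"]
        assert ranked[0].bin_score == 15.0
        assert ranked[1].bin_score == 12.0

    def test_empty_query_is_empty_run(self, four_term_index):
        assert rtrl_rank(WeightedQuery([], length=0), four_term_index) == []

    def test_unknown_terms_give_empty_result(self, four_term_index):
        wq = WeightedQuery([QueryTerm("nosuch", 1.0)], length=1)
        assert rtrl_rank(wq, four_term_index) == []

    def test_identical_docs_rank_by_doc_id(self):
        docs = {"db": {"a": 1}, "da": {"a": 1}, "dc": {"a": 1}, "dz": {"x": 1}}
        idx = make_index(docs)
        wq = WeightedQuery([QueryTerm("a", 1.0)], length=1)
        ranked = rtrl_rank(wq, idx)
        assert [d.doc_id for d in ranked] == ["da", "db", "dc"]

    def test_oracle_equivalence_on_random_corpora(self):
        """Full agreement with an independent brute-force implementation of
        the scoring equations on 200 random corpora."""
        rng = np.random.default_rng(12345)
        for _ in range(200):
            docs, q_terms = random_corpus(rng)
            idx = make_index(docs)
            wq = query_from_index(q_terms, idx)
            got = rtrl_rank(wq, idx, cutoff=10**6)
            want = brute_force_rank(docs, q_terms)
            assert [d.doc_id for d in got] == [d for d, _, _ in want]
            for g, (_, b, _) in zip(got, want):
                assert g.bin_score == pytest.approx(b)

    def test_tiebreak_never_crosses_bins(self):
        """Final scores respect bin boundaries: across 1000 observed bins
        the (bin, tie) order equals the final-score order."""
        rng = np.random.default_rng(999)
        bins_seen = 0
        while bins_seen < 1000:
            docs, q_terms = random_corpus(rng, max_docs=30, max_terms=12)
            idx = make_index(docs)
            wq = query_from_index(q_terms, idx)
            ranked = rtrl_rank(wq, idx, cutoff=10**6)
            bins_seen += len({d.bin_score for d in ranked})
            finals = [d.final_score for d in ranked]
            assert finals == sorted(finals, reverse=True)
            for hi, lo in zip(ranked, ranked[1:]):
                if hi.bin_score != lo.bin_score:
                    assert hi.bin_score > lo.bin_score
                    assert hi.final_score > lo.final_score

    def test_adding_query_term_occurrence_never_lowers_score(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            docs, q_terms = random_corpus(rng, max_docs=15, max_terms=10)
            target = next(iter(docs))
            grown = {d: dict(c) for d, c in docs.items()}
            grown[target][q_terms[0]] = grown[target].get(q_terms[0], 0) + 1
            idx_a, idx_b = make_index(docs), make_index(grown)
            wq_a = query_from_index(q_terms, idx_a)
            # term classes must be held fixed for a per-doc comparison
            score_a = rtrl_bin_score(target, wq_a, idx_a)
            score_b = rtrl_bin_score(target, wq_a, idx_b)
            assert score_b >= score_a


class TestKeyDominance:
    @pytest.mark.parametrize("c", [1.0, 2.0, 4.0])
    def test_all_key_terms_beat_any_partial_pattern(self, c):
        """Design goal of the weighting: a doc holding every key-relevant
        term once outranks any doc missing at least one of them, regardless
        of repetition, exhaustively over occurrence patterns."""
        params = RtrlParams(c=c)
        for L in range(2, 11):
            k = math.ceil(L / 2)
            wq2 = key_weight(L, params)
            champion = k * (params.wd_low + wq2)
            best_rival = 0.0
            # occupancy per key term: 0 absent / 1 once / 2 repeated,
            # with at most k-1 key terms present; relevant terms maximal
            for pattern in range(3**k):
                levels = [(pattern // 3**i) % 3 for i in range(k)]
                if sum(1 for lv in levels if lv > 0) > k - 1:
                    continue
                score = sum(
                    doc_weight(lv, params) + wq2 for lv in levels if lv > 0
                )
                score += (L - k) * (params.wd_high_ + params.wq_low)
                best_rival = max(best_rival, score)
            assert champion >= best_rival


class TestDfr:
    def test_closed_form_contribution(self):
        docs = {"d1": {"a": 2}, "d2": {"b": 2}}
        idx = make_index(docs)
        wq = WeightedQuery([QueryTerm("a", 1.0)], length=1)
        ranked = dfr_rank(wq, idx, c_norm=1.0)
        # tfn = 2*log2(2) = 2; contribution = (2/3)*log2(3/1.5) = 2/3
        assert ranked == [("d1", pytest.approx(2 / 3))]

    def test_absent_terms_contribute_nothing(self):
        docs = {"d1": {"a": 1}, "d2": {"b": 1}}
        idx = make_index(docs)
        wq = WeightedQuery([QueryTerm("a", 1.0), QueryTerm("zz", 1.0)], length=2)
        ranked = dfr_rank(wq, idx)
        assert [d for d, _ in ranked] == ["d1"]

    def test_invalid_c_norm_rejected(self):
        idx = make_index({"d1": {"a": 1}})
        with pytest.raises(ValueError):
            dfr_rank(WeightedQuery([QueryTerm("a", 1.0)], length=1), idx, c_norm=0)

    def test_expansion_weights_scale_contributions(self):
        docs = {"d1": {"a": 1}, "d2": {"b": 1}, "d3": {"c": 1}}
        idx = make_index(docs)
        full = WeightedQuery([QueryTerm("a", 1.0)], length=1)
        half = WeightedQuery([QueryTerm("a", 0.5)], length=1)
        (_, s_full), = [e for e in dfr_rank(full, idx) if e[0] == "d1"]
        (_, s_half), = [e for e in dfr_rank(half, idx) if e[0] == "d1"]
        assert s_half == pytest.approx(0.5 * s_full)
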