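import math

import numpy as np
import pytest

from helpers_oracle import oracle_marginal_probability
from medlink import ConceptEntry, TermDictionary
from medlink.fusion import (
    CandidatePool,
    CombinerParams,
    ScoredCandidate,
    TrainConfig,
    TrainingError,
    combine_linear,
    marginal_loss,
    marginal_loss_gradient,
    marginal_probability,
    mine_candidates,
    normalize_channel,
    train_combiner,
)


def make_pool(scores_semantic, scores_string, positives, params=None, query_id="q"):
    params = params or CombinerParams(scheme="linear", alpha=1.0, beta=1.0)
    cands = tuple(
        ScoredCandidate(
            concept_id=f"C{i}",
            term=f"t{i}",
            s_string=float(b),
            s_semantic=float(a),
            s_combined=float(params.alpha * a + params.beta * b),
            is_positive=bool(p),
        )
        for i, (a, b, p) in enumerate(zip(scores_semantic, scores_string, positives))
    )
    return CandidatePool(query_id=query_id, candidates=cands, k=len(cands))


class TestNormalizeChannel:
    def test_zscore_closed_form(self):
        out = normalize_channel([1.0, 2.0, 3.0], "zscore")
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_minmax_endpoints(self):
        np.testing.assert_allclose(
            normalize_channel([1.0, 2.0, 3.0], "minmax"), [0.0, 0.5, 1.0]
        )

    def test_degenerate_pools(self):
        np.testing.assert_allclose(normalize_channel([5.0] * 3, "tanh"), 0.5)
        np.testing.assert_allclose(normalize_channel([5.0] * 3, "minmax"), 0.5)
        np.testing.assert_allclose(normalize_channel([5.0] * 3, "zscore"), 0.0)

    def test_tanh_closed_form(self):
        scores = np.array([1.0, 2.0, 3.0])
        sd = scores.std()
        expected = 0.5 * (np.tanh(0.01 * (scores - 2.0) / sd) + 1.0)
        np.testing.assert_allclose(normalize_channel(scores, "tanh"), expected)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            normalize_channel([1.0], "sigmoid")

    @pytest.mark.parametrize("scheme", ["zscore", "minmax", "tanh"])
    def test_monotone_order_preserving(self, scheme, rng):
        for _ in range(20):
            scores = rng.standard_normal(15)
            out = normalize_channel(scores, scheme)
            order_in = np.argsort(scores, kind="stable")
            assert np.all(np.diff(out[order_in]) >= -1e-15)


class TestCombineLinear:
    def test_reference_weights(self):
        # converged weights of the reference configuration
        params = CombinerParams(scheme="linear", alpha=33.11, beta=7.28)
        assert combine_linear(0.9, 0.5, params) == pytest.approx(33.439)

    def test_single_channel_reductions(self):
        sem_only = CombinerParams(scheme="semantic_only")
        str_only = CombinerParams(scheme="string_only")
        assert combine_linear(0.7, 0.3, sem_only) == 0.7
        assert combine_linear(0.7, 0.3, str_only) == 0.3

    def test_non_finite_rejected(self):
        params = CombinerParams(scheme="linear")
        with pytest.raises(ValueError):
            combine_linear(float("nan"), 0.0, params)


@pytest.fixture
def score_fixture(rng):
    n = 50
    dictionary = TermDictionary(
        [ConceptEntry(f"C{i:03d}", f"term {i:03d}") for i in range(n)]
    )
    string_row = rng.random(n)
    semantic_row = rng.random(n)
    return dictionary, string_row, semantic_row


class TestMineCandidates:
    def test_exhaustive_pool_is_full_sort(self, score_fixture):
        dictionary, string_row, semantic_row = score_fixture
        params = CombinerParams(scheme="linear", alpha=1.0, beta=1.0)
        pool = mine_candidates(
            string_row, semantic_row, params, k=len(dictionary), dictionary=dictionary
        )
        combined = semantic_row + string_row
        expected = [dictionary[i].concept_id for i in np.argsort(-combined, kind="stable")]
        assert [c.concept_id for c in pool.candidates] == expected
        assert all(
            a.s_combined >= b.s_combined
            for a, b in zip(pool.candidates, pool.candidates[1:])
        )

    def test_tie_break_by_dictionary_position(self):
        d = TermDictionary([ConceptEntry(f"C{i}", f"t{i}") for i in range(4)])
        params = CombinerParams(scheme="linear", alpha=1.0, beta=1.0)
        pool = mine_candidates([0.5] * 4, [0.5] * 4, params, k=2, dictionary=d)
        assert [c.concept_id for c in pool.candidates] == ["C0", "C1"]

    def test_oversized_k_truncates_with_warning(self, score_fixture, caplog):
        dictionary, string_row, semantic_row = score_fixture
        params = CombinerParams(scheme="linear")
        pool = mine_candidates(
            string_row, semantic_row, params, k=999, dictionary=dictionary
        )
        assert len(pool) == len(dictionary)

    def test_gold_labels_fill_is_positive(self, score_fixture):
        dictionary, string_row, semantic_row = score_fixture
        params = CombinerParams(scheme="linear")
        gold = {"C003", "C007"}
        pool = mine_candidates(
            string_row, semantic_row, params, k=50, dictionary=dictionary, gold=gold
        )
        for cand in pool.candidates:
            assert cand.is_positive == (cand.concept_id in gold)


class TestMarginalProbability:
    def test_all_positive_is_one(self):
        pool = make_pool([0.3, 0.9], [0.1, 0.4], [True, True])
        params = CombinerParams(scheme="linear")
        assert marginal_probability(pool, params) == pytest.approx(1.0, abs=1e-12)

    def test_two_term_closed_form(self):
        # combined scores (2, 0), first positive: P' = e^2 / (e^2 + 1)
        pool = make_pool([2.0, 0.0], [0.0, 0.0], [True, False])
        params = CombinerParams(scheme="linear", alpha=1.0, beta=1.0)
        expected = math.exp(2) / (math.exp(2) + 1)
        assert marginal_probability(pool, params) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8808, abs=5e-5)

    def test_uniform_pool_is_p_over_m(self):
        m, p = 8, 3
        pool = make_pool([0.5] * m, [0.5] * m, [True] * p + [False] * (m - p))
        params = CombinerParams(scheme="linear")
        assert marginal_probability(pool, params) == pytest.approx(p / m, abs=1e-12)

    def test_no_positive_violates_contract(self):
        pool = make_pool([0.5, 0.2], [0.1, 0.3], [False, False])
        with pytest.raises(TrainingError):
            marginal_probability(pool, CombinerParams(scheme="linear"))

    def test_matches_brute_force_on_random_pools(self, rng):
        params = CombinerParams(scheme="linear", alpha=1.7, beta=0.4)
        for _ in range(30):
            m = int(rng.integers(2, 21))
            sem = rng.standard_normal(m)
            stg = rng.standard_normal(m)
            pos = rng.random(m) < 0.3
            if not pos.any():
                pos[int(rng.integers(m))] = True
            pool = make_pool(sem, stg, pos)
            combined = [params.alpha * a + params.beta * b for a, b in zip(sem, stg)]
            expected = oracle_marginal_probability(combined, pos.tolist())
            assert marginal_probability(pool, params) == pytest.approx(
                expected, abs=1e-12
            )


class TestMarginalLoss:
    def test_perfect_pools_give_zero_loss(self):
        pools = [make_pool([1.0], [1.0], [True]) for _ in range(3)]
        params = CombinerParams(scheme="linear")
        assert marginal_loss(pools, params) == pytest.approx(0.0, abs=1e-12)

    def test_single_pool_closed_form(self):
        pool = make_pool([2.0, 0.0], [0.0, 0.0], [True, False])
        params = CombinerParams(scheme="linear")
        expected = -math.log(math.exp(2) / (math.exp(2) + 1))
        assert marginal_loss([pool], params) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1269, abs=5e-5)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            marginal_loss([], CombinerParams(scheme="linear"))

    def test_loss_decreases_when_positive_semantic_score_rises(self):
        params = CombinerParams(scheme="linear", alpha=1.0, beta=1.0)
        base = marginal_loss(
            [make_pool([0.5, 0.6, 0.7], [0.2, 0.2, 0.2], [True, False, False])], params
        )
        raised = marginal_loss(
            [make_pool([0.9, 0.6, 0.7], [0.2, 0.2, 0.2], [True, False, False])], params
        )
        assert raised < base

    def test_gradient_matches_finite_differences(self, rng):
        params = CombinerParams(scheme="linear", alpha=0.8, beta=1.3)
        pools = []
        for _ in range(20):
            m = int(rng.integers(3, 21))
            sem = rng.standard_normal(m)
            stg = rng.standard_normal(m)
            pos = rng.random(m) < 0.4
            if not pos.any():
                pos[0] = True
            pools.append(make_pool(sem, stg, pos))
        g_alpha, g_beta = marginal_loss_gradient(pools, params)
        eps = 1e-6
        num_alpha = (
            marginal_loss(pools, CombinerParams("linear", params.alpha + eps, params.beta))
            - marginal_loss(pools, CombinerParams("linear", params.alpha - eps, params.beta))
        ) / (2 * eps)
        num_beta = (
            marginal_loss(pools, CombinerParams("linear", params.alpha, params.beta + eps))
            - marginal_loss(pools, CombinerParams("linear", params.alpha, params.beta - eps))
        ) / (2 * eps)
        assert g_alpha == pytest.approx(num_alpha, abs=1e-6)
        assert g_beta == pytest.approx(num_beta, abs=1e-6)


class TestTrainCombiner:
    def _toy_problem(self, rng, informative="semantic"):
        """30 concepts; the informative channel scores gold highest."""
        n = 30
        dictionary = TermDictionary(
            [ConceptEntry(f"C{i:03d}", f"term {i:03d}") for i in range(n)]
        )
        from medlink.lexicon import Query

        queries, sem_rows, stg_rows = [], [], []
        for j in range(40):
            gold = int(rng.integers(n))
            signal = rng.random(n) * 0.4
            signal[gold] = 0.9 + 0.1 * rng.random()
            noise = rng.random(n)
            sem_rows.append(signal if informative == "semantic" else noise)
            stg_rows.append(noise if informative == "semantic" else signal)
            queries.append(
                Query(query_id=f"q{j}", surface="x", gold_concept_ids={f"C{gold:03d}"})
            )
        return dictionary, queries, np.array(stg_rows), np.array(sem_rows)

    def test_recovers_informative_semantic_channel(self, rng):
        d, q, stg, sem = self._toy_problem(rng, informative="semantic")
        params, trace = train_combiner(
            q, stg, sem, d, TrainConfig(k=10, epochs=30, learning_rate=0.5)
        )
        assert params.alpha > params.beta
        assert trace[-1] < trace[0]

    def test_recovers_informative_string_channel(self, rng):
        d, q, stg, sem = self._toy_problem(rng, informative="string")
        params, trace = train_combiner(
            q, stg, sem, d, TrainConfig(k=10, epochs=30, learning_rate=0.5)
        )
        assert params.beta > params.alpha
        assert trace[-1] < trace[0]

    def test_reproducible(self, rng):
        d, q, stg, sem = self._toy_problem(rng)
        out1 = train_combiner(q, stg, sem, d, TrainConfig(k=10, epochs=10))
        out2 = train_combiner(q, stg, sem, d, TrainConfig(k=10, epochs=10))
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_unlabeled_query_rejected(self, rng):
        from medlink.lexicon import Query

        d, q, stg, sem = self._toy_problem(rng)
        q[0] = Query(query_id="q0", surface="x", gold_concept_ids=frozenset())
        with pytest.raises(ValueError, match="no gold labels"):
            train_combiner(q, stg, sem, d, TrainConfig())

    def test_params_persistence(self, tmp_path):
        params = CombinerParams(scheme="linear", alpha=2.5, beta=0.75)
        path = tmp_path / "params.json"
        params.save(path, loss_trace=[1.0, 0.5])
        assert CombinerParams.load(path) == params


class TestParamValidation:
    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            CombinerParams(scheme="bm25")

    def test_single_channel_weights_pinned(self):
        p = CombinerParams(scheme="string_only", alpha=5.0, beta=5.0)
        assert (p.alpha, p.beta) == (0.0, 1.0)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(k=1)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
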