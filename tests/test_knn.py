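import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridcbr import (
    CaseBase,
    KnnConfig,
    fit_logistic,
    fuse,
    pearson_residuals,
    predict,
    select_neighbors,
    similarity,
    tune_k,
)
from hybridcbr.knn import similarity_matrix
from hybridcbr.weighting import WeightSet, attribute_weights, case_weights

from conftest import random_case_base
from naive_oracle import naive_knn_scores, naive_variant_scores


class TestSimilarity:
    def test_identical_vectors(self):
        w = np.full(4, 0.25)
        p = np.array([1.0, 0, 1, 0])
        assert similarity(p, p, w) == 1.0

    def test_complement_vectors(self):
        w = np.full(4, 0.25)
        p = np.array([1.0, 0, 1, 0])
        assert similarity(p, 1 - p, w) == pytest.approx(0.0, abs=1e-12)

    def test_single_mismatch_uniform(self):
        w = np.full(4, 0.25)
        p = np.array([1.0, 0, 1, 0])
        q = np.array([1.0, 0, 1, 1])
        assert similarity(p, q, w) == pytest.approx(0.75)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            similarity(np.zeros(3), np.zeros(4), np.full(4, 0.25))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 30))
        p = (rng.random(m) < 0.5).astype(float)
        q = (rng.random(m) < 0.5).astype(float)
        w = rng.random(m)
        w /= w.sum()
        assert similarity(p, q, w) == similarity(q, p, w)
        assert similarity(p, p, w) == 1.0
        assert 0.0 <= similarity(p, q, w) <= 1.0 + 1e-12

    def test_matrix_matches_scalar_bitwise(self):
        rng = np.random.default_rng(3)
        Q = (rng.random((7, 11)) < 0.5).astype(float)
        L = (rng.random((13, 11)) < 0.5).astype(float)
        w = rng.random(11)
        w /= w.sum()
        S = similarity_matrix(Q, L, w)
        for i in range(7):
            for j in range(13):
                assert S[i, j] == similarity(Q[i], L[j], w)


class TestSelectNeighbors:
    def test_exact_match_first(self, tiny_labeled):
        w = np.full(3, 1 / 3)
        idx = select_neighbors(tiny_labeled.values[4], tiny_labeled, w, k=1)
        assert idx.tolist() == [4]

    def test_equidistant_tie_rule(self):
        # all labeled cases at the same distance from the query
        cb = CaseBase(
            tuple(str(i) for i in range(4)),
            ("a", "b"),
            np.array([[1.0, 0], [0, 1], [1, 0], [0, 1]]),
            labels=np.array([0, 1, 0, 1]),
        )
        w = np.array([0.5, 0.5])
        idx = select_neighbors(np.array([1.0, 1.0]), cb, w, k=3)
        assert idx.tolist() == [0, 1, 2]  # lowest indices first

    def test_against_brute_force(self):
        rng = np.random.default_rng(11)
        cb = random_case_base(rng, 30, 6)
        w = rng.random(6)
        w /= w.sum()
        q = (rng.random(6) < 0.5).astype(float)
        idx = select_neighbors(q, cb, w, k=5)
        sims = [similarity(q, cb.values[j], w) for j in range(30)]
        expected = sorted(range(30), key=lambda j: (-sims[j], j))[:5]
        assert idx.tolist() == expected

    def test_k_bounds(self, tiny_labeled):
        w = np.full(3, 1 / 3)
        with pytest.raises(ValueError):
            select_neighbors(tiny_labeled.values[0], tiny_labeled, w, k=7)


class TestFuse:
    def test_unanimous_labels(self):
        assert fuse(np.ones(4)) == 1.0
        assert fuse(np.zeros(4), np.array([0.3, 0.1, 0.2, 0.4])) == 0.0

    def test_uniform_arithmetic(self):
        assert fuse(np.array([1.0, 0.0, 1.0])) == pytest.approx(2 / 3)

    def test_weighted_arithmetic(self):
        score = fuse(np.array([1.0, 0.0, 1.0]), np.array([0.5, 0.3, 0.2]))
        assert score == pytest.approx(0.7)

    def test_convexity_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(1, 10))
            labels = (rng.random(k) < 0.5).astype(float)
            raw = rng.random(k) + 1e-9
            s = fuse(labels, raw)
            assert labels.min() - 1e-12 <= s <= labels.max() + 1e-12

    def test_zero_weights_fall_back_to_uniform(self):
        assert fuse(np.array([1.0, 0.0]), np.zeros(2)) == pytest.approx(0.5)


class TestTuneK:
    def _weighted_inputs(self, rng, n=40, m=5):
        labeled = random_case_base(rng, n, m, prefix="t")
        setting = random_case_base(rng, 25, m, prefix="s")
        w = rng.random(m)
        w /= w.sum()
        cw = rng.uniform(0.01, 0.39, size=n)
        return labeled, setting, w, cw

    def test_matches_exhaustive_scan(self):
        """tune_k equals a brute-force scan that re-predicts at every k."""
        from hybridcbr.evaluation import auc

        rng = np.random.default_rng(21)
        labeled, setting, w, cw = self._weighted_inputs(rng)
        k_best, aucs = tune_k(labeled, setting, w, cw, k_max=15)
        brute = []
        for k in range(1, 16):
            scores = naive_knn_scores(
                setting.values, labeled.values, labeled.labels,
                labeled.case_ids, dict(zip(labeled.attribute_names, w)),
                labeled.attribute_names, k,
                dict(zip(labeled.case_ids, cw)),
            )
            brute.append(auc(scores, setting.labels))
        brute = np.array(brute)
        assert np.array_equal(aucs, brute)
        assert k_best == int(np.argmax(brute)) + 1

    def test_smallest_k_on_tie(self):
        # one labeled positive identical to every positive setting case:
        # k=1 reaches AUC 1.0 which cannot be beaten, so k must be 1
        labeled = CaseBase(
            ("a", "b"), ("x", "y"),
            np.array([[1.0, 1.0], [0.0, 0.0]]),
            labels=np.array([1, 0]),
        )
        setting = CaseBase(
            ("s1", "s2"), ("x", "y"),
            np.array([[1.0, 1.0], [0.0, 0.0]]),
            labels=np.array([1, 0]),
        )
        w = np.array([0.5, 0.5])
        k, _ = tune_k(labeled, setting, w, None, k_max=2)
        assert k == 1

    def test_single_class_setting_errors(self):
        labeled = CaseBase(
            ("a", "b"), ("x",), np.array([[1.0], [0.0]]), labels=np.array([1, 0])
        )
        setting = CaseBase(
            ("s1", "s2"), ("x",), np.array([[1.0], [0.0]]), labels=np.array([1, 1])
        )
        with pytest.raises(ValueError, match="single outcome class"):
            tune_k(labeled, setting, np.array([1.0]), None, k_max=2)


class TestPredictVariants:
    def _fitted_inputs(self, seed, n=40, m=5, nq=15):
        rng = np.random.default_rng(seed)
        labeled = random_case_base(rng, n, m, prefix="l")
        queries = random_case_base(rng, nq, m, labeled=False, prefix="q")
        model = fit_logistic(labeled)
        aw = attribute_weights(model, labeled.attribute_names)
        cw = case_weights(pearson_residuals(model, labeled), labeled.case_ids)
        wset = WeightSet(aw, cw)
        return labeled, queries, model, wset

    def test_wa_with_equal_weights_reduces_to_cbr(self):
        labeled, queries, model, wset = self._fitted_inputs(31)
        m = labeled.n_attributes
        flat = WeightSet(
            {a: 1.0 / m for a in labeled.attribute_names},
            wset.case_weights_raw,
        )
        cfg = lambda v: KnnConfig(variant=v, k=5)  # noqa: E731
        s_cbr = [r.score for r in predict(cfg("cbr"), model, None, labeled, queries)]
        s_wa = [r.score for r in predict(cfg("cbr_wa"), model, flat, labeled, queries)]
        assert s_cbr == s_wa

    def test_wp_with_equal_case_weights_reduces_to_cbr(self):
        labeled, queries, model, wset = self._fitted_inputs(32)
        flat = WeightSet(
            wset.attribute_weights,
            {c: 0.2 for c in labeled.case_ids},
        )
        cfg = lambda v: KnnConfig(variant=v, k=5)  # noqa: E731
        s_cbr = [r.score for r in predict(cfg("cbr"), model, None, labeled, queries)]
        s_wp = [r.score for r in predict(cfg("cbr_wp"), model, flat, labeled, queries)]
        assert s_cbr == pytest.approx(s_wp, abs=1e-12)

    def test_zero_weight_attributes_are_inert(self):
        labeled, queries, model, wset = self._fitted_inputs(33)
        aw = dict.fromkeys(labeled.attribute_names, 0.0)
        aw["x0"], aw["x1"] = 0.6, 0.4
        wset0 = WeightSet(aw, wset.case_weights_raw)
        cfg = KnnConfig(variant="cbr_wa_wp", k=7)
        base_scores = [
            r.score for r in predict(cfg, model, wset0, labeled, queries)
        ]
        # perturb every zero-weight column of the queries
        vals = queries.values.copy()
        vals[:, 2:] = 1.0 - vals[:, 2:]
        perturbed = CaseBase(
            queries.case_ids, queries.attribute_names, vals
        )
        new_scores = [
            r.score for r in predict(cfg, model, wset0, labeled, perturbed)
        ]
        assert base_scores == new_scores  # bit-identical

    def test_all_variants_match_naive_oracle(self):
        labeled, queries, model, wset = self._fitted_inputs(34)
        for variant in ("lr", "cbr", "cbr_wa", "cbr_wp", "cbr_wa_wp"):
            cfg = KnnConfig(variant=variant, k=7)
            got = np.array(
                [r.score for r in predict(cfg, model, wset, labeled, queries)]
            )
            want = naive_variant_scores(
                variant, model, wset, labeled, queries, k=7
            )
            assert np.array_equal(got, want), variant

    def test_duplicate_case_only_acts_through_tie_rule(self):
        """Appending a duplicate labeled case keeps oracle equivalence."""
        labeled, queries, model, wset = self._fitted_inputs(35)
        dup_vals = np.vstack([labeled.values, labeled.values[:1]])
        dup = CaseBase(
            labeled.case_ids + ("dup",),
            labeled.attribute_names,
            dup_vals,
            labels=np.append(labeled.labels, labeled.labels[0]),
        )
        cw = dict(wset.case_weights_raw)
        cw["dup"] = cw[labeled.case_ids[0]]
        wset2 = WeightSet(wset.attribute_weights, cw)
        cfg = KnnConfig(variant="cbr_wa_wp", k=6)
        got = np.array([r.score for r in predict(cfg, model, wset2, dup, queries)])
        want = naive_variant_scores("cbr_wa_wp", model, wset2, dup, queries, k=6)
        assert np.array_equal(got, want)

    def test_prediction_result_invariants(self):
        labeled, queries, model, wset = self._fitted_inputs(36)
        cfg = KnnConfig(variant="cbr_wa_wp", k=9)
        for r in predict(cfg, model, wset, labeled, queries):
            assert 0.0 <= r.score <= 1.0
            assert r.k_used == 9
            assert len(r.neighbor_ids) == 9
            assert sum(r.fusion_weights) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            KnnConfig(variant="bogus")

    def test_auto_k_must_be_resolved(self):
        labeled, queries, model, wset = self._fitted_inputs(37)
        with pytest.raises(ValueError, match="auto"):
            predict(KnnConfig(variant="cbr"), model, wset, labeled, queries)

    def test_missing_values_in_queries_rejected(self):
        labeled, queries, model, wset = self._fitted_inputs(38)
        vals = queries.values.copy()
        vals[0, 0] = np.nan
        bad = CaseBase(queries.case_ids, queries.attribute_names, vals)
        with pytest.raises(ValueError, match="complete"):
            predict(KnnConfig(variant="cbr", k=3), model, wset, labeled, bad)
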