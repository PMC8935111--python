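import numpy as np
import pytest
from sklearn.base import clone

import scinsight as si
from scinsight.factorization import FactorModel


def _model(V, H, W1, W2, condition_of, lambda1=0.0, lambda2=0.0):
    V = np.asarray(V, float)
    H = [np.asarray(h, float) for h in H]
    return FactorModel(V, H, [np.asarray(w, float) for w in W1],
                       [np.asarray(w, float) for w in W2], V.shape[0],
                       [h.shape[0] for h in H], lambda1, lambda2,
                       list(condition_of))


def _study(arrays, conds=None):
    conds = conds or [f"cond{i}" for i in range(len(arrays))]
    genes = [f"g{i}" for i in range(arrays[0].shape[1])]
    return si.StudyData([
        si.SampleMatrix(f"s{i}", conds[i],
                        [f"s{i}:c{j}" for j in range(a.shape[0])], genes,
                        np.asarray(a, float))
        for i, a in enumerate(arrays)
    ])


class TestObjective:
    def test_perfect_reconstruction_is_zero(self):
        W2 = np.array([[1.0, 2.0], [0.5, 1.0]])
        V = np.array([[0.2, 0.3, 0.1], [0.4, 0.0, 0.6]])
        X = W2 @ V
        m = _model(V, [np.zeros((1, 3))], [np.zeros((2, 1))], [W2], [0])
        assert si.objective(m, _study([X])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # 1 cell, 1 gene: X=2, W2=V=W1=H=1, m=1, lambda1=0.5 -> 0 + 0.5*1
        m = _model([[1.0]], [[[1.0]]], [[[1.0]]], [[[1.0]]], [0], lambda1=0.5)
        assert si.objective(m, _study([np.array([[2.0]])])) == pytest.approx(0.5)

    def test_disjoint_condition_modules_no_overlap_penalty(self):
        H1 = np.array([[1.0, 0.0, 0.0]])
        H2 = np.array([[0.0, 1.0, 1.0]])
        X = [np.ones((1, 3)), np.ones((1, 3))]
        m0 = _model(np.zeros((1, 3)), [H1, H2], [np.zeros((1, 1))] * 2,
                    [np.zeros((1, 1))] * 2, [0, 1], lambda2=0.0)
        m1 = _model(np.zeros((1, 3)), [H1, H2], [np.zeros((1, 1))] * 2,
                    [np.zeros((1, 1))] * 2, [0, 1], lambda2=100.0)
        study = _study(X)
        assert si.objective(m0, study) == pytest.approx(si.objective(m1, study))

    def test_shape_mismatch_rejected(self):
        m = _model([[1.0, 0.0]], [[[1.0, 0.0]]], [[[1.0]]], [[[1.0]]], [0])
        with pytest.raises(ValueError):
            si.objective(m, _study([np.ones((1, 3))]))


class TestInitialize:
    def test_seeded_determinism(self, tiny_study):
        a = si.initialize(tiny_study, K=2, K_j=1, seed=5)
        b = si.initialize(tiny_study, K=2, K_j=1, seed=5)
        np.testing.assert_array_equal(a.V, b.V)
        np.testing.assert_array_equal(a.W2[0], b.W2[0])
        c = si.initialize(tiny_study, K=2, K_j=1, seed=6)
        assert np.any(a.V != c.V)

    def test_unit_norm_rows(self, tiny_study):
        m = si.initialize(tiny_study, K=3, K_j=2, seed=0)
        np.testing.assert_allclose(np.linalg.norm(m.V, axis=1), 1.0)
        for h in m.H:
            np.testing.assert_allclose(np.linalg.norm(h, axis=1), 1.0)

    def test_K_exceeding_genes_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            si.initialize(tiny_study, K=5, K_j=1)


def _grid_minimize_block(model, study, setter, getter, lo=0.0, hi=10.0,
                         step=5e-4):
    """Brute force: coordinate-wise fine-grid minimization of the full
    objective over one factor row/column (independent of the update code)."""
    grid = np.arange(lo, hi + step, step)
    vec = getter(model).copy()
    for i in range(len(vec)):
        best_val, best_x = np.inf, vec[i]
        for x in grid:
            vec[i] = x
            setter(model, vec)
            val = si.objective(model, study)
            if val < best_val:
                best_val, best_x = val, x
        vec[i] = best_x
        setter(model, vec)
    return vec


class TestUpdateOracles:
    """Each single-row/column HALS update must solve its restricted
    non-negative least-squares problem; verified against a fine-grid search."""

    def test_update_V_matches_grid_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 2, (3, 3))
        W2 = rng.uniform(0.2, 1, (3, 1))
        model = _model(rng.uniform(0, 1, (1, 3)), [np.zeros((1, 3))],
                       [np.zeros((3, 1))], [W2], [0])
        study = _study([X])
        ref = _grid_minimize_block(
            model.copy(), study,
            lambda m, v: m.V.__setitem__(0, v), lambda m: m.V[0])
        si.update_V(model, study)
        np.testing.assert_allclose(model.V[0], ref, atol=1e-3)

    def test_update_W2_matches_grid_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 2, (2, 2))
        V = rng.uniform(0.2, 1, (1, 2))
        model = _model(V, [np.zeros((1, 2))], [np.zeros((2, 1))],
                       [rng.uniform(0, 1, (2, 1))], [0])
        study = _study([X])
        ref = _grid_minimize_block(
            model.copy(), study,
            lambda m, v: m.W2[0].__setitem__((slice(None), 0), v),
            lambda m: m.W2[0][:, 0])
        si.update_W2(model, study)
        np.testing.assert_allclose(model.W2[0][:, 0], ref, atol=1e-3)

    def test_update_W1_matches_grid_oracle_with_penalty(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 2, (2, 3))
        H = rng.uniform(0.2, 1, (1, 3))
        model = _model(np.zeros((1, 3)), [H], [rng.uniform(0, 1, (2, 1))],
                       [np.zeros((2, 1))], [0], lambda1=0.7)
        study = _study([X])
        ref = _grid_minimize_block(
            model.copy(), study,
            lambda m, v: m.W1[0].__setitem__((slice(None), 0), v),
            lambda m: m.W1[0][:, 0])
        si.update_W1(model, study)
        np.testing.assert_allclose(model.W1[0][:, 0], ref, atol=1e-3)

    def test_update_H_matches_grid_oracle_single_condition(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 2, (3, 2))
        model = _model(np.zeros((1, 2)), [rng.uniform(0, 1, (1, 2))],
                       [rng.uniform(0.2, 1, (3, 1))], [np.zeros((3, 1))],
                       [0], lambda1=0.3)
        study = _study([X])
        ref = _grid_minimize_block(
            model.copy(), study,
            lambda m, v: m.H[0].__setitem__(0, v), lambda m: m.H[0][0])
        si.update_H(model, study)
        np.testing.assert_allclose(model.H[0][0], ref, atol=1e-3)


class TestUpdateProperties:
    def test_fixed_point_at_zero_residual(self):
        rng = np.random.default_rng(4)
        W2 = rng.uniform(0.1, 1, (3, 2))
        V = rng.uniform(0.1, 1, (2, 4))
        X = W2 @ V
        model = _model(V, [np.zeros((1, 4))], [np.zeros((3, 1))], [W2], [0])
        study = _study([X])
        si.update_V(model, study)
        np.testing.assert_allclose(model.V, V, atol=1e-12)
        si.update_W2(model, study)
        np.testing.assert_allclose(model.W2[0], W2, atol=1e-12)

    def test_negative_push_clips_to_zero(self):
        # X = 0 with positive factors: the optimal row is all zero
        V = np.array([[0.5, 0.5]])
        W2 = np.array([[1.0], [1.0]])
        model = _model(V, [np.zeros((1, 2))], [np.zeros((2, 1))], [W2], [0])
        si.update_V(model, _study([np.zeros((2, 2))]))
        np.testing.assert_array_equal(model.V, 0.0)

    def test_larger_lambda1_shrinks_W1_step(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 2, (4, 5))
        H = rng.uniform(0.2, 1, (2, 5))
        W1 = rng.uniform(0, 0.5, (4, 2))
        norms = {}
        for lam in (0.01, 10.0):
            model = _model(np.zeros((1, 5)), [H], [W1.copy()],
                           [np.zeros((4, 1))], [0], lambda1=lam)
            si.update_W1(model, _study([X]))
            norms[lam] = np.linalg.norm(model.W1[0], axis=0)
        assert np.all(norms[10.0] <= norms[0.01] + 1e-12)

    def test_lambda2_drives_overlap_to_disjoint_support(self):
        rng = np.random.default_rng(6)
        n = 6
        H = [rng.uniform(0.5, 1, (1, n)), rng.uniform(0.5, 1, (1, n))]
        X = [rng.uniform(0, 1, (3, n)), rng.uniform(0, 1, (3, n))]
        model = _model(np.zeros((1, n)), H,
                       [rng.uniform(0.2, 1, (3, 1)) for _ in range(2)],
                       [np.zeros((3, 1))] * 2, [0, 1], lambda2=50.0)
        study = _study(X)
        for _ in range(50):
            si.update_H(model, study)
        overlap = (model.H[0][0] > 1e-8) & (model.H[1][0] > 1e-8)
        assert not overlap.any()

    def test_nonnegativity_preserved(self, small_fit):
        _, model, _, _ = small_fit
        assert (model.V >= 0).all()
        assert all((h >= 0).all() for h in model.H)
        assert all((w >= 0).all() for w in model.W1 + model.W2)


class TestRenormalize:
    def test_reconstruction_preserved_to_1e10(self):
        rng = np.random.default_rng(7)
        model = _model(rng.uniform(0, 2, (2, 5)),
                       [rng.uniform(0, 2, (2, 5)), rng.uniform(0, 2, (2, 5))],
                       [rng.uniform(0, 2, (3, 2)), rng.uniform(0, 2, (4, 2))],
                       [rng.uniform(0, 2, (3, 2)), rng.uniform(0, 2, (4, 2))],
                       [0, 1])
        before = [model.reconstruction(l) for l in range(2)]
        si.renormalize(model)
        after = [model.reconstruction(l) for l in range(2)]
        for a, b in zip(before, after):
            np.testing.assert_allclose(a, b, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(model.V, axis=1), 1.0)

    def test_objective_unchanged_without_penalties(self):
        rng = np.random.default_rng(8)
        model = _model(rng.uniform(0, 2, (2, 4)), [rng.uniform(0, 2, (1, 4))],
                       [rng.uniform(0, 2, (3, 1))], [rng.uniform(0, 2, (3, 2))],
                       [0], lambda1=0.0, lambda2=0.0)
        study = _study([rng.uniform(0, 3, (3, 4))])
        before = si.objective(model, study)
        si.renormalize(model)
        assert si.objective(model, study) == pytest.approx(before, rel=1e-12)


class TestFit:
    def test_objective_nonincreasing(self, small_fit):
        _, _, report, _ = small_fit
        tr = np.array(report.objective_trace)
        assert np.all(np.diff(tr) <= 1e-6 * tr[:-1])
        assert len(tr) == report.n_iter + 1
        assert np.isfinite(tr).all()

    def test_seeded_reproducibility(self, tiny_study):
        proc = si.accept_preprocessed(si.normalize_and_log(tiny_study, 100))
        m1, r1 = si.fit(proc, K=2, K_j=1, seed=3, max_iter=15)
        m2, r2 = si.fit(proc, K=2, K_j=1, seed=3, max_iter=15)
        np.testing.assert_array_equal(m1.V, m2.V)
        assert r1.objective_trace == r2.objective_trace

    def test_unit_norm_rows_at_convergence(self, small_fit):
        _, model, _, _ = small_fit
        np.testing.assert_allclose(np.linalg.norm(model.V, axis=1), 1.0,
                                   atol=1e-8)
        for h in model.H:
            norms = np.linalg.norm(h, axis=1)
            np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-8)

    def test_recovers_model_generated_data(self):
        # data generated exactly as W2 V: the lambda1 penalty makes W1 H = 0
        # the optimum, but BCD shrinks it only at rate ~lambda1 per cycle,
        # so this tiny noise-free instance is run long
        rng = np.random.default_rng(9)
        V = rng.uniform(0, 1, (3, 40))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        W2 = rng.uniform(0, 2, (60, 3))
        X = W2 @ V
        study = _study([X])
        model, _ = si.fit(study, K=3, K_j=1, lambda1=1e-3, lambda2=1e-3,
                          seed=0, max_iter=4000, tol=1e-13)
        recon = model.W2[0] @ model.V
        rel = np.linalg.norm(X - recon) ** 2 / np.linalg.norm(X) ** 2
        assert rel < 1e-2

    def test_recovers_true_common_modules(self):
        # well-separated unit-norm V rows are recovered with cosine > 0.9
        rng = np.random.default_rng(10)
        n, K = 60, 3
        V = np.zeros((K, n))
        for k in range(K):
            V[k, k * 20:(k + 1) * 20] = rng.uniform(0.5, 1, 20)
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        W2 = rng.uniform(0, 2, (90, K))
        X = W2 @ V
        model, _ = si.fit(_study([X]), K=K, K_j=1, lambda1=1e-3, lambda2=1e-3,
                          seed=1, max_iter=200, tol=1e-9)
        sim = (model.V / np.maximum(np.linalg.norm(model.V, axis=1,
                                                   keepdims=True), 1e-12)) @ V.T
        # optimal one-to-one matching on a 3x3 cosine matrix
        from itertools import permutations
        best = max(sum(sim[i, p[i]] for i in range(K)) / K
                   for p in permutations(range(K)))
        assert best > 0.9

    def test_nonfinite_objective_aborts(self, tiny_study):
        with pytest.raises((RuntimeError, ValueError)):
            huge = si.StudyData([
                si.SampleMatrix("a", "x", ["a:1"], ["g1"],
                                np.array([[1e308]]))])
            si.fit(huge, K=1, K_j=1, seed=0, max_iter=5)


class TestEstimator:
    def test_sklearn_protocol(self):
        est = si.SCInsight(K=4, lambda1=0.1)
        cloned = clone(est)
        assert cloned.get_params()["K"] == 4
        cloned.set_params(K=2)
        assert cloned.K == 2

    def test_fit_from_pooled_array(self, small_sim):
        _, study, truth = small_sim
        X = np.vstack(study.matrices())
        est = si.SCInsight(K=4, K_j=1, max_iter=5, random_state=0)
        emb = est.fit_transform(X, sample_labels=truth.sample_labels,
                                condition_labels=truth.condition_labels)
        assert emb.shape == (X.shape[0], 4)
        assert est.V_.shape == (4, X.shape[1])
        assert len(est.H_) == 3
        assert est.n_iter_ == 5
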