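import numpy as np
import pytest

from laminet.parafac import (
    bootstrap_decompose,
    corcondia,
    fit_parafac,
    match_components,
    select_components,
)


def best_congruence(model, truth_factors):
    """Per-component congruence (mean of per-mode cosines) after optimal matching."""
    def unit(M):
        return M / np.linalg.norm(M, axis=0)

    C = np.mean([unit(t).T @ unit(m)
                 for t, m in zip(truth_factors, model.factors)], axis=0)
    from scipy.optimize import linear_sum_assignment
    r, c = linear_sum_assignment(-C)
    return C[r, c]


class TestFitParafac:
    def test_exact_rank1(self):
        u = np.linspace(1, 2, 5)
        v = np.linspace(0.5, 3, 7)
        w = np.linspace(2, 1, 4)
        y = np.linspace(1, 4, 6)
        z = np.linspace(1, 1.5, 3)
        X = np.einsum("a,b,c,d,e->abcde", u, v, w, y, z)
        model = fit_parafac(X, K=1, seed=0)
        assert model.explained_variance >= 0.999

    def test_planted_rank4_congruence(self, rank4_tensor):
        X, truth = rank4_tensor
        model = fit_parafac(X, K=4, seed=0, tol=1e-9, max_iter=800)
        cong = best_congruence(model, truth)
        assert np.all(cong > 0.95)

    def test_seeded_determinism(self, rank4_tensor):
        X, _ = rank4_tensor
        m1 = fit_parafac(X, K=3, seed=5, max_iter=50, n_restarts=2)
        m2 = fit_parafac(X, K=3, seed=5, max_iter=50, n_restarts=2)
        for f1, f2 in zip(m1.factors, m2.factors):
            np.testing.assert_array_equal(f1, f2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_parafac(np.ones((2, 2, 2, 2, 2)), K=0)
        with pytest.raises(ValueError):
            fit_parafac(np.zeros((2, 2, 2)), K=1)
        with pytest.raises(ValueError):
            fit_parafac(-np.ones((2, 2, 2)), K=1)

    def test_normalization_convention(self, rank4_tensor):
        X, _ = rank4_tensor
        model = fit_parafac(X, K=2, seed=1, max_iter=200)
        for name, F in zip("abde", [model.a, model.b, model.d, model.e]):
            np.testing.assert_allclose(F.std(axis=0), 1.0, atol=1e-8)
        shares = model.amplitude_share()
        assert np.all(np.diff(shares) <= 1e-12)  # descending order

    def test_monotone_explained_variance_in_k(self, rank4_tensor):
        X, _ = rank4_tensor
        evs = [fit_parafac(X, K=k, seed=2, max_iter=300,
                           n_restarts=3).explained_variance
               for k in (1, 2, 3)]
        assert evs[1] >= evs[0] - 1e-6
        assert evs[2] >= evs[1] - 1e-6


class TestCorcondia:
    def test_k1_is_100(self, rank4_tensor):
        X, _ = rank4_tensor
        model = fit_parafac(X, K=1, seed=0, max_iter=100)
        assert corcondia(model, X) == 100.0

    def test_exact_rank4_high_score(self):
        rng = np.random.default_rng(3)
        # well-separated bumps (noise-free)
        from tests.conftest import rank4_tensor as _  # noqa: F401
        shape = (6, 6, 30, 20, 10)
        factors = []
        for s in shape:
            F = np.zeros((s, 4))
            for k in range(4):
                center = (k + 0.5) * s / 4
                F[:, k] = np.exp(-0.5 * ((np.arange(s) - center) / (s / 8)) ** 2)
            factors.append(F + 0.02)
        X = np.zeros(shape)
        for k in range(4):
            term = factors[0][:, k]
            for f in factors[1:]:
                term = np.multiply.outer(term, f[:, k])
            X += term
        model = fit_parafac(X, K=4, seed=0, tol=1e-12, max_iter=1500)
        assert corcondia(model, X) >= 99.0

    def test_overfactoring_low_score(self):
        rng = np.random.default_rng(4)
        shape = (5, 5, 20, 15, 8)
        factors = []
        for s in shape:
            F = np.zeros((s, 2))
            F[: s // 2, 0] = 1.0
            F[s // 2:, 1] = 1.0
            factors.append(F + 0.05)
        X = np.zeros(shape)
        for k in range(2):
            term = factors[0][:, k]
            for f in factors[1:]:
                term = np.multiply.outer(term, f[:, k])
            X += term
        X += rng.normal(scale=0.01 * X.std(), size=shape)
        X = np.clip(X, 0, None)
        model = fit_parafac(X, K=4, seed=1, max_iter=500)
        assert corcondia(model, X) < 50.0


class TestSelectAndBootstrap:
    def _animal_tensors(self, n=5, seed=0, K=2):
        rng = np.random.default_rng(seed)
        shape = (4, 4, 20, 10, 6)
        base = []
        for k in range(K):
            fs = []
            for s in shape:
                F = np.zeros(s)
                center = (k + 0.5) * s / K
                F[:] = np.exp(-0.5 * ((np.arange(s) - center) / (s / 6)) ** 2)
                fs.append(F + 0.05)
            term = fs[0]
            for f in fs[1:]:
                term = np.multiply.outer(term, f)
            base.append(term)
        out = []
        for a in range(n):
            w = rng.uniform(0.8, 1.2, size=K)
            X = sum(wk * b for wk, b in zip(w, base))
            X = X + rng.normal(scale=0.03 * X.std(), size=shape)
            out.append(np.clip(X, 0, None))
        return out

    def test_rank1_tensors_select_1(self):
        tensors = self._animal_tensors(n=4, K=1)
        K = select_components(tensors, [1, 2, 3], n_diag_boots=3,
                              subset_size=3, seed=0, max_iter=150)
        assert K == 1

    def test_bad_args(self):
        tensors = self._animal_tensors(n=3)
        with pytest.raises(ValueError):
            select_components(tensors, [], n_diag_boots=2, subset_size=2)
        with pytest.raises(ValueError):
            select_components(tensors, [2], n_diag_boots=0, subset_size=2)
        with pytest.raises(ValueError):
            bootstrap_decompose(tensors, n_boot=2, subset_size=9, K=2)

    def test_bootstrap_reproducible_and_sized(self):
        tensors = self._animal_tensors(n=4)
        m1 = bootstrap_decompose(tensors, n_boot=3, subset_size=3, K=2,
                                 seed=9, max_iter=100)
        m2 = bootstrap_decompose(tensors, n_boot=3, subset_size=3, K=2,
                                 seed=9, max_iter=100)
        assert len(m1) == 3
        for a, b in zip(m1, m2):
            for fa, fb in zip(a.factors, b.factors):
                np.testing.assert_array_equal(fa, fb)

    def test_identical_tensors_identical_models(self):
        tensors = self._animal_tensors(n=1) * 4
        models = bootstrap_decompose(tensors, n_boot=3, subset_size=2, K=2,
                                     seed=1, max_iter=200)
        aligned, summary = match_components(models)
        assert np.all(summary["intra_consistency"] > 0.999)


class TestMatchComponents:
    def test_identity_and_permutation(self, rank4_tensor):
        X, _ = rank4_tensor
        model = fit_parafac(X, K=4, seed=0, max_iter=300)
        from laminet.parafac import ParafacModel
        perm = [2, 0, 3, 1]
        permuted = ParafacModel(
            factors=[f[:, perm] for f in model.factors], K=4,
            explained_variance=model.explained_variance,
            n_iter=model.n_iter, converged=model.converged)
        aligned, summary = match_components([model, permuted])
        for f1, f2 in zip(aligned[0].factors, aligned[1].factors):
            np.testing.assert_allclose(f1, f2)
        assert np.all(summary["intra_consistency"] > 0.999)

    def test_mismatched_k_raises(self, rank4_tensor):
        X, _ = rank4_tensor
        m1 = fit_parafac(X, K=2, seed=0, max_iter=50)
        m2 = fit_parafac(X, K=3, seed=0, max_iter=50)
        with pytest.raises(ValueError):
            match_components([m1, m2])
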