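"""Nonnegative PARAFAC (canonical polyadic) decomposition of the group tensor.

The 5-way connectivity tensor is modeled as a sum of K rank-1 components,

    X[sl, tl, t, f, c] ≈ sum_k a[sl,k] b[tl,k] c_t[t,k] d[f,k] e[c,k],

with all loadings nonnegative.  Fitting uses alternating least squares with
HALS (hierarchical, column-wise) nonnegative updates and random
initialization; reconstruction error is non-increasing over iterations.  On
exit the a, b, d, e columns are normalized to variance 1 (scale division, no
centering) with the component scale carried by the temporal loadings, and
components are ordered by descending amplitude share.

Model-order selection refits the model on diagnostic bootstraps of animal
subsets and gates on component stability (per-component consistency across
aligned bootstrap models) and between-component loading correlations;
Corcondia, explained variance and MSE are computed and logged per fit (see
``select_components`` for why they do not gate on this data class).
Robustness of the chosen model is assessed by a larger bootstrap whose
components are aligned across resamples by optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .connectivity import ConnectivityTensor

__all__ = [
    "ParafacModel",
    "fit_parafac",
    "corcondia",
    "select_components",
    "bootstrap_decompose",
    "match_components",
]

MODE_NAMES = ("a", "b", "c", "d", "e")  # source layer, target layer, time,
                                        # frequency, connection


@dataclass
class ParafacModel:
    """Fitted nonnegative PARAFAC model of a 5-way connectivity tensor.

    ``a, b, d, e`` columns have variance 1; the component scale is carried by
    the temporal loadings ``c``.  Components are ordered by descending
    amplitude share (mean temporal loading).
    """

    factors: list                       # [a, b, c, d, e] arrays (I_n x K)
    K: int
    explained_variance: float
    n_iter: int
    converged: bool
    seed: int | None = None
    corcondia_score: float | None = None
    axes: dict = field(default_factory=dict)  # labels per mode

    @property
    def a(self) -> np.ndarray:
        return self.factors[0]

    @property
    def b(self) -> np.ndarray:
        return self.factors[1]

    @property
    def c(self) -> np.ndarray:
        return self.factors[2]

    @property
    def d(self) -> np.ndarray:
        return self.factors[3]

    @property
    def e(self) -> np.ndarray:
        return self.factors[4]

    def reconstruct(self) -> np.ndarray:
        """Full tensor reconstruction (use only at small sizes)."""
        K = self.K
        shape = tuple(f.shape[0] for f in self.factors)
        out = np.zeros(shape)
        for k in range(K):
            term = self.factors[0][:, k]
            for f in self.factors[1:]:
                term = np.multiply.outer(term, f[:, k])
            out += term
        return out

    def amplitude_share(self) -> np.ndarray:
        """Relative amplitude per component from mean temporal loadings."""
        m = self.c.mean(axis=0)
        return m / m.sum()

    def concat_loadings(self, modes=(0, 1, 3, 4)) -> np.ndarray:
        """Concatenated loading vectors over the given modes, (L, K)."""
        return np.concatenate([self.factors[m] for m in modes], axis=0)


def _as_array(tensor) -> np.ndarray:
    if isinstance(tensor, ConnectivityTensor):
        return np.asarray(tensor.values, dtype=np.float64)
    return np.asarray(tensor, dtype=np.float64)


def _axes_dict(tensor) -> dict:
    if isinstance(tensor, ConnectivityTensor):
        return {"layers": list(tensor.layers), "times": np.asarray(tensor.times),
                "freqs": np.asarray(tensor.freqs),
                "connections": list(tensor.connections)}
    return {}


def _mttkrp(X: np.ndarray, factors: list, mode: int) -> np.ndarray:
    """Matricized tensor times Khatri-Rao product for one mode.

    Contracts every mode but ``mode`` with its factor, keeping the component
    axis; contraction starts from the last axis so the dominant cost is a
    single BLAS matmul over the raveled tensor.
    """
    N = X.ndim
    t = X
    axes = list(range(N))
    for m in range(N - 1, -1, -1):
        if m == mode:
            continue
        F = factors[m]
        pos = axes.index(m)
        if t.ndim == len(axes):  # no component axis yet
            t = np.tensordot(t, F, axes=(pos, 0))
        else:  # component axis is last
            t = np.einsum(t, list(range(t.ndim)),
                          F, [pos, t.ndim - 1],
                          [i for i in range(t.ndim) if i != pos])
        axes.pop(pos)
    # remaining axes: (mode, K)
    return np.ascontiguousarray(t)


def _grams(factors: list) -> list:
    return [f.T @ f for f in factors]


def _hals_update(F: np.ndarray, M: np.ndarray, G: np.ndarray,
                 eps: float = 1e-12) -> None:
    """In-place nonnegative HALS column updates: minimize ||X - ...|| over F."""
    K = F.shape[1]
    for k in range(K):
        denom = G[k, k]
        if denom < eps:
            denom = eps
        upd = F[:, k] + (M[:, k] - F @ G[:, k]) / denom
        np.maximum(upd, 0.0, out=upd)
        if not np.any(upd > 0):
            upd[:] = eps  # rescue a dead component
        F[:, k] = upd


def _svd_init(X: np.ndarray, K: int, rng: np.random.Generator) -> list:
    """Magnitudes of leading singular vectors per mode (plus jitter)."""
    factors = []
    for mode in range(X.ndim):
        Xn = np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)
        G = Xn @ Xn.T
        w, V = np.linalg.eigh(G)
        lead = np.abs(V[:, ::-1][:, :K])
        if lead.shape[1] < K:
            extra = rng.uniform(0.1, 1.0, size=(X.shape[mode],
                                                K - lead.shape[1]))
            lead = np.concatenate([lead, extra], axis=1)
        lead = lead + 0.1 * lead.mean() * rng.uniform(0, 1, size=lead.shape)
        factors.append(np.ascontiguousarray(lead))
    return factors


def _fit_once(X: np.ndarray, K: int, rng: np.random.Generator,
              tol: float, max_iter: int, init: str = "random"
              ) -> tuple[list, float, int, bool]:
    shape = X.shape
    if init == "svd":
        factors = _svd_init(X, K, rng)
    else:
        scale = (X.mean() / K) ** (1.0 / X.ndim) if X.mean() > 0 else 1.0
        factors = [rng.uniform(0.1, 1.0, size=(s, K)) * scale for s in shape]
    normX2 = float(np.sum(X ** 2))
    col_scale = [np.linalg.norm(f, axis=0).mean() for f in factors]
    prev_err = None
    err = np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if it % 10 == 0:
            # reseed components that collapsed to (near) zero
            energy = np.ones(K)
            for f in factors:
                energy *= np.linalg.norm(f, axis=0)
            dead = energy < 1e-10 * max(energy.max(), 1e-300)
            for k in np.flatnonzero(dead):
                for m, f in enumerate(factors):
                    f[:, k] = rng.uniform(0.1, 1.0, size=f.shape[0]) \
                        * max(col_scale[m], 1e-6)
                prev_err = None
        for mode in range(X.ndim):
            M = _mttkrp(X, factors, mode)
            grams = _grams(factors)
            G = np.ones((K, K))
            for m, g in enumerate(grams):
                if m != mode:
                    G *= g
            _hals_update(factors[mode], M, G)
        # fit via last mode's quantities
        M = _mttkrp(X, factors, X.ndim - 1)
        gram_all = np.ones((K, K))
        for m in range(X.ndim - 1):
            gram_all *= factors[m].T @ factors[m]
        F_last = factors[-1]
        inner = float(np.sum(M * F_last))
        norm_model = float(np.sum(gram_all * (F_last.T @ F_last)))
        err = max(normX2 - 2.0 * inner + norm_model, 0.0)
        if prev_err is not None:
            denom = max(prev_err, 1e-300)
            if abs(prev_err - err) / denom < tol:
                converged = True
                break
        prev_err = err
    ev = 1.0 - err / normX2 if normX2 > 0 else 0.0
    return factors, ev, it, converged


def _normalize_and_order(factors: list, eps: float = 1e-12) -> list:
    """Variance-1 normalization of a, b, d, e; scale into c; order by share."""
    a, b, c, d, e = factors
    c = c.copy()
    out = []
    for F in (a, b, d, e):
        F = F.copy()
        sd = F.std(axis=0)
        fallback = np.sqrt((F ** 2).mean(axis=0))
        scale = np.where(sd > eps, sd, np.where(fallback > eps, fallback, 1.0))
        F /= scale
        c *= scale
        out.append(F)
    a, b, d, e = out
    order = np.argsort(c.mean(axis=0))[::-1]
    return [a[:, order], b[:, order], c[:, order], d[:, order], e[:, order]]


def fit_parafac(tensor, K: int, seed: int = 0, tol: float = 1e-8,
                max_iter: int = 2000, n_restarts: int = 3) -> ParafacModel:
    """Fit a nonnegative PARAFAC model with random-restart HALS-ALS.

    Parameters
    ----------
    tensor : ConnectivityTensor or nonnegative ndarray.
    K : number of components (>= 1).
    seed : seeds the random initializations (deterministic).
    n_restarts : independent initializations; the best-fit model is kept.

    Raises
    ------
    ValueError for K < 1, negative entries, or an all-zero tensor.
    """
    X = _as_array(tensor)
    if K < 1:
        raise ValueError("K must be >= 1")
    if np.any(X < 0):
        raise ValueError("tensor must be nonnegative")
    if not np.any(X > 0):
        raise ValueError("tensor is all zero")
    root = np.random.SeedSequence(seed)
    best = None
    for r, child in enumerate(root.spawn(max(n_restarts, 1))):
        rng = np.random.default_rng(child)
        factors, ev, it, conv = _fit_once(X, K, rng, tol, max_iter,
                                          init="svd" if r == 0 else "random")
        if best is None or ev > best[1]:
            best = (factors, ev, it, conv)
    factors, ev, it, conv = best
    factors = _normalize_and_order(factors)
    return ParafacModel(factors=factors, K=K, explained_variance=float(ev),
                        n_iter=it, converged=conv, seed=seed,
                        axes=_axes_dict(tensor))


def corcondia(model: ParafacModel, tensor) -> float:
    """Core consistency diagnostic of a fitted model.

    Computes the least-squares core tensor G given the loadings and compares
    it with the superdiagonal target T (ones on the diagonal):
    ``100 · (1 − Σ(g − t)² / Σ t²)``.  Scores near 100 indicate an
    appropriate component count; overfactored models score low (possibly
    negative).  For K = 1 the score is 100 by convention.
    """
    X = _as_array(tensor)
    K = model.K
    if any(not np.any(np.abs(f) > 0) for f in model.factors):
        raise ValueError("degenerate (all-zero) loadings")
    if K == 1:
        return 100.0
    core = X
    for mode in range(X.ndim):
        P = np.linalg.pinv(model.factors[mode])  # (K, I_n)
        core = np.tensordot(core, P, axes=(0, 1))  # rotates axes; mode order kept
    # after contracting each leading axis in turn, core has shape (K,)*ndim
    target = np.zeros_like(core)
    idx = np.arange(K)
    target[tuple(idx for _ in range(X.ndim))] = 1.0
    return float(100.0 * (1.0 - np.sum((core - target) ** 2) / K))


def _decimate(X: np.ndarray, time_stride: int, freq_stride: int) -> np.ndarray:
    if time_stride > 1:
        X = X[:, :, ::time_stride]
    if freq_stride > 1:
        X = X[:, :, :, ::freq_stride]
    return X


def _mean_subset_tensor(tensors: Sequence, subset: np.ndarray,
                        time_stride: int = 1, freq_stride: int = 1
                        ) -> np.ndarray:
    # decimate before accumulating: subsampling commutes with the mean and
    # avoids materializing full-resolution float64 copies per animal
    acc = None
    for i in subset:
        arr = np.asarray(_decimate(
            tensors[i].values if isinstance(tensors[i], ConnectivityTensor)
            else tensors[i], time_stride, freq_stride), dtype=np.float64)
        acc = arr.copy() if acc is None else acc + arr
    return acc / len(subset)


def _max_between_corr(model: ParafacModel) -> float:
    L = model.concat_loadings()
    Ln = (L - L.mean(axis=0)) / (L.std(axis=0) + 1e-300)
    C = (Ln.T @ Ln) / L.shape[0]
    K = model.K
    if K < 2:
        return 0.0
    off = np.abs(C[~np.eye(K, dtype=bool)])
    return float(off.max())


def select_components(tensors: Sequence, K_range: Sequence[int],
                      n_diag_boots: int = 10, subset_size: int = 8,
                      seed: int = 0,
                      stability_min: float = 0.7,
                      between_corr_max: float = 0.8,
                      time_stride: int = 1, freq_stride: int = 1,
                      tol: float = 1e-7, max_iter: int = 200,
                      return_diagnostics: bool = False):
    """Select the PARAFAC component count from bootstrap model diagnostics.

    For each K in ``K_range`` one model is fitted per diagnostic bootstrap
    (the mean tensor of a random animal subset); the models are aligned by
    optimal assignment and summarized.  K* is the largest candidate for
    which

    * every component's intra-bootstrap consistency (mean correlation of its
      aligned loadings across bootstrap pairs) is at least
      ``stability_min`` — components that only capture noise do not
      replicate across animal subsets;
    * the median maximal between-component loading correlation stays below
      ``between_corr_max`` — beyond the true count, extra components
      duplicate existing structure;
    * at least half of the fits converged.

    Corcondia, explained variance and MSE are computed and logged for every
    fit but do not gate the decision: with a dominant additive estimation
    floor the explained-variance curve is nearly flat in K and the
    least-squares core underlying Corcondia is ill-conditioned for broad
    nonnegative loadings, so neither indicator discriminates (both remain
    available in the diagnostics table).

    ``time_stride``/``freq_stride`` decimate the tensor for the diagnostic
    fits only (a runtime measure; the decision is insensitive to the smooth
    oversampled axes).
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValueError("empty K range")
    if n_diag_boots < 1:
        raise ValueError("n_diag_boots must be >= 1")
    if subset_size > len(tensors):
        raise ValueError("subset size exceeds number of animals")
    rng = np.random.default_rng(seed)
    subsets = [rng.choice(len(tensors), size=subset_size, replace=False)
               for _ in range(n_diag_boots)]
    boot_tensors = [
        _mean_subset_tensor(tensors, s, time_stride, freq_stride)
        for s in subsets]
    records = []
    summary = {}
    for K in K_range:
        models = []
        for b, X in enumerate(boot_tensors):
            model = fit_parafac(X, K, seed=int(rng.integers(2**31 - 1)),
                                tol=tol, max_iter=max_iter, n_restarts=1)
            models.append(model)
            records.append({
                "boot": b, "K": K,
                "corcondia": corcondia(model, X),
                "explained_variance": model.explained_variance,
                "mse": (1.0 - model.explained_variance) * float(np.mean(X**2)),
                "converged": model.converged,
                "max_between_corr": _max_between_corr(model),
            })
        if len(models) > 1:
            _, consistency = match_components(models)
            min_intra = float(consistency["intra_consistency"].min())
        else:
            min_intra = 1.0
        summary[K] = {
            "min_intra": min_intra,
            "med_between": float(np.median(
                [r["max_between_corr"] for r in records if r["K"] == K])),
            "frac_converged": float(np.mean(
                [r["converged"] for r in records if r["K"] == K])),
        }
    passing = [K for K in K_range
               if summary[K]["min_intra"] >= stability_min
               and summary[K]["med_between"] < between_corr_max
               and summary[K]["frac_converged"] >= 0.5]
    K_star = max(passing) if passing else min(K_range)
    diag = pd.DataFrame.from_records(records)
    diag["min_intra"] = diag["K"].map(lambda k: summary[k]["min_intra"])
    if return_diagnostics:
        return K_star, diag
    return K_star


def bootstrap_decompose(tensors: Sequence, n_boot: int, subset_size: int,
                        K: int, seed: int = 0,
                        time_stride: int = 1, freq_stride: int = 1,
                        tol: float = 1e-7, max_iter: int = 300,
                        n_restarts: int = 1) -> list:
    """Fit PARAFAC on ``n_boot`` seeded random animal-subset averages."""
    if subset_size > len(tensors):
        raise ValueError("subset size exceeds number of animals")
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_boot):
        subset = rng.choice(len(tensors), size=subset_size, replace=False)
        X = _mean_subset_tensor(tensors, subset, time_stride, freq_stride)
        models.append(fit_parafac(X, K, seed=int(rng.integers(2**31 - 1)),
                                  tol=tol, max_iter=max_iter,
                                  n_restarts=n_restarts))
    return models


def match_components(models: Sequence) -> tuple[list, pd.DataFrame]:
    """Align components across models and summarize their consistency.

    Components of every model are permuted to match the first model by
    maximizing the total correlation of concatenated (a, b, d, e) loadings
    (optimal assignment).  Returns the aligned models and a summary with the
    per-component mean correlation across model pairs (intra) and the mean
    correlation between different components (inter).
    """
    models = list(models)
    if not models:
        raise ValueError("no models to match")
    K = models[0].K
    if any(m.K != K for m in models):
        raise ValueError("models have mismatched component counts")

    def unit(L):
        Ln = L - L.mean(axis=0)
        return Ln / (np.linalg.norm(Ln, axis=0) + 1e-300)

    ref = unit(models[0].concat_loadings())
    aligned = [models[0]]
    for m in models[1:]:
        cur = unit(m.concat_loadings())
        C = ref.T @ cur  # (K, K) correlations
        row, col = linear_sum_assignment(-C)
        perm = col[np.argsort(row)]
        factors = [f[:, perm] for f in m.factors]
        aligned.append(ParafacModel(
            factors=factors, K=K,
            explained_variance=m.explained_variance, n_iter=m.n_iter,
            converged=m.converged, seed=m.seed,
            corcondia_score=m.corcondia_score, axes=m.axes))
    stack = np.stack([unit(m.concat_loadings()) for m in aligned])  # (M, L, K)
    M = len(aligned)
    intra = np.zeros(K)
    inter_vals = []
    # correlations between all model pairs
    Cfull = np.einsum("mlk,nlj->mnkj", stack, stack)
    iu = np.triu_indices(M, k=1)
    pairs = Cfull[iu]  # (n_pairs, K, K)
    for k in range(K):
        intra[k] = pairs[:, k, k].mean()
    off = ~np.eye(K, dtype=bool)
    inter = float(pairs[:, off].mean()) if K > 1 and M > 1 else 0.0
    summary = pd.DataFrame({
        "component": np.arange(K),
        "intra_consistency": intra,
        "inter_consistency": np.full(K, inter),
    })
    return aligned, summary
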