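import numpy as np
import pandas as pd
import pytest

from laminet.preprocess import EpochSet


def make_epochs(signals, fs=250.0, t0=-0.3, areas=None, layers=None):
    """Wrap a (trials, channels, time) array into an EpochSet."""
    signals = np.asarray(signals, dtype=float)
    n_ch = signals.shape[1]
    times = t0 + np.arange(signals.shape[2]) / fs
    if areas is None:
        areas = ["V1"] * n_ch
    if layers is None:
        layers = [f"L{i + 1}" for i in range(n_ch)]
    meta = pd.DataFrame({"area": areas, "layer": layers,
                         "depth": 100.0 * np.arange(n_ch)})
    return EpochSet(signals, fs, times, meta)


def simulate_var(A, sigma, n_trials, n_times, rng, burn=100):
    """Simulate a stationary VAR process with coefficient list A (per lag)."""
    A = [np.atleast_2d(a) for a in A]
    n = A[0].shape[0]
    p = len(A)
    T = n_times + burn
    x = np.zeros((n_trials, n, T))
    innov = rng.normal(scale=np.sqrt(sigma), size=(n_trials, n, T))
    for t in range(T):
        acc = innov[:, :, t].copy()
        for k in range(1, min(p, t) + 1):
            acc += x[:, :, t - k] @ A[k - 1].T
        x[:, :, t] = acc
    return x[:, :, burn:]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def rank4_tensor():
    """Well-separated nonnegative rank-4 tensor with 5% noise + ground truth."""
    rng = np.random.default_rng(7)
    shape = (6, 6, 60, 40, 15)
    K = 4
    factors = []
    for s in shape:
        F = np.zeros((s, K))
        for k in range(K):
            # localized bumps at distinct positions -> well separated
            center = (k + 0.5) * s / K
            F[:, k] = np.exp(-0.5 * ((np.arange(s) - center) / (s / 8)) ** 2)
        F += 0.05
        factors.append(F)
    X = np.zeros(shape)
    for k in range(K):
        term = factors[0][:, k]
        for f in factors[1:]:
            term = np.multiply.outer(term, f[:, k])
        X += term
    noise = rng.normal(scale=0.05 * X.std(), size=shape)
    Xn = np.clip(X + noise, 0.0, None)
    return Xn, factors
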