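"""Time-varying MVAR estimation with an adaptive recursive (Kalman/RLS) scheme.

A time-varying multivariate autoregressive (tvMVAR) model predicts every
channel from the lagged values of all channels,

    x(t) = sum_{k=1..p} A_k(t) x(t-k) + w(t),      w(t) ~ (0, Sigma_w),

with coefficients A_k(t) that follow the data adaptively.  Estimation treats
all trials at a given time point as repeated measurements of the same
regression and down-weights the past exponentially with a filter (forgetting)
factor ``c`` close to 1:

    R(t) = c R(t-1) + Z(t)'Z(t)/N
    r(t) = c r(t-1) + Z(t)'X(t)/N
    A(t) = R(t)^+ r(t)

where Z(t) stacks the p lagged samples of all channels over trials.  The
pseudo-inverse truncates eigenvalues of the regressor covariance below 1e-8 of
the largest, regularizing ill-conditioned updates.  The effective memory is
~1/(1-c) samples; the paper-scale default is c = 0.98 with order p = 15
samples (60 ms at 250 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import EpochSet

__all__ = ["TvMVARModel", "fit_tvmvar", "select_model_order", "parametric_psd"]

_EIG_TRUNC = 1e-8


@dataclass
class TvMVARModel:
    """Fitted time-varying MVAR model.

    Attributes
    ----------
    A : ndarray, shape (n_times, p, n, n)
        AR coefficients; ``A[t, k-1]`` multiplies ``x(t-k)``.
    sigma : ndarray, shape (n, n)
        Residual covariance averaged over time (symmetric PSD).
    sigma_t : ndarray, shape (n_times, n, n) or None
        Exponentially-averaged per-time residual covariance.
    p : int
        Model order in samples.
    c : float
        Filter (forgetting) factor in (0, 1].
    fs : float
        Sampling rate (Hz).
    times : ndarray
        Time axis of the fitted epoch (seconds).
    labels : list of str
        Channel labels.
    burn_in : int
        Number of initial samples that carry initialization values.
    """

    A: np.ndarray
    sigma: np.ndarray
    p: int
    c: float
    fs: float
    times: np.ndarray
    labels: list = field(default_factory=list)
    sigma_t: np.ndarray | None = None
    burn_in: int = 0

    @property
    def n_channels(self) -> int:
        return self.A.shape[-1]

    @property
    def order_ms(self) -> float:
        """Temporal span of the model order in milliseconds."""
        return 1000.0 * self.p / self.fs


def _truncated_solve(R: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Solve R a = r with eigenvalue truncation of the symmetric PSD matrix R."""
    w, V = np.linalg.eigh(R)
    keep = w > _EIG_TRUNC * w[-1]
    if not np.all(keep):
        warnings.warn(
            "ill-conditioned regressor covariance; truncated "
            f"{int((~keep).sum())} eigenvalues", RuntimeWarning, stacklevel=3)
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    return (V * winv) @ (V.T @ r)


def fit_tvmvar(epochs: EpochSet, p: int, c: float = 0.98) -> TvMVARModel:
    """Fit a tvMVAR model by exponentially-weighted recursive least squares.

    Parameters
    ----------
    epochs : EpochSet with n_trials >= 1 and more samples than ``p``.
    p : model order in samples (>= 1).
    c : filter factor in (0, 1]; smaller values track faster but are noisier.

    Returns
    -------
    TvMVARModel with coefficients defined for every time point from ``p`` on;
    the first ``p`` samples replicate the first estimate and are flagged via
    ``burn_in``.
    """
    if not (0.0 < c <= 1.0):
        raise ValueError(f"filter factor c={c} outside (0, 1]")
    if p < 1:
        raise ValueError("model order must be >= 1")
    x = epochs.signals  # (N, n, T)
    n_tr, n, T = x.shape
    if p >= T:
        raise ValueError(f"model order p={p} must be smaller than epoch length {T}")

    d = n * p
    # lagged design per time point: Z[t] has rows [x(t-1); ...; x(t-p)] per trial
    # Warm-start the recursion by cycling over the earliest (baseline)
    # segment until the exponentially-weighted statistics reach steady state;
    # a cold start would otherwise leave a large ramp-in transient in the
    # first ~1/(1-c) samples of the coefficient estimates.
    scale = float(np.mean(x**2)) or 1.0
    R = np.eye(d) * scale * 1e-6
    r = np.zeros((d, n))
    seg_end = min(max(3 * p, int(0.3 * T)), T)
    seg = list(range(p, seg_end))
    target = 3.0 / (1.0 - c) if c < 1.0 else 3 * p
    warm_steps = int(min(max(target, 2 * p), 2000))
    for i in range(warm_steps):
        t = seg[i % len(seg)]
        Z = np.concatenate([x[:, :, t - k] for k in range(1, p + 1)], axis=1)
        R = c * R + (Z.T @ Z) / n_tr
        r = c * r + (Z.T @ x[:, :, t]) / n_tr
    A = np.empty((T, p, n, n))
    sigma_t = np.empty((T, n, n))
    sig_run = np.zeros((n, n))
    sig_sum = np.zeros((n, n))
    count = 0
    for t in range(p, T):
        Z = np.concatenate([x[:, :, t - k] for k in range(1, p + 1)], axis=1)  # (N, d)
        X = x[:, :, t]  # (N, n)
        R = c * R + (Z.T @ Z) / n_tr
        r = c * r + (Z.T @ X) / n_tr
        coef = _truncated_solve(R, r)          # (d, n)
        At = coef.T.reshape(n, p, n).transpose(1, 0, 2)  # (p, n, n): A_k[i, j]
        A[t] = At
        resid = X - Z @ coef
        S = (resid.T @ resid) / max(n_tr - 1, 1)
        sig_run = c * sig_run + (1.0 - c) * S if c < 1.0 else sig_run + S
        sigma_t[t] = sig_run / (1.0 if c < 1.0 else (t - p + 1))
        sig_sum += S
        count += 1
    A[:p] = A[p]
    sigma_t[:p] = sigma_t[p]
    sigma = sig_sum / max(count, 1)
    sigma = 0.5 * (sigma + sigma.T)
    labels = [f"ch{i}" for i in range(n)]
    if "area" in epochs.channels:
        labels = [
            f"{row.area}/{row.layer}" if row.layer else f"ch{i}"
            for i, row in enumerate(epochs.channels.itertuples())
        ]
    return TvMVARModel(A=A, sigma=sigma, p=p, c=c, fs=epochs.fs,
                       times=epochs.times, labels=labels,
                       sigma_t=sigma_t, burn_in=p)


def parametric_psd(model: TvMVARModel, freqs: Sequence[float]) -> np.ndarray:
    """Power spectral density implied by the tvMVAR coefficients.

    ``P(t, f, i) = [H(f, t) Sigma_w H(f, t)^H]_ii`` with
    ``H = Abar^{-1}`` and ``Abar(f, t) = I − sum_k A_k(t) e^{−i 2π f k / fs}``.

    Raises
    ------
    ValueError
        For frequencies above Nyquist or a singular ``Abar`` (the offending
        frequency is named).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs > model.fs / 2.0):
        bad = freqs[freqs > model.fs / 2.0]
        raise ValueError(f"frequencies above Nyquist ({model.fs / 2} Hz): {bad}")
    T, p, n, _ = model.A.shape
    F = len(freqs)
    E = np.exp(-2j * np.pi * np.outer(np.arange(1, p + 1), freqs) / model.fs)  # (p, F)
    out = np.empty((T, F, n))
    I = np.eye(n)
    for t in range(T):
        Abar = I[None] - np.tensordot(E, model.A[t], axes=(0, 0))  # (F, n, n)
        sig = model.sigma_t[t] if model.sigma_t is not None else model.sigma
        for fi in range(F):
            M = Abar[fi]
            if abs(np.linalg.det(M)) < 1e-300:
                raise ValueError(f"singular spectral matrix at f={freqs[fi]} Hz")
            H = np.linalg.inv(M)
            out[t, fi] = np.real(np.einsum("ij,jk,ik->i", H, sig, H.conj()))
    return out


def select_model_order(
    epochs: EpochSet,
    candidates: Sequence[int],
    reference_spectra: np.ndarray,
    freqs: Sequence[float],
    c: float = 0.98,
    return_errors: bool = False,
):
    """Select the tvMVAR order matching a nonparametric reference spectrum.

    For each candidate order a model is fitted and its parametric PSD compared
    with the reference (e.g. Morlet-wavelet) power in log units, after
    aligning the per-channel mean log level (the two estimators carry
    different arbitrary unit factors).  Returns the candidate minimizing the
    mean squared log difference over (time, frequency, channel); ties break to
    the smallest order.

    Parameters
    ----------
    reference_spectra : ndarray, shape (n_times, n_freqs, n_channels)
        Must share the epoch's time axis and ``freqs``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate order list is empty")
    ref = np.asarray(reference_spectra, dtype=float)
    logref = np.log(np.maximum(ref, 1e-300))
    errors = {}
    for p in sorted(candidates):
        model = fit_tvmvar(epochs, p=p, c=c)
        psd = parametric_psd(model, freqs)
        sl = slice(max(model.burn_in, 1), None)
        lp = np.log(np.maximum(psd[sl], 1e-300))
        lr = logref[sl]
        # per-channel scale alignment
        offset = (lp - lr).mean(axis=(0, 1), keepdims=True)
        errors[p] = float(np.mean((lp - lr - offset) ** 2))
    best = min(sorted(errors), key=lambda k: errors[k])
    if return_errors:
        return best, errors
    return best
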