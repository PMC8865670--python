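"""Statistical characterization of decomposed network components.

Given bootstrap distributions of PARAFAC loadings, this module answers the
standard descriptive questions about each network: which layers carry it
(laminar significance against a uniform layer profile), how it evolves in
time (percent change from baseline with Bonferroni-corrected per-timepoint
tests), how large it is (amplitude share), what its frequency profile is
(power-law vs lognormal vs exponential curve fits), and whether its temporal
dynamics are rhythmically modulated (detrended Fourier spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SpectralFit",
    "laminar_significance",
    "temporal_stats",
    "amplitude_share",
    "fit_frequency_models",
    "modulation_spectrum",
]


def laminar_significance(loadings: np.ndarray, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Flag layers whose loading exceeds a uniform layer profile.

    Each bootstrap's layer-loading vector is normalized to sum 1; a layer is
    flagged when the lower bound of the bootstrap (1−alpha) confidence
    interval of its normalized weight exceeds 1/n_layers (the uniform value).

    Parameters
    ----------
    loadings : ndarray, shape (n_layers, n_boot), nonnegative.

    Returns
    -------
    DataFrame with columns layer, mean_weight, ci_low, ci_high, significant.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need layer x bootstrap loadings with >= 2 bootstraps")
    norm = L / L.sum(axis=0, keepdims=True)
    lo = np.percentile(norm, 100 * alpha / 2, axis=1)
    hi = np.percentile(norm, 100 * (1 - alpha / 2), axis=1)
    uniform = 1.0 / L.shape[0]
    return pd.DataFrame({
        "layer": np.arange(L.shape[0]),
        "mean_weight": norm.mean(axis=1),
        "ci_low": lo,
        "ci_high": hi,
        "significant": lo > uniform,
    })


def temporal_stats(c_t: np.ndarray, times: np.ndarray,
                   baseline: tuple[float, float] = (-0.3, 0.0),
                   alpha: float = 0.05, burn_in: int = 0,
                   two_sided: bool = False) -> pd.DataFrame:
    """Percent change of temporal loadings with per-timepoint significance.

    ``percent = 100 · (x − x̄_base) / x̄_base`` with the baseline mean taken
    per bootstrap over the pre-stimulus window (excluding the model burn-in).
    Each post-stimulus timepoint is tested across bootstraps against the
    baseline mean (one-sided increase by default), Bonferroni-corrected by
    the number of post-stimulus timepoints.

    Parameters
    ----------
    c_t : ndarray, shape (n_times, n_boot).
    """
    X = np.asarray(c_t, dtype=float)
    times = np.asarray(times, dtype=float)
    t0, t1 = baseline
    if t0 >= times[-1] or t1 > 0 + 1e-12 and t1 > times[-1]:
        raise ValueError("baseline window outside epoch")
    base_sel = (times >= t0) & (times <= t1)
    base_sel[:burn_in] = False
    if not np.any(base_sel):
        raise ValueError("baseline window is empty")
    base = X[base_sel].mean(axis=0)  # per bootstrap
    if np.any(np.abs(base.mean()) < 1e-300):
        raise ValueError("zero baseline mean")
    pct = 100.0 * (X - base[None, :]) / base[None, :]
    post = times > 0
    n_post = int(post.sum())
    pvals = np.full(len(times), np.nan)
    diffs = X - base[None, :]
    for i in np.flatnonzero(post):
        d = diffs[i]
        if np.allclose(d.std(), 0.0):
            pvals[i] = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
            continue
        t_stat, p2 = stats.ttest_1samp(d, 0.0)
        if two_sided:
            pvals[i] = p2
        else:
            pvals[i] = p2 / 2.0 if t_stat > 0 else 1.0 - p2 / 2.0
    sig = pvals < alpha / max(n_post, 1)
    return pd.DataFrame({
        "time": times,
        "percent_change": pct.mean(axis=1),
        "percent_change_sd": pct.std(axis=1),
        "p": pvals,
        "significant": np.where(np.isnan(pvals), False, sig),
    })


def amplitude_share(models) -> pd.DataFrame:
    """Amplitude share of each component over bootstrap models.

    The share of component k in one model is its mean temporal loading
    divided by the sum of all components' mean temporal loadings; shares are
    summarized as mean ± SD over models.
    """
    shares = np.stack([m.amplitude_share() for m in models])  # (M, K)
    return pd.DataFrame({
        "component": np.arange(shares.shape[1]),
        "share_mean": shares.mean(axis=0),
        "share_sd": shares.std(axis=0),
    })


@dataclass
class SpectralFit:
    """Frequency-profile model comparison result.

    ``params`` per family: powerlaw (c, beta) for c·f^−β; lognormal
    (c, mu, sigma) for c·LogN(f; mu, sigma); exponential (c, beta) for
    c·e^{β·f}.  ``best`` attains the minimum MSE; failed fits carry
    infinite MSE.
    """

    params: dict
    mse: dict
    best: str


def _powerlaw(f, c, beta):
    return c * f ** (-beta)


def _lognormal(f, c, mu, sigma):
    return c / (f * np.abs(sigma) * np.sqrt(2 * np.pi)) * np.exp(
        -((np.log(f) - mu) ** 2) / (2 * sigma ** 2))


def _exponential(f, c, beta):
    return c * np.exp(beta * f)


def fit_frequency_models(d: np.ndarray, freqs: np.ndarray) -> SpectralFit:
    """Fit power-law, lognormal and exponential curves to a frequency loading.

    Nonlinear least squares in linear space; the family with the lowest mean
    squared error wins.  Initialization: powerlaw (c = value at the lowest
    frequency, β = 1), lognormal (μ = log of the argmax frequency, σ = 1),
    exponential (c = max, β = −0.05).

    Raises
    ------
    ValueError for non-positive frequencies, negative loadings, or when all
    three fits fail.
    """
    d = np.asarray(d, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(d < 0):
        raise ValueError("loading must be nonnegative")
    fams = {
        "powerlaw": (_powerlaw, [max(d[0], 1e-9), 1.0]),
        "lognormal": (_lognormal,
                      [max(d.max(), 1e-9) * freqs[np.argmax(d)],
                       float(np.log(freqs[np.argmax(d)])), 1.0]),
        "exponential": (_exponential, [max(d.max(), 1e-9), -0.05]),
    }
    params, mse = {}, {}
    for name, (fn, p0) in fams.items():
        try:
            popt, _ = optimize.curve_fit(fn, freqs, d, p0=p0, maxfev=20000)
            resid = d - fn(freqs, *popt)
            params[name] = tuple(float(v) for v in popt)
            mse[name] = float(np.mean(resid ** 2))
        except Exception:
            params[name] = None
            mse[name] = np.inf
    if all(np.isinf(v) for v in mse.values()):
        raise ValueError("all frequency-model fits failed")
    best = min(mse, key=mse.get)
    return SpectralFit(params=params, mse=mse, best=best)


def modulation_spectrum(c_t: np.ndarray, times: np.ndarray,
                        window: tuple[float, float] = (0.0, 1.0)
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude spectrum of the (detrended) post-stimulus temporal loading.

    A linear trend is removed from the windowed loading before the discrete
    Fourier transform; frequency resolution is 1/window-length.  Reveals
    rhythmic modulation of a network's amplitude dynamics (e.g. theta-band
    modulation of feedforward networks).

    Returns
    -------
    (freqs_hz, amplitude) — one-sided spectrum excluding DC.
    """
    times = np.asarray(times, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    x = np.asarray(c_t, dtype=float)[sel]
    if x.shape[0] < 2:
        raise ValueError("window shorter than 2 samples")
    fs = 1.0 / np.mean(np.diff(times[sel]))
    from scipy.signal import detrend
    xd = detrend(x, axis=0, type="linear")
    amp = np.abs(np.fft.rfft(xd, axis=0)) / x.shape[0]
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fs)
    return freqs[1:], amp[1:]
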