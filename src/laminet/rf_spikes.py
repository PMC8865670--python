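"""Receptive-field convergence and spike–network coupling analyses.

Receptive fields (RFs) are detected per recording site by a permutation test
on position-tuned responses; significant sites get a centroid, and distances
between source and target centroids are regressed against reconstructed
between-area connection strengths with a linear mixed-effects model
(random intercepts for bootstrap and connection).  Feedforward streams are
expected to show *convergent* interactions (strength decreasing with RF
distance), feedback streams divergent or no RF dependence.

Spiking activity is pooled per (area, layer) into 4-ms bins (units below the
SNR threshold excluded) and correlated with the bootstrapped temporal
loadings of each network; significance comes from the central 95 % of the
bootstrap correlation distribution excluding zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RFMap",
    "detect_rf",
    "rf_distance",
    "reconstruct_connection_strength",
    "regress_rf",
    "bin_spikes",
    "correlate_networks_spikes",
]


@dataclass
class RFMap:
    """Receptive-field detection result for one site."""

    significant: bool
    p_value: float
    centroid: tuple[float, float] | None  # (azimuth, elevation), degrees
    site: int | None = None


def detect_rf(responses: pd.DataFrame, n_perm: int = 1000,
              alpha: float = 0.05, seed: int = 0,
              centroid_threshold: float = 0.5) -> RFMap:
    """Permutation test for a significant receptive field at one site.

    The observed statistic is the maximum position-mean response; the null is
    built by permuting position labels across trials.  The p-value is the
    fraction of null statistics at least as large as observed (add-one
    estimator, so p ∈ (0, 1]).  For significant sites the centroid is the
    response-weighted mean position over pixels above
    ``centroid_threshold`` × max mean response (half-max by default).

    Parameters
    ----------
    responses : DataFrame with columns azimuth, elevation, response (one row
        per trial and stimulus position).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pos_key = responses[["azimuth", "elevation"]].apply(tuple, axis=1)
    codes, uniques = pd.factorize(pos_key)
    vals = responses["response"].to_numpy(dtype=float)
    n_pos = len(uniques)
    counts = np.bincount(codes, minlength=n_pos)
    sums = np.bincount(codes, weights=vals, minlength=n_pos)
    means = sums / np.maximum(counts, 1)
    observed = means.max()
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(codes)
        s = np.bincount(perm, weights=vals, minlength=n_pos)
        null[i] = (s / np.maximum(counts, 1)).max()
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    significant = p < alpha
    centroid = None
    if significant:
        supra = means >= centroid_threshold * observed
        pos = np.array([list(u) for u in uniques], dtype=float)
        w = means[supra]
        centroid = tuple(np.average(pos[supra], axis=0, weights=w))
    site = int(responses["site"].iloc[0]) if "site" in responses else None
    return RFMap(significant=bool(significant), p_value=float(p),
                 centroid=centroid, site=site)


def rf_distance(c1, c2) -> float:
    """Euclidean distance between two RF centroids, in degrees."""
    if c1 is None or c2 is None:
        raise ValueError("both centroids must be defined (significant RFs)")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    return float(np.linalg.norm(c1 - c2))


def reconstruct_connection_strength(model, k: int) -> np.ndarray:
    """Per-connection mean reconstructed strength of one component.

    Averaging the rank-1 reconstruction ``a ⊗ b ⊗ c ⊗ d ⊗ e`` over source
    layers, target layers, time and frequency factorizes into
    ``e[:, k] · mean(a) · mean(b) · mean(c) · mean(d)``.
    """
    if not (0 <= k < model.K):
        raise ValueError(f"component {k} out of range for K={model.K}")
    scale = 1.0
    for f in model.factors[:4]:
        scale *= float(f[:, k].mean())
    return model.factors[4][:, k] * scale


def regress_rf(strengths: pd.DataFrame, distances: pd.DataFrame,
               reml: bool = False) -> dict:
    """Mixed-effects regression of connection strength on RF distance.

    Model: ``strength ~ distance`` with random intercepts for bootstrap and
    connection (variance components), fitted by maximum likelihood; a
    likelihood-ratio test against the fixed-effects-only OLS model is
    reported along with naive adjusted R² on fitted-vs-observed values.

    Parameters
    ----------
    strengths : DataFrame with columns connection, bootstrap, strength.
    distances : DataFrame with columns connection, distance (only
        connections with significant RFs at both ends).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = strengths.merge(distances, on="connection", how="inner")
    if df["connection"].nunique() < 2:
        raise ValueError("need >= 2 connections with significant RFs")
    if df["connection"].nunique() < 2 and df["bootstrap"].nunique() < 2:
        raise ValueError("single grouping level in both random factors")
    df = df.copy()
    df["group"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(
            "strength ~ distance", df, groups="group",
            vc_formula={"conn": "0 + C(connection)",
                        "boot": "0 + C(bootstrap)"})
        fit = md.fit(reml=reml, method="lbfgs", maxiter=200)
        ols = smf.ols("strength ~ distance", df).fit()
    lr = 2.0 * (fit.llf - ols.llf)
    lr_p = stats.chi2.sf(max(lr, 0.0), df=2)
    resid = df["strength"] - fit.fittedvalues
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((df["strength"] - df["strength"].mean()) ** 2))
    n, p = len(df), 2
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return {
        "slope": float(fit.params["distance"]),
        "slope_p": float(fit.pvalues["distance"]),
        "intercept": float(fit.params["Intercept"]),
        "lr_stat": float(lr),
        "lr_p": float(lr_p),
        "r2_adj": float(r2_adj),
        "fit": fit,
    }


def bin_spikes(spikes: pd.DataFrame, binsize: float = 0.004,
               window: tuple[float, float] = (0.0, 1.0),
               snr_min: float = 3.0,
               exclude_layers: tuple = ("L1",)) -> pd.DataFrame:
    """Pool qualifying units into per-(area, layer) spike-count series.

    Units at or below ``snr_min`` are excluded, as are layers in
    ``exclude_layers`` (L1 by default, which carries too little spiking for
    stable rates; pass an empty tuple to keep it).  Counts are conserved:
    the summed series equals the number of in-window spikes of qualifying
    units.  Sites with no qualifying unit are emitted with all-zero counts
    and a warning.

    Returns
    -------
    DataFrame with columns area, layer, bin_start, count, n_units.
    """
    lo, hi = window
    n_bins = (hi - lo) / binsize
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("binsize must divide the window length")
    n_bins = int(round(n_bins))
    edges = lo + np.arange(n_bins + 1) * binsize
    out = []
    for (area, layer), grp in spikes.groupby(["area", "layer"], sort=True):
        if layer in exclude_layers:
            continue
        ok = grp[grp["snr"] > snr_min]
        n_units = ok["unit"].nunique()
        if n_units == 0:
            warnings.warn(f"no units above SNR {snr_min} for {area}/{layer}",
                          RuntimeWarning, stacklevel=2)
            counts = np.zeros(n_bins, dtype=int)
        else:
            t = ok["time_s"].to_numpy(dtype=float)
            t = t[(t >= lo) & (t < hi)]
            counts, _ = np.histogram(t, bins=edges)
        for b in range(n_bins):
            out.append((area, layer, float(edges[b]), int(counts[b]), n_units))
    return pd.DataFrame(out, columns=["area", "layer", "bin_start",
                                      "count", "n_units"])


def correlate_networks_spikes(loadings: np.ndarray, loading_times: np.ndarray,
                              rates: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Correlate bootstrapped temporal loadings with laminar firing rates.

    The loading series (time × bootstrap) is resampled onto the spike-bin
    grid; the Pearson correlation with the pooled spike-count series is
    computed per bootstrap.  A site is significant when the central
    (1 − alpha) interval of the bootstrap correlation distribution excludes
    zero.  Constant rate series (undefined correlation) are flagged and
    excluded.

    Returns
    -------
    DataFrame with columns area, layer, r, r_lo, r_hi, significant, valid.
    """
    L = np.asarray(loadings, dtype=float)
    loading_times = np.asarray(loading_times, dtype=float)
    rows = []
    for (area, layer), grp in rates.groupby(["area", "layer"], sort=True):
        grp = grp.sort_values("bin_start")
        y = grp["count"].to_numpy(dtype=float)
        # loadings (4-ms native grid) and spike bins share the same grid
        centers = grp["bin_start"].to_numpy(dtype=float)
        if np.allclose(y.std(), 0.0):
            rows.append((area, layer, np.nan, np.nan, np.nan, False, False))
            continue
        X = np.empty((len(y), L.shape[1]))
        for b in range(L.shape[1]):
            X[:, b] = np.interp(centers, loading_times, L[:, b])
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc)
        with np.errstate(invalid="ignore"):
            r = (Xc.T @ yc) / denom
        r = r[np.isfinite(r)]
        if r.size == 0:
            rows.append((area, layer, np.nan, np.nan, np.nan, False, False))
            continue
        lo = np.percentile(r, 100 * alpha / 2)
        hi = np.percentile(r, 100 * (1 - alpha / 2))
        sig = (lo > 0) or (hi < 0)
        rows.append((area, layer, float(r.mean()), float(lo), float(hi),
                     bool(sig), True))
    return pd.DataFrame(rows, columns=["area", "layer", "r", "r_lo", "r_hi",
                                       "significant", "valid"])
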