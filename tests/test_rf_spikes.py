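import numpy as np
import pandas as pd
import pytest

from laminet.rf_spikes import (
    bin_spikes,
    correlate_networks_spikes,
    detect_rf,
    reconstruct_connection_strength,
    regress_rf,
    rf_distance,
)


def gaussian_rf_responses(cx=10.0, cy=5.0, noise=0.1, seed=0,
                          grid_step=10.0, n_trials=12):
    rng = np.random.default_rng(seed)
    rows = []
    for az in np.arange(-55, 56, grid_step):
        for el in np.arange(-42.5, 43, grid_step):
            mu = np.exp(-((az - cx) ** 2 + (el - cy) ** 2) / (2 * 12.0 ** 2))
            for tr in range(n_trials):
                rows.append((0, az, el, tr,
                             max(mu + rng.normal(scale=noise), 0.0)))
    return pd.DataFrame(rows, columns=["site", "azimuth", "elevation",
                                       "trial", "response"])


class TestDetectRF:
    def test_planted_gaussian_centroid(self):
        df = gaussian_rf_responses(cx=10.0, cy=5.0, noise=0.05)
        m = detect_rf(df, n_perm=300, seed=1)
        assert m.significant
        assert abs(m.centroid[0] - 10.0) <= 10.0
        assert abs(m.centroid[1] - 5.0) <= 10.0

    def test_alpha_zero_never_significant(self):
        df = gaussian_rf_responses(noise=0.05)
        m = detect_rf(df, n_perm=200, alpha=0.0, seed=1)
        assert not m.significant
        assert m.centroid is None

    def test_nperm_floor(self):
        df = gaussian_rf_responses()
        with pytest.raises(ValueError):
            detect_rf(df, n_perm=50)

    def test_null_type_i_rate(self):
        """Label-shuffled responses significant in about alpha of seeds."""
        rng = np.random.default_rng(3)
        n_sig = 0
        n_rep = 200
        base = gaussian_rf_responses(noise=0.05, n_trials=6)
        for i in range(n_rep):
            df = base.copy()
            df["response"] = rng.permutation(df["response"].to_numpy())
            if detect_rf(df, n_perm=150, alpha=0.05, seed=i).significant:
                n_sig += 1
        assert n_sig / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_null_pvalues_uniform(self):
        """Permutation p-values are ~uniform under the null (KS test)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(4)
        pvals = []
        az = np.repeat(np.arange(8.0), 8 * 5)
        el = np.tile(np.repeat(np.arange(8.0), 5), 8)
        for i in range(300):
            df = pd.DataFrame({
                "site": 0, "azimuth": az, "elevation": el,
                "trial": np.tile(np.arange(5), 64),
                "response": rng.normal(size=len(az))})
            pvals.append(detect_rf(df, n_perm=199, seed=i).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRFDistance:
    def test_pythagoras(self):
        assert rf_distance((0, 0), (3, 4)) == 5.0

    def test_identity_and_symmetry(self):
        assert rf_distance((2, 2), (2, 2)) == 0.0
        assert rf_distance((1, 2), (4, 6)) == rf_distance((4, 6), (1, 2))

    def test_missing_centroid(self):
        with pytest.raises(ValueError):
            rf_distance(None, (0, 0))


class TestReconstruction:
    def test_all_ones_returns_connection_loading(self):
        from laminet.parafac import ParafacModel
        factors = [np.ones((s, 2)) for s in (6, 6, 10, 5, 30)]
        model = ParafacModel(factors=factors, K=2, explained_variance=1.0,
                            n_iter=1, converged=True)
        out = reconstruct_connection_strength(model, 0)
        np.testing.assert_allclose(out, 1.0)

    def test_matches_bruteforce_tensor_average(self, rank4_tensor):
        from laminet.parafac import fit_parafac
        X, _ = rank4_tensor
        model = fit_parafac(X, K=3, seed=0, max_iter=100)
        for k in range(3):
            fast = reconstruct_connection_strength(model, k)
            full = np.einsum("a,b,c,d,e->abcde",
                             model.a[:, k], model.b[:, k], model.c[:, k],
                             model.d[:, k], model.e[:, k])
            brute = full.mean(axis=(0, 1, 2, 3))
            np.testing.assert_allclose(fast, brute, atol=1e-10)

    def test_multilinearity_and_bounds(self, rank4_tensor):
        from laminet.parafac import fit_parafac, ParafacModel
        X, _ = rank4_tensor
        model = fit_parafac(X, K=2, seed=0, max_iter=50)
        doubled = ParafacModel(
            factors=[model.a, model.b, 2.0 * model.c, model.d, model.e],
            K=2, explained_variance=1.0, n_iter=1, converged=True)
        np.testing.assert_allclose(
            reconstruct_connection_strength(doubled, 1),
            2.0 * reconstruct_connection_strength(model, 1))
        with pytest.raises(ValueError):
            reconstruct_connection_strength(model, 5)


class TestRegressRF:
    def _planted(self, slope=-0.02, seed=0, n_conn=12, n_boot=200, noise=0.01):
        rng = np.random.default_rng(seed)
        dist = rng.uniform(5, 50, size=n_conn)
        conn_off = rng.normal(scale=0.005, size=n_conn)
        boot_off = rng.normal(scale=0.005, size=n_boot)
        rows = []
        for b in range(n_boot):
            for c in range(n_conn):
                y = 1.0 + slope * dist[c] + conn_off[c] + boot_off[b] \
                    + rng.normal(scale=noise)
                rows.append((f"c{c}", b, y))
        strengths = pd.DataFrame(rows,
                                 columns=["connection", "bootstrap",
                                          "strength"])
        distances = pd.DataFrame({"connection": [f"c{c}" for c in
                                                 range(n_conn)],
                                  "distance": dist})
        return strengths, distances

    def test_negative_slope_recovered(self):
        s, d = self._planted(slope=-0.02)
        out = regress_rf(s, d)
        assert out["slope"] < 0
        assert out["slope_p"] < 0.01

    def test_null_slope_not_significant(self):
        hits = 0
        for seed in range(20):
            s, d = self._planted(slope=0.0, seed=seed, n_boot=40)
            out = regress_rf(s, d)
            hits += out["slope_p"] < 0.05
        assert hits <= 4  # ~alpha of 20 runs, generous binomial slack

    def test_too_few_connections(self):
        s, d = self._planted(n_conn=1)
        with pytest.raises(ValueError):
            regress_rf(s, d)


class TestBinSpikes:
    def _spikes(self, times, snr=5.0, area="V1", layer="L4", unit=0):
        return pd.DataFrame({"unit": unit, "area": area, "layer": layer,
                             "time_s": times, "snr": snr})

    def test_basic_binning(self):
        df = self._spikes([0.002, 0.006, 0.010])
        out = bin_spikes(df, binsize=0.004, window=(0.0, 1.0))
        counts = out["count"].to_numpy()
        assert counts[:3].tolist() == [1, 1, 1]
        assert counts.sum() == 3

    def test_count_conservation_with_filtering(self):
        rng = np.random.default_rng(0)
        good = self._spikes(rng.uniform(0, 1, 100), snr=5.0, unit=0)
        bad = self._spikes(rng.uniform(0, 1, 50), snr=2.0, unit=1)
        df = pd.concat([good, bad], ignore_index=True)
        out = bin_spikes(df, binsize=0.004)
        assert out["count"].sum() == 100  # SNR <= 3 units excluded

    def test_l1_excluded_by_default(self):
        df = self._spikes([0.1, 0.2], layer="L1")
        out = bin_spikes(df)
        assert out.empty
        out2 = bin_spikes(df, exclude_layers=())
        assert out2["count"].sum() == 2

    def test_all_low_snr_warns_empty(self):
        df = self._spikes([0.1], snr=1.0)
        with pytest.warns(RuntimeWarning):
            out = bin_spikes(df)
        assert out["count"].sum() == 0

    def test_bad_binsize(self):
        with pytest.raises(ValueError):
            bin_spikes(self._spikes([0.1]), binsize=0.003, window=(0.0, 1.0))


class TestCorrelateNetworksSpikes:
    def _rates_from(self, series, area="V1", layer="L4"):
        bins = np.arange(len(series)) * 0.004
        return pd.DataFrame({"area": area, "layer": layer,
                             "bin_start": bins, "count": series,
                             "n_units": 3})

    def test_affine_rate_gives_r_one(self):
        times = np.arange(0, 1.0, 0.004)
        load = 1.0 + np.sin(2 * np.pi * 3 * times)
        L = np.tile(load[:, None], (1, 30))
        rates = self._rates_from((5 + 3 * load).astype(int))
        # integer cast breaks exact affinity; use a float-friendly count
        rates["count"] = 5 + 3 * load[: len(rates)]
        out = correlate_networks_spikes(L, times, rates)
        assert out["r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert out["significant"].iloc[0]

    def test_constant_rate_flagged_invalid(self):
        times = np.arange(0, 1.0, 0.004)
        L = np.random.default_rng(0).uniform(1, 2, size=(len(times), 10))
        rates = self._rates_from(np.full(len(times), 4))
        out = correlate_networks_spikes(L, times, rates)
        assert not out["valid"].iloc[0]

    def test_independent_noise_mostly_nonsignificant(self):
        rng = np.random.default_rng(1)
        times = np.arange(0, 1.0, 0.004)
        n_sig = 0
        n_rep = 100
        for _ in range(n_rep):
            base = rng.normal(size=len(times))
            # bootstrap scatter comparable to the shared structure, as for
            # loadings re-estimated from resampled animal subsets
            L = base[:, None] + 1.5 * rng.normal(size=(len(times), 40))
            rates = self._rates_from(rng.poisson(5, size=len(times)))
            out = correlate_networks_spikes(L, times, rates)
            n_sig += int(out["significant"].iloc[0])
        assert n_sig / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
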