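import numpy as np
import pytest

from laminet import synthgen as sg
from laminet.synthgen import (
    _max_spectral_radius,
    default_config,
    reduced_config,
    simulate_epochs,
    simulate_rfs,
    simulate_spikes,
)


class TestDefaultConfig:
    @pytest.mark.parametrize("contrast,peak", [("high", 38.0), ("low", 26.0)])
    def test_gamma_peak_frequency(self, contrast, peak):
        planted = default_config(contrast)
        gamma = next(c for c in planted.components if c.name == "gamma_ff")
        assert sg.FREQS[np.argmax(gamma.spectrum)] == peak

    def test_four_components_and_weight_sums(self):
        for factory in (default_config, reduced_config):
            for contrast in ("high", "low"):
                planted = factory(contrast)
                assert len(planted.components) == 4
                for c in planted.components:
                    assert np.sum(c.source_weights) == pytest.approx(1.0)
                    assert np.sum(c.target_weights) == pytest.approx(1.0)
                    assert np.all(c.envelope >= 0)
                    assert np.all(c.spectrum >= 0)

    def test_invalid_contrast(self):
        with pytest.raises(ValueError):
            default_config("medium")

    def test_default_geometry(self):
        planted = default_config("high")
        assert planted.n_channels == 36
        assert len(planted.connections) == 30
        assert planted.fs == 250.0
        np.testing.assert_allclose(planted.times[0], -0.3)
        np.testing.assert_allclose(planted.times[-1], 1.0)


class TestStability:
    def test_reduced_config_stable_everywhere(self):
        planted = reduced_config("high")
        A = planted.stabilized_coefficients()
        rho = _max_spectral_radius(A, stride=1)
        assert rho < 1.0
        assert rho <= planted.radius_cap + 1e-6

    def test_default_config_stable_on_grid(self):
        for contrast in ("high", "low"):
            planted = default_config(contrast)
            A = planted.stabilized_coefficients()
            assert _max_spectral_radius(A, stride=8) < 1.0


class TestSimulateEpochs:
    def test_seeded_determinism(self):
        planted = reduced_config("high")
        e1 = simulate_epochs(planted, n_trials=5, seed=3)
        e2 = simulate_epochs(planted, n_trials=5, seed=3)
        np.testing.assert_array_equal(e1.signals, e2.signals)
        e3 = simulate_epochs(planted, n_trials=5, seed=4)
        assert not np.array_equal(e1.signals, e3.signals)

    def test_shape_and_axes(self):
        planted = reduced_config("high")
        ep = simulate_epochs(planted, n_trials=7, seed=0)
        assert ep.signals.shape == (7, 9, len(planted.times))
        assert ep.fs == 250.0
        assert list(ep.channels["area"][:3]) == ["V1", "V1", "V1"]

    def test_zero_coupling_ipdc_floor(self):
        """With all couplings off, between-area iPDC stays at the noise floor."""
        from laminet.connectivity import build_group_tensor, ipdc
        from laminet.stok import fit_tvmvar

        planted = reduced_config("high")
        def group_values(ep):
            m = fit_tvmvar(ep, p=8, c=0.98)
            t = ipdc(m, np.arange(1.0, 101.0, 4.0), channels=ep.channels,
                     animal="A0")
            return build_group_tensor([t]).values

        ep0 = simulate_epochs(planted, n_trials=60, seed=1,
                              gains=np.zeros(4))
        v0 = group_values(ep0)
        # null: independent white noise with the same geometry
        rng = np.random.default_rng(9)
        from tests.conftest import make_epochs
        white = rng.normal(size=ep0.signals.shape)
        epw = make_epochs(white, fs=250.0,
                          areas=list(ep0.channels["area"]),
                          layers=list(ep0.channels["layer"]))
        vw = group_values(epw)
        assert np.median(v0) < 3.0 * np.percentile(vw, 95)

    def test_n_trials_validation(self):
        with pytest.raises(ValueError):
            simulate_epochs(reduced_config("high"), n_trials=0)


class TestSimulateSpikes:
    def test_poisson_mean_constant_rate(self):
        """Unmodulated 10 Hz units produce ~10 spikes/s on average."""
        planted = reduced_config("high")
        df = simulate_spikes(planted, seed=0, units_per_site=40,
                             base_rates={"": 10.0},
                             gains={}, window=(0.0, 1.0))
        n_units = planted.n_channels * 40
        mean_count = len(df) / n_units
        # lognormal(0, 0.25) unit jitter has mean exp(0.25^2/2) ~ 1.032
        assert mean_count == pytest.approx(10.0 * 1.032, rel=0.05)

    def test_zero_gain_flat_psth(self):
        planted = reduced_config("high")
        df = simulate_spikes(planted, seed=1, units_per_site=30, gains={},
                             base_rates={"": 20.0}, window=(0.0, 1.0))
        hist, _ = np.histogram(df["time_s"], bins=10, range=(0.0, 1.0))
        assert hist.std() / hist.mean() < 0.1

    def test_negative_base_rate_rejected(self):
        planted = reduced_config("high")
        with pytest.raises(ValueError):
            simulate_spikes(planted, base_rates={"": -1.0}, gains={})

    def test_determinism_and_schema(self):
        planted = reduced_config("high")
        d1 = simulate_spikes(planted, seed=5, units_per_site=2)
        d2 = simulate_spikes(planted, seed=5, units_per_site=2)
        assert d1.equals(d2)
        assert set(d1.columns) == {"unit", "area", "layer", "time_s", "snr"}
        assert (d1["snr"] >= 0).all()
        assert d1["time_s"].between(planted.times[0], planted.times[-1]).all()


class TestSimulateRFs:
    def test_determinism_and_bounds(self):
        planted = reduced_config("high")
        r1, c1 = simulate_rfs(planted, seed=2)
        r2, c2 = simulate_rfs(planted, seed=2)
        assert r1.equals(r2) and c1.equals(c2)
        assert r1["azimuth"].abs().max() <= 60.0
        assert r1["elevation"].abs().max() <= 47.5
        assert (r1["response"] >= 0).all()

    def test_detector_recovers_planted_centroid(self):
        from laminet.rf_spikes import detect_rf
        planted = reduced_config("high")
        resp, cents = simulate_rfs(planted, seed=3, noise=0.15)
        site = cents.iloc[0]
        m = detect_rf(resp[resp["site"] == site["site"]], n_perm=200, seed=0)
        assert m.significant
        assert abs(m.centroid[0] - site["azimuth"]) <= 10.0
        assert abs(m.centroid[1] - site["elevation"]) <= 10.0

    @pytest.mark.parametrize("mode,expect", [("convergent", "neg"),
                                             ("none", "ns")])
    def test_rf_modes_drive_regression_outcome(self, mode, expect):
        """Convergent geometry yields a significant negative strength-vs-
        distance slope for the planted gamma network; unstructured geometry
        yields no significant relation."""
        import pandas as pd
        from laminet.rf_spikes import regress_rf
        planted = default_config("high")
        _, cents = simulate_rfs(planted, seed=4, modes={"gamma_ff": mode})
        gamma = next(c for c in planted.components if c.name == "gamma_ff")
        area_pos = cents.groupby("area")[["azimuth", "elevation"]].mean()
        rng = np.random.default_rng(0)
        rows = []
        n_boot = 60
        for b in range(n_boot):
            noise = rng.lognormal(0, 0.1, size=len(planted.connections))
            for (src, tgt), w, z in zip(planted.connections,
                                        gamma.connection_weights, noise):
                rows.append((f"{src}->{tgt}", b, w * z))
        strengths = pd.DataFrame(rows, columns=["connection", "bootstrap",
                                                "strength"])
        distances = pd.DataFrame({
            "connection": [f"{s}->{t}" for s, t in planted.connections],
            "distance": [np.linalg.norm(area_pos.loc[s] - area_pos.loc[t])
                         for s, t in planted.connections]})
        out = regress_rf(strengths, distances)
        if expect == "neg":
            assert out["slope"] < 0 and out["slope_p"] < 0.01
        else:
            assert out["slope_p"] > 0.05

    def test_grid_outside_field_rejected(self):
        planted = reduced_config("high")
        with pytest.raises(ValueError):
            simulate_rfs(planted, grid_step=200.0)
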