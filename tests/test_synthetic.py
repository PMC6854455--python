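"""Signal phantoms, smoothed noise generation, and the simulation driver."""

import numpy as np
import pytest
from scipy import stats

from copesets import (NoiseSpec, SignalSpec, SimulationConfig, make_noise,
                      make_signal, run_simulation, smooth_gaussian)
from copesets.bootstrap import BootstrapConfig
from copesets.synthetic import _FWHM_TO_SIGMA, preset


class TestSignals:
    def test_ramp_spans_range_constant_across_rows(self):
        mu = make_signal(SignalSpec(kind="ramp", shape=(100, 100),
                                    ramp_range=(1.0, 3.0))).values
        assert np.allclose(mu[:, 0], 1.0)
        assert np.allclose(mu[:, -1], 3.0)
        assert np.allclose(mu, mu[0])  # constant down each column
        assert np.allclose(np.diff(mu[0]), np.diff(mu[0])[0])  # linear

    def test_unsmoothed_circle_is_indicator(self):
        spec = SignalSpec(kind="circle", shape=(100, 100), radius=30.0,
                          magnitude=3.0, smoothing_fwhm=0.0)
        mu = make_signal(spec).values
        assert set(np.unique(mu)) == {0.0, 3.0}
        yy, xx = np.mgrid[:100, :100]
        inside = np.hypot(yy - 49.5, xx - 49.5) <= 30.0
        assert np.array_equal(mu > 0, inside)

    def test_smoothed_sphere_rescaled_max(self):
        spec = SignalSpec(kind="sphere", shape=(40, 40, 40), radius=5.0,
                          rescale_to_max=3.0)
        mu = make_signal(spec).values
        assert mu.max() == pytest.approx(3.0, abs=1e-12)
        assert mu.min() >= 0.0

    def test_multi_sphere_and_validation(self):
        mu = make_signal(SignalSpec(kind="multi_sphere", shape=(48, 48, 48),
                                    radii=(3.0, 5.0, 7.0, 9.0),
                                    rescale_to_max=3.0)).values
        assert mu.max() == pytest.approx(3.0)
        with pytest.raises(ValueError):
            make_signal(SignalSpec(kind="warp", shape=(10, 10)))
        with pytest.raises(ValueError):
            SignalSpec(kind="circle", shape=(20, 20), radius=30.0)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        f = rng.standard_normal((9, 9))
        assert np.array_equal(smooth_gaussian(f, 0.0), f)

    def test_constant_field_interior_unchanged(self):
        f = np.ones((40, 40))
        s = smooth_gaussian(f, 3.0)
        assert np.allclose(s[10:30, 10:30], 1.0)
        assert s[0, 0] < 1.0  # zero-padded border attenuates

    def test_impulse_gives_discretized_gaussian(self):
        n = 31
        f = np.zeros(n * n).reshape(n, n)
        f[15, 15] = 1.0
        s = smooth_gaussian(f, 3.0)
        sigma = 3.0 / _FWHM_TO_SIGMA
        radius = int(4.0 * sigma + 0.5)  # kernel truncated at 4 sigma
        x = np.arange(n) - 15.0
        k = np.where(np.abs(x) <= radius,
                     np.exp(-0.5 * (x / sigma) ** 2), 0.0)
        k /= k.sum()
        assert np.allclose(s, np.outer(k, k), atol=1e-12)


class TestNoise:
    def test_pointwise_sd_matches_target(self):
        """Renormalization: marginal sd 1 within Monte-Carlo tolerance,
        estimated over 10,000 draws at fixed voxels."""
        noise = make_noise(NoiseSpec(), 10000, (15, 15), seed=4)
        sd = noise.std(axis=0, ddof=1)
        assert np.allclose(sd, 1.0, atol=0.04)  # 3.5 MC sigmas

    def test_sd_ramp_structure(self):
        spec = NoiseSpec(sd_structure="linear_ramp", sd_range=(0.5, 1.5))
        noise = make_noise(spec, 4000, (12, 8), seed=5)
        sd = noise.std(axis=0, ddof=1)
        target = np.linspace(0.5, 1.5, 12)[:, None] * np.ones((1, 8))
        assert np.allclose(sd, target, atol=0.05)
        assert spec.sd_field((12, 8))[0, 0] == pytest.approx(0.5)
        assert spec.sd_field((12, 8))[-1, 0] == pytest.approx(1.5)

    def test_lag1_autocorrelation_matches_gaussian_kernel(self):
        """Smoothed white noise: corr at lag h is exp(-h^2 / (4 sigma^2))."""
        sigma = 3.0 / _FWHM_TO_SIGMA
        noise = make_noise(NoiseSpec(), 6000, (24, 24), seed=6)
        interior = noise[:, 8:16, 8:16]
        shifted = noise[:, 8:16, 9:17]
        rho = np.mean([
            np.corrcoef(interior[:, i, j], shifted[:, i, j])[0, 1]
            for i in range(8) for j in range(8)
        ])
        assert rho == pytest.approx(np.exp(-1.0 / (4 * sigma**2)), abs=0.02)

    def test_unsmoothed_noise_is_iid_standard_normal(self):
        noise = make_noise(NoiseSpec(smoothing_fwhm=0.0), 40, (20, 20), seed=7)
        stat, p = stats.kstest(noise.ravel(), "norm")
        assert p > 0.01
        # neighbours uncorrelated
        r = np.corrcoef(noise[:, :, :-1].ravel(), noise[:, :, 1:].ravel())[0, 1]
        assert abs(r) < 0.02

    def test_independent_across_subjects(self):
        noise = make_noise(NoiseSpec(), 2000, (6, 6), seed=8)
        r = np.corrcoef(noise[:-1].ravel(), noise[1:].ravel())[0, 1]
        assert abs(r) < 0.03


@pytest.fixture(scope="module")
def tiny_config():
    return SimulationConfig(
        signal=SignalSpec(kind="circle", shape=(24, 24), radius=7.0),
        noise=NoiseSpec(),
        n_subjects=20,
        trials=8,
        c=2.0,
        alphas=(0.10,),
        bootstrap=BootstrapConfig(B=100),
        boundary_choice="both",
        seed=99,
    )


def test_single_trial_coverage_is_binary(tiny_config):
    import dataclasses
    cfg = dataclasses.replace(tiny_config, trials=1,
                              boundary_choice="estimated")
    tab = run_simulation(cfg).frame
    assert set(tab["empirical_coverage"]) <= {0.0, 1.0}


def test_table_structure_and_determinism(tiny_config):
    t1 = run_simulation(tiny_config).frame
    t2 = run_simulation(tiny_config).frame
    assert t1.equals(t2)
    assert set(t1["assessment"]) == {"lattice", "interpolated", "conjunction"}
    assert set(t1["boundary_choice"]) == {"estimated", "true"}
    assert (t1["trials"] == 8).all()
    p = t1["empirical_coverage"]
    hw = t1["mc_halfwidth"]
    assert np.allclose(hw, 1.96 * np.sqrt(p * (1 - p) / 8))


def test_conjunction_bounded_by_lattice(tiny_config):
    tab = run_simulation(tiny_config).frame
    for (choice, alpha), grp in tab.groupby(["boundary_choice", "alpha"]):
        by = grp.set_index("assessment")["empirical_coverage"]
        assert by["conjunction"] <= by["lattice"]
        assert by["conjunction"] <= by["interpolated"]


def test_preset_overrides():
    cfg = preset("circle_2d", trials=5, multiplier="gaussian",
                 variant="plain", n_subjects=30)
    assert cfg.trials == 5
    assert cfg.n_subjects == 30
    assert cfg.bootstrap.multiplier == "gaussian"
    assert cfg.bootstrap.variant == "plain"
    full = preset("large_sphere_3d", scale="full")
    assert full.signal.shape == (100, 100, 100)
    assert full.trials == 3000 and full.bootstrap.B == 5000
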