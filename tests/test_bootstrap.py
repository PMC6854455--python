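"""Multiplier bootstrap of the boundary supremum and the critical value."""

import itertools

import numpy as np
import pytest

from copesets import (BootstrapConfig, SupDistribution,
                      bootstrap_sup_distribution, critical_value)
from copesets.bootstrap import _draw_multipliers


class _ForcedRng:
    """Stands in for a Generator, returning fixed multipliers."""

    def __init__(self, R):
        self.R = np.asarray(R, dtype=float)

    def standard_normal(self, size):
        assert size == self.R.shape
        return self.R

    def integers(self, lo, hi, size):
        assert size == self.R.shape
        return (self.R + 1) / 2  # maps +-1 back to {1, 0}


def _sups_with_multipliers(eps, R, variant="plain"):
    cfg = BootstrapConfig(B=len(R), multiplier="gaussian", variant=variant,
                          seed=_ForcedRng(np.asarray(R, float)))
    return bootstrap_sup_distribution(np.asarray(eps, float), cfg).sups


def brute_force_sup(eps, r, variant="plain"):
    """Direct per-replicate oracle following the definitions literally."""
    eps = np.asarray(eps, float)
    n = eps.shape[0]
    g = np.array([np.sum(r * eps[:, e]) / np.sqrt(n)
                  for e in range(eps.shape[1])])
    if variant == "t":
        sd = np.array([np.std(r * eps[:, e], ddof=1)
                       for e in range(eps.shape[1])])
        g = np.where(sd == 0, 0.0, g / np.where(sd == 0, 1.0, sd))
    return np.max(np.abs(g))


def test_all_ones_multipliers_annihilate_one_sample_residuals(rng):
    """Residuals orthogonal to the intercept sum to zero, so r = 1 gives
    a identically-zero bootstrap field."""
    raw = rng.standard_normal((10, 4))
    eps = raw - raw.mean(axis=0)  # one-sample standardized residual structure
    sups = _sups_with_multipliers(eps, np.ones((3, 10)))
    assert np.allclose(sups, 0.0)


def test_two_subject_enumeration():
    """N=2, eps = (+1, -1): the four sign patterns give sup 0 or sqrt(2)."""
    eps = np.array([[1.0], [-1.0]])
    seen = {}
    for r in itertools.product([-1.0, 1.0], repeat=2):
        sup = _sups_with_multipliers(eps, np.array([r]))[0]
        seen[r] = sup
        assert sup == pytest.approx(brute_force_sup(eps, np.array(r)))
    vals = sorted(set(round(v, 12) for v in seen.values()))
    assert vals == [0.0, round(np.sqrt(2), 12)]
    assert sum(v == 0 for v in seen.values()) == 2


def test_global_sign_flip_leaves_sup_unchanged(rng):
    eps = rng.standard_normal((6, 3))
    R = rng.standard_normal((5, 6))
    for variant in ("plain", "t"):
        a = _sups_with_multipliers(eps, R, variant)
        b = _sups_with_multipliers(eps, -R, variant)
        assert np.allclose(a, b)


@pytest.mark.parametrize("variant", ["plain", "t"])
def test_exhaustive_rademacher_enumeration_vs_oracle(rng, variant):
    """All 2^N sign vectors at N=8, E=3: vectorized implementation equals
    the per-replicate brute-force oracle, and the sup set is invariant
    under flipping the sign of any residual row (plain variant)."""
    n, n_edges = 8, 3
    eps = rng.standard_normal((n, n_edges))
    R = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    sups = _sups_with_multipliers(eps, R, variant)
    oracle = np.array([brute_force_sup(eps, r, variant) for r in R])
    assert np.allclose(sups, oracle)

    if variant == "plain":
        eps_flip = eps.copy()
        eps_flip[2] *= -1
        sups_flip = _sups_with_multipliers(eps_flip, R, variant)
        assert np.allclose(np.sort(sups), np.sort(sups_flip))


def test_gaussian_moments_at_large_B(rng):
    """E[G*] = 0 and Var[G*] = mean(eps_i^2) per boundary point."""
    n = 12
    eps = rng.standard_normal((n, 2)) * np.array([1.0, 2.5])
    cfg = BootstrapConfig(B=40000, multiplier="gaussian", variant="plain",
                          seed=99)
    R = _draw_multipliers(cfg.rng(), "gaussian", cfg.B, n)
    G = (R @ eps) / np.sqrt(n)
    assert np.allclose(G.mean(axis=0), 0.0, atol=0.05)
    assert np.allclose(G.var(axis=0), (eps**2).mean(axis=0), rtol=0.05)


def test_degenerate_sigma_star_contributes_zero():
    """All-zero residual column: the t variant warns and scores it 0."""
    eps = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 0.5]])
    with pytest.warns(RuntimeWarning, match="sigma"):
        sups = _sups_with_multipliers(eps, np.ones((2, 3)) * [[1], [-1]],
                                      variant="t")
    assert np.all(np.isfinite(sups))


def test_critical_value_order_statistic():
    assert critical_value(np.full(17, 3.25), 0.05) == 3.25
    assert critical_value(np.full(17, 3.25), 0.5) == 3.25
    sups = np.arange(1.0, 101.0)
    np.random.default_rng(0).shuffle(sups)
    assert critical_value(sups, 0.05) == 95.0  # ceil(0.95 * 100) = 95
    with pytest.raises(ValueError):
        critical_value(sups, 0.0)
    with pytest.raises(ValueError):
        critical_value(sups, 1.0)


def test_critical_value_monotone_in_alpha(rng):
    sups = SupDistribution(np.abs(rng.standard_normal(400)))
    ks = [critical_value(sups, a) for a in np.linspace(0.01, 0.9, 15)]
    assert all(k1 >= k2 for k1, k2 in zip(ks, ks[1:]))


def test_reproducible_for_fixed_seed(rng):
    eps = rng.standard_normal((7, 4))
    cfg = BootstrapConfig(B=50, seed=42)
    a = bootstrap_sup_distribution(eps, cfg).sups
    b = bootstrap_sup_distribution(eps, BootstrapConfig(B=50, seed=42)).sups
    assert np.array_equal(a, b)
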