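"""Multiplier (wild) bootstrap for the boundary supremum distribution.

The critical value k of the confidence sets is the (1 - alpha) quantile of
``sup_{s in dA_c} |G(s)|`` where G is the limiting error field.  With
standardized residuals interpolated to E boundary points, each bootstrap
replicate draws i.i.d. multipliers r_1..r_N (Gaussian, or Rademacher +-1)
and forms

    G*(s)      = N^{-1/2} sum_i r_i eps~_i(s)                (plain)
    G~*(s)     = N^{-1/2} sum_i r_i eps~_i(s) / sigma*(s)    (t variant)

where sigma*(s) is the sample sd (divisor N - 1) of the multiplied
residuals {r_i eps~_i(s)} at that boundary point.  The replicate's
contribution is the supremum over boundary points of the absolute field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings of one bootstrap run.

    multiplier : {"gaussian", "rademacher"}
    variant    : {"plain", "t"} — "t" studentizes each replicate.
    seed       : int, SeedSequence or Generator.
    """

    B: int = 5000
    multiplier: str = "rademacher"
    variant: str = "t"
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.multiplier not in ("gaussian", "rademacher"):
            raise ValueError(f"unknown multiplier {self.multiplier!r}")
        if self.variant not in ("plain", "t"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def rng(self) -> np.random.Generator:
        # accept any Generator-like source of multiplier draws
        if hasattr(self.seed, "standard_normal"):
            return self.seed  # type: ignore[return-value]
        return np.random.default_rng(self.seed)

    def with_seed(self, seed) -> "BootstrapConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SupDistribution:
    """B bootstrap suprema of the absolute boundary field."""

    sups: np.ndarray

    def __post_init__(self) -> None:
        sups = np.asarray(self.sups, dtype=float)
        if sups.size == 0:
            raise ValueError("empty supremum sample")
        if not np.all(np.isfinite(sups)) or np.any(sups < 0):
            raise ValueError("suprema must be finite and nonnegative")
        object.__setattr__(self, "sups", sups)


def _draw_multipliers(
    rng: np.random.Generator, multiplier: str, B: int, n: int
) -> np.ndarray:
    if multiplier == "gaussian":
        return rng.standard_normal((B, n))
    return rng.integers(0, 2, size=(B, n)) * 2.0 - 1.0


def bootstrap_sup_distribution(
    boundary_residuals: np.ndarray, config: BootstrapConfig
) -> SupDistribution:
    """Bootstrap the supremum of |G| over the boundary points.

    Parameters
    ----------
    boundary_residuals : ndarray, shape (N, E)
        Standardized residuals interpolated to the E boundary points.
    """
    eps = np.asarray(boundary_residuals, dtype=float)
    if eps.ndim != 2:
        raise ValueError("boundary_residuals must be (N, E)")
    n, n_edges = eps.shape
    if n < 2 or n_edges < 1:
        raise ValueError("need N >= 2 subjects and E >= 1 boundary points")

    rng = config.rng()
    R = _draw_multipliers(rng, config.multiplier, config.B, n)  # (B, N)
    S1 = R @ eps                                                # (B, E)
    G = S1 / np.sqrt(n)
    if config.variant == "t":
        # sample variance of {r_i eps_i(s)} over i, without a (B, N, E)
        # temporary: sum of squares minus mean correction
        S2 = (R**2) @ (eps**2)
        var = (S2 - S1**2 / n) / (n - 1)
        var = np.maximum(var, 0.0)
        zero = var == 0
        if zero.any():
            warnings.warn(
                "sigma* = 0 at some boundary points in some replicates; "
                "those points contribute 0 to the supremum",
                RuntimeWarning,
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            G = np.where(zero, 0.0, G / np.sqrt(var))
    sups = np.max(np.abs(G), axis=1)
    return SupDistribution(sups)


def critical_value(sups: SupDistribution | np.ndarray, alpha: float) -> float:
    """The conservative empirical (1 - alpha) quantile of the suprema.

    k is the ceil((1 - alpha) B)-th smallest supremum — a pure order
    statistic, reproducible bit-exactly, no interpolation.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    arr = sups.sups if isinstance(sups, SupDistribution) else np.asarray(sups, float)
    b = arr.size
    rank = int(np.ceil((1 - alpha) * b))
    rank = min(max(rank, 1), b)
    return float(np.sort(arr)[rank - 1])
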