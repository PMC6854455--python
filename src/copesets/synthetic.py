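"""Synthetic signal-plus-noise fields and Monte-Carlo coverage experiments.

The generator reproduces the phantoms used to validate the method:

* 2D, 100x100 — a linear ramp rising from 1 to 3 along x, and a circular
  phantom of magnitude 3 and radius 30 smoothed with a 3-voxel-FWHM
  Gaussian kernel;
* 3D, 100^3 — spherical phantoms of magnitude 3 with radius 5 or 30, and
  a four-sphere configuration, each smoothed (3-voxel FWHM) and rescaled
  to a maximum intensity of 3;
* subject noise — Gaussian white noise smoothed with a 3-voxel-FWHM
  kernel and renormalized to unit pointwise sd, then scaled by either a
  constant sd of 1 or a linear sd ramp 0.5 -> 1.5 along the first axis.

``run_simulation`` drives repeated trials of the one-sample
signal-plus-noise model Y_i = mu + eps_i, computes confidence sets per
trial, and tabulates empirical coverage with binomial Monte-Carlo error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .boundary import EmptyBoundaryError, find_boundary_edges, interpolate_to_boundary
from .bootstrap import BootstrapConfig, bootstrap_sup_distribution, critical_value
from .confidence_sets import construct_cs
from .coverage import assess_interpolated, assess_lattice
from .glm import DesignSpec, fit_glm
from .lattice import FieldLattice

logger = logging.getLogger(__name__)

#: FWHM -> Gaussian sigma conversion factor, 2 sqrt(2 ln 2)
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# smoothing


def smooth_gaussian(field_values: np.ndarray | FieldLattice,
                    fwhm_voxels: float) -> np.ndarray:
    """Separable Gaussian convolution, sigma = fwhm / (2 sqrt(2 ln 2)).

    Zero-padded (constant) boundary handling with the kernel truncated at
    4 sigma; fwhm = 0 is the identity.
    """
    arr = field_values.values if isinstance(field_values, FieldLattice) \
        else np.asarray(field_values, dtype=float)
    if fwhm_voxels < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_voxels == 0:
        return arr.copy()
    sigma = fwhm_voxels / _FWHM_TO_SIGMA
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="constant",
                                   truncate=4.0)


def _gaussian_kernel_1d(fwhm_voxels: float) -> np.ndarray:
    """The discrete 1D kernel gaussian_filter applies (truncate=4)."""
    sigma = fwhm_voxels / _FWHM_TO_SIGMA
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smoothed_noise_sd(shape: tuple[int, ...], fwhm_voxels: float) -> np.ndarray:
    """Exact pointwise sd of zero-padded smoothed unit white noise.

    Var(s) = prod_axes conv1d(ones, kernel^2)(s_axis) by separability.
    """
    if fwhm_voxels == 0:
        return np.ones(shape)
    k2 = _gaussian_kernel_1d(fwhm_voxels) ** 2
    var = np.ones(shape)
    for axis, n in enumerate(shape):
        v = ndimage.correlate1d(np.ones(n), k2, mode="constant")
        sl = [None] * len(shape)
        sl[axis] = slice(None)
        var = var * v[tuple(sl)]
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# signals


@dataclass(frozen=True)
class SignalSpec:
    """The noise-free mean field mu.

    kind : {"ramp", "circle", "sphere", "multi_sphere", "custom"}
    shape : lattice dimensions
    magnitude : phantom height before smoothing
    radius / radii : in voxels (circle/sphere; multi_sphere)
    ramp_range : (low, high) for the linear ramp along the last axis
    smoothing_fwhm : voxels; 0 disables smoothing
    rescale_to_max : if set, the final image is rescaled to this maximum
    custom_values : mean image for kind="custom"
    """

    kind: str = "circle"
    shape: tuple[int, ...] = (100, 100)
    magnitude: float = 3.0
    radius: float = 30.0
    radii: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0)
    ramp_range: tuple[float, float] = (1.0, 3.0)
    smoothing_fwhm: float = 3.0
    rescale_to_max: float | None = None
    custom_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.smoothing_fwhm < 0:
            raise ValueError("fwhm must be >= 0")
        if self.kind in ("circle", "sphere"):
            if any(self.radius > n / 2 for n in self.shape):
                raise ValueError("radius does not fit inside the lattice")


def _ball_indicator(shape: tuple[int, ...], center: Sequence[float],
                    radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (d2 <= radius**2).astype(float)


def make_signal(spec: SignalSpec) -> FieldLattice:
    """Build the noise-free mean field from its specification."""
    shape = tuple(spec.shape)
    if spec.kind == "ramp":
        lo, hi = spec.ramp_range
        ramp = np.linspace(lo, hi, shape[-1])
        mu = np.broadcast_to(ramp, shape).copy()
    elif spec.kind in ("circle", "sphere"):
        center = [(n - 1) / 2 for n in shape]
        mu = spec.magnitude * _ball_indicator(shape, center, spec.radius)
        mu = smooth_gaussian(mu, spec.smoothing_fwhm)
    elif spec.kind == "multi_sphere":
        mu = np.zeros(shape)
        centers = _multi_sphere_centers(shape, spec.radii)
        for ctr, rad in zip(centers, spec.radii):
            mu = np.maximum(mu, spec.magnitude * _ball_indicator(shape, ctr, rad))
        mu = smooth_gaussian(mu, spec.smoothing_fwhm)
    elif spec.kind == "custom":
        if spec.custom_values is None:
            raise ValueError("custom signal requires custom_values")
        mu = smooth_gaussian(np.asarray(spec.custom_values, float),
                             spec.smoothing_fwhm) if spec.smoothing_fwhm else \
            np.asarray(spec.custom_values, float).copy()
        if mu.shape != shape:
            raise ValueError("custom_values shape does not match spec.shape")
    else:
        raise ValueError(f"unknown signal kind {spec.kind!r}")
    if spec.rescale_to_max is not None:
        mu = mu * (spec.rescale_to_max / mu.max())
    return FieldLattice(mu)


def _multi_sphere_centers(shape, radii):
    """Place the phantoms at the cell centres of a 2x2(x1) grid."""
    quarters = [n // 4 for n in shape]
    three_quarters = [3 * n // 4 for n in shape]
    corners = [
        (quarters[0], quarters[1]),
        (quarters[0], three_quarters[1]),
        (three_quarters[0], quarters[1]),
        (three_quarters[0], three_quarters[1]),
    ]
    if len(shape) == 3:
        mid = shape[2] // 2
        corners = [c + (mid,) for c in corners]
    return corners[: len(radii)]


# ---------------------------------------------------------------------------
# noise


@dataclass(frozen=True)
class NoiseSpec:
    """Subject-specific Gaussian noise field specification.

    sd_structure : {"constant", "linear_ramp", "custom"}
    sd_value : constant sd (default 1)
    sd_range : (low, high) linear sd ramp along ``ramp_axis``
    smoothing_fwhm : voxels of Gaussian smoothing applied to white noise
    custom_sd_values : sd image for sd_structure="custom"
    """

    sd_structure: str = "constant"
    sd_value: float = 1.0
    sd_range: tuple[float, float] = (0.5, 1.5)
    ramp_axis: int = 0
    smoothing_fwhm: float = 3.0
    custom_sd_values: np.ndarray | None = None

    def sd_field(self, shape: tuple[int, ...]) -> np.ndarray:
        if self.sd_structure == "constant":
            if self.sd_value <= 0:
                raise ValueError("sd must be > 0")
            return np.full(shape, float(self.sd_value))
        if self.sd_structure == "linear_ramp":
            lo, hi = self.sd_range
            if lo <= 0 or hi <= 0:
                raise ValueError("sd must be > 0")
            ramp = np.linspace(lo, hi, shape[self.ramp_axis])
            sl = [None] * len(shape)
            sl[self.ramp_axis] = slice(None)
            return np.broadcast_to(ramp[tuple(sl)], shape).copy()
        if self.sd_structure == "custom":
            sd = np.asarray(self.custom_sd_values, dtype=float)
            if sd.shape != shape:
                raise ValueError("custom sd image shape mismatch")
            if np.any(sd <= 0):
                raise ValueError("sd must be > 0 everywhere")
            return sd
        raise ValueError(f"unknown sd structure {self.sd_structure!r}")


def make_noise(
    spec: NoiseSpec,
    n_subjects: int,
    shape: tuple[int, ...],
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw N independent smoothed Gaussian noise fields, shape (N, ...).

    White noise is smoothed with the spec's FWHM, renormalized so the
    pointwise marginal sd is exactly 1 (the smoothing-induced variance
    shrinkage, including border attenuation, is divided out), then scaled
    by the target sd field.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    white = rng.standard_normal((n_subjects, *shape))
    if spec.smoothing_fwhm > 0:
        sigma = spec.smoothing_fwhm / _FWHM_TO_SIGMA
        smoothed = ndimage.gaussian_filter(
            white, sigma=(0.0, *([sigma] * len(shape))), mode="constant",
            truncate=4.0,
        )
        smoothed /= _smoothed_noise_sd(shape, spec.smoothing_fwhm)
    else:
        smoothed = white
    return smoothed * spec.sd_field(shape)


# ---------------------------------------------------------------------------
# Monte-Carlo coverage experiments


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the coverage validation study.

    ``boundary_choice`` selects which boundary calibrates the bootstrap:
    the plug-in estimated boundary (as with real data), the true boundary
    of the known mean (simulation-only diagnostic), or "both" to evaluate
    the two on shared trial data.
    """

    signal: SignalSpec
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_subjects: int = 60
    trials: int = 3000
    c: float = 2.0
    alphas: tuple[float, ...] = (0.20, 0.10, 0.05)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    boundary_choice: str = "estimated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.n_subjects < 2:
            raise ValueError("need N >= 2")
        if self.boundary_choice not in ("estimated", "true", "both"):
            raise ValueError(f"bad boundary_choice {self.boundary_choice!r}")


@dataclass(frozen=True)
class CoverageTable:
    """Empirical coverage per (N, alpha, bootstrap settings, assessment).

    ``frame`` columns: n_subjects, alpha, multiplier, variant,
    boundary_choice, assessment, empirical_coverage, mc_halfwidth,
    trials, excluded_trials.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cov = self.frame["empirical_coverage"]
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("coverage outside [0, 1]")

    def coverage(self, **key) -> float:
        """Look up one cell, e.g. coverage(alpha=0.05, assessment="conjunction")."""
        df = self.frame
        for col, val in key.items():
            df = df[df[col] == val]
        if len(df) != 1:
            raise KeyError(f"key {key} selects {len(df)} rows")
        return float(df["empirical_coverage"].iloc[0])


def mc_halfwidth(p: float, trials: int) -> float:
    """Binomial 95% Monte-Carlo half-width 1.96 sqrt(p(1-p)/trials)."""
    return 1.96 * np.sqrt(p * (1.0 - p) / trials)


_ASSESSMENTS = ("lattice", "interpolated", "conjunction")


def run_simulation(config: SimulationConfig) -> CoverageTable:
    """Monte-Carlo empirical coverage of the confidence-set procedure.

    Per trial: draw Y_i = mu + eps_i, fit the one-sample GLM, bootstrap
    the critical value on the chosen boundary, build the sets at each
    alpha, and assess coverage with the lattice check, the interpolated
    check, and their conjunction.  Trials whose estimated excursion set
    has no boundary are excluded with a logged count.  Fully reproducible
    from ``config.seed``.
    """
    mu = make_signal(config.signal)
    shape = mu.shape
    design = DesignSpec.one_sample(config.n_subjects)
    truth = mu.values >= config.c
    true_edges = find_boundary_edges(mu, config.c, source="true")
    choices = ("estimated", "true") if config.boundary_choice == "both" \
        else (config.boundary_choice,)

    ss = np.random.SeedSequence(config.seed)
    trial_seeds = ss.spawn(config.trials)
    hits = {(ch, a, m): 0 for ch in choices for a in config.alphas
            for m in _ASSESSMENTS}
    excluded = 0
    for t in range(config.trials):
        noise_ss, boot_ss = trial_seeds[t].spawn(2)
        noise = make_noise(config.noise, config.n_subjects, shape,
                           seed=np.random.default_rng(noise_ss))
        fit = fit_glm(mu.values[None] + noise, design)
        try:
            per_choice_sups = {}
            for choice in choices:
                edges = true_edges if choice == "true" else \
                    find_boundary_edges(fit.contrast, config.c)
                resid_b = interpolate_to_boundary(fit.std_residuals, edges)
                per_choice_sups[choice] = bootstrap_sup_distribution(
                    resid_b,
                    config.bootstrap.with_seed(np.random.default_rng(boot_ss)),
                )
        except EmptyBoundaryError:
            excluded += 1
            logger.warning("trial %d excluded: empty estimated boundary", t)
            continue
        for choice in choices:
            sups = per_choice_sups[choice]
            for alpha in config.alphas:
                k = critical_value(sups, alpha)
                cs = construct_cs(fit, config.c, k, alpha=alpha)
                lat = assess_lattice(truth, cs)
                interp = assess_interpolated(mu, fit, cs)
                hits[(choice, alpha, "lattice")] += lat
                hits[(choice, alpha, "interpolated")] += interp
                hits[(choice, alpha, "conjunction")] += lat and interp

    used = config.trials - excluded
    if excluded:
        logger.warning("%d of %d trials excluded (empty boundary)",
                       excluded, config.trials)
    if used == 0:
        raise RuntimeError("all trials excluded: empty estimated boundaries")
    rows = []
    for (choice, alpha, method), h in hits.items():
        p = h / used
        rows.append({
            "n_subjects": config.n_subjects,
            "alpha": alpha,
            "multiplier": config.bootstrap.multiplier,
            "variant": config.bootstrap.variant,
            "boundary_choice": choice,
            "assessment": method,
            "empirical_coverage": p,
            "mc_halfwidth": mc_halfwidth(p, used),
            "trials": used,
            "excluded_trials": excluded,
        })
    return CoverageTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# named presets

#: full-scale study conditions (100x100 / 100^3 grids, 3000 trials, B=5000)
FULL_SCALE_PRESETS: dict[str, SimulationConfig] = {
    "circle_2d": SimulationConfig(
        signal=SignalSpec(kind="circle", shape=(100, 100), radius=30.0),
        trials=3000, bootstrap=BootstrapConfig(B=5000),
    ),
    "ramp_2d": SimulationConfig(
        signal=SignalSpec(kind="ramp", shape=(100, 100), smoothing_fwhm=0.0),
        trials=3000, bootstrap=BootstrapConfig(B=5000),
    ),
    "small_sphere_3d": SimulationConfig(
        signal=SignalSpec(kind="sphere", shape=(100, 100, 100), radius=5.0,
                          rescale_to_max=3.0),
        trials=3000, bootstrap=BootstrapConfig(B=5000),
    ),
    "large_sphere_3d": SimulationConfig(
        signal=SignalSpec(kind="sphere", shape=(100, 100, 100), radius=30.0,
                          rescale_to_max=3.0),
        trials=3000, bootstrap=BootstrapConfig(B=5000),
    ),
    "multi_sphere_3d": SimulationConfig(
        signal=SignalSpec(kind="multi_sphere", shape=(100, 100, 100),
                          rescale_to_max=3.0),
        trials=3000, bootstrap=BootstrapConfig(B=5000),
    ),
}

#: desk-scale presets: smaller grids / radii, fewer trials, smaller B
REDUCED_SCALE_PRESETS: dict[str, SimulationConfig] = {
    "circle_2d": SimulationConfig(
        signal=SignalSpec(kind="circle", shape=(50, 50), radius=15.0),
        trials=500, bootstrap=BootstrapConfig(B=1000),
    ),
    "small_sphere_3d": SimulationConfig(
        signal=SignalSpec(kind="sphere", shape=(40, 40, 40), radius=5.0,
                          rescale_to_max=3.0),
        trials=300, bootstrap=BootstrapConfig(B=500),
    ),
    "large_sphere_3d": SimulationConfig(
        signal=SignalSpec(kind="sphere", shape=(40, 40, 40), radius=12.0,
                          rescale_to_max=3.0),
        trials=300, bootstrap=BootstrapConfig(B=500),
    ),
}


def preset(name: str, scale: str = "reduced", **overrides) -> SimulationConfig:
    """Fetch a named configuration, optionally overriding fields.

    Bootstrap-level overrides (multiplier, variant, B) are passed through
    to the nested BootstrapConfig.
    """
    table = REDUCED_SCALE_PRESETS if scale == "reduced" else FULL_SCALE_PRESETS
    cfg = table[name]
    boot_over = {k: overrides.pop(k) for k in ("multiplier", "variant", "B")
                 if k in overrides}
    if boot_over:
        cfg = replace(cfg, bootstrap=replace(cfg.bootstrap, **boot_over))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
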