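"""Assembly of upper/lower confidence sets from a fitted GLM.

Given the critical value k, the three sets are plain voxelwise thresholds
of the fitted contrast:

    point estimate  A^_c   = {s : contrast(s) >= c}
    upper CS        A^_c+  = {s : contrast(s) >= c + k sigma^(s) v_w}
    lower CS        A^_c-  = {s : contrast(s) >= c - k sigma^(s) v_w}

all restricted to the mask.  With simultaneous (1 - alpha) confidence the
true excursion set A_c is bracketed: A^_c+ inside A_c inside A^_c-.  The
set difference lower \\ upper is a confidence region for the boundary of
A_c itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapConfig
from .glm import DesignSpec, GLMFit
from .lattice import FieldLattice


@dataclass(frozen=True)
class ConfidenceSets:
    """The nested set triple and the settings that produced it."""

    point_estimate: FieldLattice
    upper: FieldLattice
    lower: FieldLattice
    k: float
    c: float
    alpha: float | None = None
    settings: dict | None = None

    @property
    def mask(self) -> np.ndarray:
        return self.point_estimate.mask

    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(upper, point-estimate, lower) boolean arrays."""
        return (
            self.upper.values.astype(bool),
            self.point_estimate.values.astype(bool),
            self.lower.values.astype(bool),
        )

    def label_map(self) -> np.ndarray:
        """Nesting-encoded labels: 0 none, 1 lower only, 2 point est., 3 upper."""
        up, pe, lo = self.masks()
        return (lo.astype(np.uint8) + pe.astype(np.uint8) + up.astype(np.uint8))


def construct_cs(fit: GLMFit, c: float, k: float, alpha: float | None = None,
                 settings: dict | None = None) -> ConfidenceSets:
    """Threshold the fitted contrast into the nested set triple."""
    if k < 0:
        raise ValueError(f"critical value k must be >= 0, got {k}")
    mask = fit.mask
    con = fit.contrast.values
    margin = k * fit.sigma_hat.values * fit.vw
    point = (con >= c) & mask
    upper = (con >= c + margin) & mask
    lower = (con >= c - margin) & mask
    return ConfidenceSets(
        point_estimate=FieldLattice(point.astype(float), mask),
        upper=FieldLattice(upper.astype(float), mask),
        lower=FieldLattice(lower.astype(float), mask),
        k=float(k),
        c=float(c),
        alpha=alpha,
        settings=settings,
    )


def compute_confidence_sets(
    data,
    design: DesignSpec,
    c: float,
    alpha: float,
    config: BootstrapConfig | None = None,
    mask: np.ndarray | None = None,
) -> ConfidenceSets:
    """End-to-end confidence sets from a subject stack (plug-in boundary).

    Thin wrapper over :class:`copesets.estimator.ConfidenceSetEstimator`.
    """
    from .estimator import ConfidenceSetEstimator

    config = config or BootstrapConfig()
    est = ConfidenceSetEstimator(
        threshold=c,
        alpha=alpha,
        n_bootstrap=config.B,
        multiplier=config.multiplier,
        variant=config.variant,
        random_state=config.seed,
    )
    est.fit(data, design=design, mask=mask)
    return est.confidence_sets_
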