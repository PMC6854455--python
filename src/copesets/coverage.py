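"""Coverage assessment for simulated trials with known truth.

A trial is covered when the subset condition

    upper CS  ⊂  A_c  ⊂  lower CS

holds.  Two checks are combined:

* the *lattice* check compares the three voxel masks directly — simple,
  but blind to sub-voxel upcrossings of the continuous boundary, so it is
  positively biased on coarse grids;
* the *interpolated* check samples the true continuous boundary dA_c at
  the sub-voxel crossing points of the known mean, interpolates the
  fitted thresholds there with the same linear weights, and flags a
  violation whenever the interpolated upper threshold is met on the
  boundary (the upper set has leaked out of A_c) or the interpolated
  lower threshold fails there (A_c has leaked out of the lower set).

A trial counts as covered only if both checks pass.
"""

from __future__ import annotations

import numpy as np

from .boundary import find_boundary_edges, interpolate_to_boundary
from .confidence_sets import ConfidenceSets
from .glm import GLMFit
from .lattice import FieldLattice, as_lattice


def assess_lattice(true_set: np.ndarray | FieldLattice, cs: ConfidenceSets) -> bool:
    """Direct voxel-mask comparison: upper ⊆ truth ⊆ lower on the mask."""
    truth = true_set.values.astype(bool) if isinstance(true_set, FieldLattice) \
        else np.asarray(true_set).astype(bool)
    mask = cs.mask
    if truth.shape != mask.shape:
        raise ValueError("true set shape does not match the lattice")
    up, _, lo = cs.masks()
    m = mask
    return bool(np.all(truth[m] | ~up[m]) and np.all(lo[m] | ~truth[m]))


def assess_interpolated(
    mu: FieldLattice | np.ndarray, fit: GLMFit, cs: ConfidenceSets
) -> bool:
    """Sub-voxel check of the subset condition on the true boundary.

    Builds the boundary edges of the noise-free mean ``mu`` at the
    threshold of ``cs``, interpolates the fitted upper / lower threshold
    statements to each crossing point s*, and reports coverage iff no
    point violates either statement.
    """
    mu = as_lattice(mu, None if isinstance(mu, FieldLattice) else fit.mask)
    edges = find_boundary_edges(mu, cs.c, source="true")
    k, vw = cs.k, fit.vw
    con = interpolate_to_boundary(fit.contrast.values, edges)
    margin = k * vw * interpolate_to_boundary(fit.sigma_hat.values, edges)
    # s* in the fitted upper set => the upper set touches/crosses dA_c
    upper_violation = np.any(con - margin >= cs.c)
    # s* outside the fitted lower set => A_c not contained in it
    lower_violation = np.any(con + margin < cs.c)
    return not (upper_violation or lower_violation)


def assess_trial(
    mu: FieldLattice | np.ndarray, fit: GLMFit, cs: ConfidenceSets
) -> bool:
    """Covered iff both the lattice and the interpolated checks pass."""
    mu_lat = as_lattice(mu, None if isinstance(mu, FieldLattice) else fit.mask)
    truth = (mu_lat.values >= cs.c) & mu_lat.mask
    return assess_lattice(truth, cs) and assess_interpolated(mu_lat, fit, cs)
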