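"""Mass-univariate general linear model for subject-level contrast stacks.

At every voxel s the model is ``Y(s) = X beta(s) + eps(s)`` with a common
design matrix ``X`` (N subjects x p regressors) across voxels and
independent mean-zero errors of voxelwise variance ``sigma^2(s)``.  The
quantity of interest is the contrast ``w' beta(s)`` in raw-effect units
(e.g. %BOLD change).  The fit produces everything downstream stages need:
the contrast map, the pointwise residual standard deviation, the
standardized residual stack used by the multiplier bootstrap, and the
normalized contrast standard deviation ``v_w = sqrt(w'(X'X)^{-1}w)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import FieldLattice


class DesignError(ValueError):
    """Invalid design matrix / contrast vector."""


class DegenerateVarianceError(ValueError):
    """Residual variance is exactly zero at a masked voxel."""


@dataclass(frozen=True)
class DesignSpec:
    """Design matrix and contrast vector of the group-level GLM.

    ``X`` has one row per subject image; ``w`` is a p-vector in the raw
    units of the effect (for a one-sample %BOLD model, X a column of ones
    and w = (1) make ``w' beta_hat`` a mean %BOLD change).
    """

    X: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        n, p = X.shape
        if w.shape != (p,):
            raise DesignError(f"contrast length {w.shape} != p={p}")
        if n <= p:
            raise DesignError(f"need N > p, got N={n}, p={p}")
        if np.linalg.matrix_rank(X) < p:
            raise DesignError("design matrix is rank deficient")
        if not np.any(w):
            raise DesignError("contrast vector is all zero")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "w", w)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def one_sample(cls, n: int) -> "DesignSpec":
        """One-sample design: X a column of ones, w = (1)."""
        return cls(np.ones((n, 1)), np.ones(1))


@dataclass(frozen=True)
class GLMFit:
    """Fitted GLM summaries on the lattice.

    Attributes
    ----------
    contrast : FieldLattice
        ``w' beta_hat`` per voxel, raw-effect units.
    sigma_hat : FieldLattice
        Pointwise residual sd, divisor N - p.
    std_residuals : ndarray, shape (N, ...)
        Standardized residuals ``(Y_i - X beta_hat)_i / sigma_hat``.
    vw : float
        Normalized contrast sd ``sqrt(w'(X'X)^{-1}w)``.
    dof : int
        Residual degrees of freedom N - p.
    """

    contrast: FieldLattice
    sigma_hat: FieldLattice
    std_residuals: np.ndarray
    vw: float
    dof: int

    @property
    def mask(self) -> np.ndarray:
        return self.contrast.mask


def fit_glm(data: np.ndarray | list, design: DesignSpec) -> GLMFit:
    """Fit the voxelwise GLM to a stack of N subject images.

    Parameters
    ----------
    data : array-like, shape (N, ...) or list of FieldLattice
        Subject-level contrast images sharing one grid and mask.
    design : DesignSpec

    Raises
    ------
    DegenerateVarianceError
        If the residual sd is exactly zero at any masked voxel.
    """
    mask = None
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], FieldLattice):
        mask = data[0].mask
        for img in data[1:]:
            if img.shape != data[0].shape or not np.array_equal(img.mask, mask):
                raise ValueError("subject images differ in shape or mask")
        Y = np.stack([img.values for img in data])
    else:
        Y = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(Y.shape[1:], dtype=bool)
    X, w = design.X, design.w
    n, p = design.n, design.p
    if Y.shape[0] != n:
        raise ValueError(f"data has {Y.shape[0]} images but design has N={n}")

    shape = Y.shape[1:]
    Yf = Y.reshape(n, -1)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Yf)            # (p, V)
    resid = Yf - X @ beta                  # (N, V)
    dof = n - p
    sigma = np.sqrt(np.sum(resid**2, axis=0) / dof)

    sig_img = sigma.reshape(shape)
    bad = mask & (sig_img == 0)
    if bad.any():
        voxel = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DegenerateVarianceError(
            f"zero residual variance at masked voxel {voxel}"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        std_resid = np.where(sigma > 0, resid / sigma, 0.0)
    contrast = (w @ beta).reshape(shape)
    vw = float(np.sqrt(w @ xtx_inv @ w))
    return GLMFit(
        contrast=FieldLattice(contrast, mask),
        sigma_hat=FieldLattice(sig_img, mask),
        std_residuals=std_resid.reshape(Y.shape),
        vw=vw,
        dof=dof,
    )
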