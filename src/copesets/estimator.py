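"""Scikit-learn style estimator for spatial confidence sets.

``ConfidenceSetEstimator`` runs the full pipeline on a stack of subject
images: voxelwise GLM fit, plug-in boundary of the thresholded contrast,
sub-voxel interpolation of the standardized residuals onto that boundary,
multiplier bootstrap of the boundary supremum, critical value k, and the
nested upper / point-estimate / lower sets.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .boundary import find_boundary_edges, interpolate_to_boundary
from .bootstrap import BootstrapConfig, bootstrap_sup_distribution, critical_value
from .confidence_sets import construct_cs
from .glm import DesignSpec, fit_glm
from .lattice import FieldLattice


class ConfidenceSetEstimator(BaseEstimator):
    """Simultaneous confidence sets for the excursion set of a contrast map.

    With confidence 1 - alpha, the upper set ``upper_`` lies inside the
    true excursion set {w'beta >= threshold} and the true set lies inside
    ``lower_``, simultaneously.

    Parameters
    ----------
    threshold : float
        Raw-effect threshold c (e.g. %BOLD change).
    alpha : float
        1 - confidence level, in (0, 1).
    n_bootstrap : int
        Number of multiplier-bootstrap replicates B.
    multiplier : {"rademacher", "gaussian"}
        Bootstrap multiplier distribution.
    variant : {"t", "plain"}
        "t" studentizes each bootstrap replicate (wild t-bootstrap,
        recommended); "plain" is the unstudentized wild bootstrap.
    random_state : int or numpy Generator
        Seed for the bootstrap multipliers.

    Attributes
    ----------
    contrast_ : ndarray           Fitted contrast map w'beta_hat.
    sigma_ : ndarray              Pointwise residual sd.
    vw_ : float                   Normalized contrast sd sqrt(w'(X'X)^-1 w).
    k_ : float                    Bootstrap critical value.
    sup_distribution_ : ndarray   The B bootstrap suprema.
    point_estimate_ : ndarray     Boolean mask {contrast >= c}.
    upper_, lower_ : ndarray      Boolean upper / lower confidence sets.
    confidence_sets_ : ConfidenceSets
    n_boundary_edges_ : int

    Examples
    --------
    >>> import numpy as np
    >>> from copesets import ConfidenceSetEstimator
    >>> rng = np.random.default_rng(0)
    >>> y = 3.0 * (np.hypot(*np.mgrid[-20:20, -20:20]) < 10)[None] \\
    ...     + rng.standard_normal((40, 40, 40))
    >>> est = ConfidenceSetEstimator(threshold=2.0, alpha=0.05).fit(y)
    >>> bool(est.upper_.sum() <= est.lower_.sum())
    True
    """

    def __init__(
        self,
        threshold: float = 0.0,
        alpha: float = 0.05,
        n_bootstrap: int = 5000,
        multiplier: str = "rademacher",
        variant: str = "t",
        random_state=0,
    ):
        self.threshold = threshold
        self.alpha = alpha
        self.n_bootstrap = n_bootstrap
        self.multiplier = multiplier
        self.variant = variant
        self.random_state = random_state

    def _bootstrap_config(self) -> BootstrapConfig:
        return BootstrapConfig(
            B=self.n_bootstrap,
            multiplier=self.multiplier,
            variant=self.variant,
            seed=self.random_state,
        )

    def fit(self, X, y=None, design: DesignSpec | None = None,
            mask: np.ndarray | None = None):
        """Fit the GLM and calibrate the confidence sets.

        Parameters
        ----------
        X : array-like, shape (N, ...) — stack of N subject images.
        y : ignored (sklearn API).
        design : DesignSpec, optional
            Defaults to the one-sample design (column of ones, w = (1)).
        mask : boolean ndarray, optional
            Observation mask; defaults to all voxels.
        """
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        data = np.asarray(X, dtype=float)
        if data.ndim < 2:
            raise ValueError("X must be a stack of images, shape (N, ...)")
        if design is None:
            design = DesignSpec.one_sample(data.shape[0])

        if mask is None:
            glm = fit_glm(data, design)
        else:
            glm = fit_glm([FieldLattice(img, mask) for img in data], design)
        config = self._bootstrap_config()
        edges = find_boundary_edges(glm.contrast, self.threshold,
                                    source="estimated")
        resid_b = interpolate_to_boundary(glm.std_residuals, edges)
        sups = bootstrap_sup_distribution(resid_b, config)
        k = critical_value(sups, self.alpha)
        cs = construct_cs(
            glm, self.threshold, k, alpha=self.alpha,
            settings={
                "c": self.threshold, "alpha": self.alpha, "B": self.n_bootstrap,
                "multiplier": self.multiplier, "variant": self.variant,
                "seed": None if isinstance(self.random_state, np.random.Generator)
                else self.random_state,
                "boundary": "estimated", "k": k,
            },
        )

        self.glm_ = glm
        self.boundary_edges_ = edges
        self.n_boundary_edges_ = len(edges)
        self.sup_distribution_ = sups.sups
        self.k_ = k
        self.confidence_sets_ = cs
        self.contrast_ = glm.contrast.values
        self.sigma_ = glm.sigma_hat.values
        self.vw_ = glm.vw
        self.mask_ = glm.mask
        up, pe, lo = cs.masks()
        self.upper_, self.point_estimate_, self.lower_ = up, pe, lo
        return self

    def predict(self, X=None) -> np.ndarray:
        """Return the nesting-encoded label map of the fitted sets.

        0 outside the lower set, 1 lower only, 2 point estimate, 3 upper.
        ``X`` is ignored; the sets are properties of the fitted group.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "confidence_sets_")
        return self.confidence_sets_.label_map()
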