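# Methods

## The model

At each lattice location $s$ in a 2D or 3D image domain, subject-level
raw-effect images (e.g. %BOLD-change contrast maps) follow the
mass-univariate general linear model

$$Y(s) = X\beta(s) + \varepsilon(s),$$

with an $N \times p$ design matrix $X$ shared across locations,
independent mean-zero errors of pointwise variance $\sigma^2(s)$, and an
arbitrary (unknown) spatial correlation.  For a contrast $w$ in raw
units, the target of inference is the excursion set

$$A_c = \{s : w^\top\beta(s) \ge c\},$$

the region where the population raw effect meets a threshold $c$.

The procedure produces three nested sets from the OLS fit
$\hat\beta = (X^\top X)^{-1}X^\top Y$: the point-estimate set
$\hat A_c = \{w^\top\hat\beta \ge c\}$ and the upper/lower confidence
sets

$$\hat A_c^{+} = \{w^\top\hat\beta \ge c + k\,\hat\sigma v_w\},\qquad
  \hat A_c^{-} = \{w^\top\hat\beta \ge c - k\,\hat\sigma v_w\},$$

where $v_w = \sqrt{w^\top(X^\top X)^{-1}w}$ is the normalized contrast
sd (equal to $1/\sqrt N$ in the one-sample model).  The critical value
$k$ is chosen so that, asymptotically,
$P[\hat A_c^{+} \subset A_c \subset \hat A_c^{-}] \ge 1-\alpha$
*simultaneously*: every voxel inside the upper set can be asserted to
exceed $c$, every voxel outside the lower set to fall below $c$, with a
single $(1-\alpha)$ confidence statement.  The set difference
$\hat A_c^{-} \setminus \hat A_c^{+}$ is a confidence region for the
boundary $\partial A_c$.

All three sets use closed thresholds ($\ge$), so ties sit inside; voxels
outside the mask never enter any computation or output.

## Critical value: the wild t-bootstrap on the boundary

$k$ is the $(1-\alpha)$ quantile of $\sup_{\partial A_c}|G|$, where $G$
is the limiting unit-variance error field.  The supremum distribution is
approximated by a multiplier bootstrap on the standardized residuals
$\tilde\varepsilon_i = (Y_i - X\hat\beta)/\hat\sigma$: each replicate
draws i.i.d. multipliers $r_1,\dots,r_N$ and forms

$$G^*(s) = \frac{1}{\sqrt N}\sum_i r_i\,\tilde\varepsilon_i(s)
  \quad\text{(plain)},\qquad
  \tilde G^*(s) = \frac{G^*(s)}{\hat\sigma^*(s)}
  \quad\text{(t variant)},$$

with $\hat\sigma^*(s)$ the sample sd (divisor $N-1$) of
$\{r_i\tilde\varepsilon_i(s)\}$ within the replicate.  The supremum of
$|{\cdot}|$ over the boundary points is recorded per replicate, and $k$
is the $\lceil(1-\alpha)B\rceil$-th smallest of the $B$ suprema — a pure
order statistic, bit-reproducible and slightly conservative, with no
interpolation between order statistics.

Defaults are Rademacher multipliers ($\pm 1$ each w.p. 1/2) and the
t variant: the studentization makes each replicate a monotone,
tail-inflating transform of the multiplier sum, mimicking the
$t$-distribution of the actual standardized estimation error and
restoring validity at moderate $N$ where the plain Gaussian-multiplier
bootstrap under-covers (see the acceptance experiments).

Implementation notes: the per-replicate variance is computed via
$\hat\sigma^{*2} = (\sum_i (r_i\tilde\varepsilon_i)^2 - (\sum_i
r_i\tilde\varepsilon_i)^2/N)/(N-1)$, avoiding any $B\times N\times E$
temporary; a boundary point with $\hat\sigma^* = 0$ (possible only for
degenerate residuals) contributes 0 to that replicate's supremum and
logs a warning — aborting the replicate would bias $k$.

## Boundary on the lattice

The continuous boundary $\partial A_c$ is sampled at sub-voxel crossing
points: for every axis-adjacent masked pair with $f(s_I) \ge c >
f(s_O)$, linearity along the edge puts the crossing at the point whose
interpolation weights are $m_1 = (f(s_I)-c)/(f(s_I)-f(s_O))$ on $s_O$
and $m_2 = (c-f(s_O))/(f(s_I)-f(s_O))$ on $s_I$; the same weights carry
residuals, fitted contrast and sd to the crossing point.  Adjacency is
deliberately axis-aligned (4-neighbourhood in 2D, 6 in 3D): diagonal
edges would over-sample corners.  With real data the plug-in boundary of
$\hat A_c$ is used; in simulation the true boundary of the known mean is
also available as a diagnostic.

## Coverage assessment in simulation

Direct comparison of the three voxel masks misses violations in which
the continuous upper set leaks across $\partial A_c$ between lattice
points, inflating empirical coverage (severely so in 3D).  The sub-voxel
assessment therefore interpolates the fitted threshold statements to
every crossing point $s^*$ of the *true* boundary: an upper violation is
declared when $m_1(\hat\mu(s_O)-k\hat\sigma(s_O)v_w) +
m_2(\hat\mu(s_I)-k\hat\sigma(s_I)v_w) \ge c$ (the upper set reaches the
boundary), a lower violation when the analogous $+k$ combination falls
below $c$.  A trial counts as covered only when the lattice check and
the sub-voxel check both pass; the conjunction is never more lenient
than the lattice check alone.

## Synthetic study conditions

The generator reproduces the validation designs: 2D $100\times100$
fields with a linear ramp (1 to 3 along x) or a circular phantom
(magnitude 3, radius 30, smoothed with a 3-voxel-FWHM Gaussian); 3D
$100^3$ fields with spherical phantoms of radius 5 or 30 and a
four-sphere configuration, smoothed and rescaled to maximum 3 (the
four radii are not dictated by the design; the defaults 4, 8, 12, 16
voxels are well separated and configurable).  Noise is white Gaussian
smoothed with a 3-voxel-FWHM kernel and scaled to a target sd field —
constant 1, or a linear ramp 0.5 to 1.5 along the first axis.  Thresholds
are $c=2$ with $1-\alpha \in \{0.80, 0.90, 0.95\}$, sample sizes
$N \in \{60, 120, 240, 480\}$, 3000 trials and $B=5000$ at full scale.

Two conventions the design descriptions leave open:

* **Noise renormalization.**  Smoothing shrinks the variance of white
  noise, so the smoothed field is divided by its exact pointwise sd
  (a separable convolution of the squared kernel) before applying the
  target sd — the stated sd is then the sd of the noise actually added,
  everywhere including near the zero-padded border.  Coverage is
  invariant to a global noise scale (residuals are standardized), so
  this choice affects interpretability, not results.
* **sd divisors.**  $\hat\sigma$ uses $N-p$ (residual dof);
  $\hat\sigma^*$ uses $N-1$.

Smoothing is separable Gaussian convolution with
$\sigma = \mathrm{FWHM}/(2\sqrt{2\ln 2})$, zero padding, kernel
truncated at $4\sigma$ — so a constant field is attenuated only within
$4\sigma$ of the border.

Reproducibility: each trial draws its noise and bootstrap multipliers
from an independent child of the master seed (`numpy` `SeedSequence`
spawning), so results are bit-identical for a fixed configuration and
seed regardless of execution order.  Trials whose estimated excursion
set has no boundary cannot calibrate $k$; they are excluded with a
logged count (none occur at the shipped configurations).

## What the synthetic experiments do and do not show

The phantoms share key features of group-level fMRI raw-effect maps —
smooth compact activation with a sharp intensity gradient at the cluster
edge, stationary or smoothly varying noise sd, realistic smoothness
(3-voxel FWHM ≈ 6 mm at 2 mm voxels) — but the noise is Gaussian,
stationary in correlation, and independent across subjects by
construction.  Passing coverage here supports the calibration of $k$
under the model's assumptions; it cannot detect sensitivity to heavy
tails, inter-subject correlation, or registration error in real data.
The generic custom-signal/custom-sd hooks accept empirical mean and sd
images for study-specific simulation.

## Problem sizes used in the shipped experiments

The packaged validation runs use reduced Monte-Carlo scale chosen to
keep a full run on one CPU in minutes: the 2D circle at the original
$100\times100$ grid with 500–1000 trials and $B=1000$; 3D spheres in a
$40^3$ box (radii 5 and 12) with 300 trials and $B=500$.  The 2D
experiments run at the original grid and reproduce the published
full-scale coverage behaviour closely.  The severity of the plain
Gaussian-bootstrap under-coverage in 3D grows with the boundary size
(the supremum is taken over more effectively-independent points, pushing
the calibration further into the tail where the Gaussian and
$t$-distributions separate), so the reduced 3D configuration
demonstrates the direction but not the full magnitude of that effect;
the wild t-bootstrap's validity band is scale-stable and is reproduced
directly.

## Known limitations

* Inference is for raw (not standardized) effect sizes; thresholds are
  in the units of the input maps.
* Confidence sets at different thresholds $c$ are each marginally
  $(1-\alpha)$; there is no joint calibration across thresholds.
* The coverage assessment samples the continuous boundary at finitely
  many crossing points and can still miss violations between them, a
  positive bias that grows with boundary length and coarseness.
* Degenerate inputs fail loudly: zero residual variance at a masked
  voxel, rank-deficient designs, and empty estimated boundaries raise
  typed errors rather than returning sets.
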