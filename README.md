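# copesets

Simultaneous spatial confidence sets for excursion sets of raw-effect-size
images.

Mass-univariate group analyses of neuroimaging data usually end in a
thresholded statistic map: it tells you where a null effect can be
rejected, but nothing about *where the raw effect size itself exceeds a
meaningful level*, nor how that region would vary under repeated
sampling.  `copesets` addresses both for users of subject-level raw
effect maps (e.g. %BOLD-change contrast images).  Given a threshold $c$
and confidence level $1-\alpha$, it produces three nested sets from the
voxelwise GLM $Y(s) = X\beta(s) + \varepsilon(s)$:

- the **point-estimate set** $\hat A_c = \{s: w^\top\hat\beta(s) \ge c\}$,
- an **upper confidence set** $\hat A_c^{+} = \{w^\top\hat\beta \ge
  c + k\hat\sigma v_w\}$ — voxels asserted to truly exceed $c$,
- a **lower confidence set** $\hat A_c^{-} = \{w^\top\hat\beta \ge
  c - k\hat\sigma v_w\}$ — voxels outside it asserted to truly fall
  below $c$,

such that $P[\hat A_c^{+} \subset A_c \subset \hat A_c^{-}] \ge 1-\alpha$
holds *simultaneously* for the true excursion set
$A_c = \{w^\top\beta \ge c\}$.  The critical value $k$ is the
$(1-\alpha)$ quantile of the supremum of the limiting error field over
the excursion-set boundary, computed by a wild t-bootstrap (Rademacher
multipliers, per-replicate studentization) of standardized residuals
linearly interpolated onto sub-voxel boundary crossing points.  The
package also ships the full Monte-Carlo machinery used to validate
empirical coverage on synthetic 2D/3D phantoms, including the sub-voxel
(interpolated) coverage assessment that removes the upward bias of
comparing voxel masks directly.

See `docs/methods.md` for the model, the bootstrap variants, and every
numerical convention.

## Worked example

Sixty synthetic subjects: a circular raw effect of magnitude 3 (radius
30, 3-voxel-FWHM smoothing) in a 100×100 image plus smoothed unit-sd
Gaussian noise; confidence sets for the region exceeding $c = 2$ at 95%
confidence.

```python
import numpy as np
from copesets import ConfidenceSetEstimator
from copesets.synthetic import SignalSpec, NoiseSpec, make_signal, make_noise

mu = make_signal(SignalSpec(kind="circle", shape=(100, 100), radius=30.0))
noise = make_noise(NoiseSpec(), 60, mu.shape, seed=2024)
data = mu.values[None] + noise

est = ConfidenceSetEstimator(threshold=2.0, alpha=0.05, n_bootstrap=1000,
                             multiplier="rademacher", variant="t",
                             random_state=7).fit(data)
print(f"critical value k = {est.k_:.3f} over {est.n_boundary_edges_} boundary edges")
print(f"upper CS: {est.upper_.sum()} voxels   point estimate: "
      f"{est.point_estimate_.sum()} voxels   lower CS: {est.lower_.sum()} voxels")
```

prints

```
critical value k = 3.772 over 238 boundary edges
upper CS: 2606 voxels   point estimate: 2721 voxels   lower CS: 2826 voxels
```

Reading: all 2606 upper-CS voxels can be asserted (with 95% simultaneous
confidence) to have a true raw effect above 2; everything outside the
2826-voxel lower CS is asserted to lie below 2; the 220-voxel shell
between them is a confidence region for the true cluster boundary.  In
this realization the true excursion set (2708 voxels) is indeed
bracketed by the two sets.

The estimator follows scikit-learn conventions (`get_params`,
`set_params`, trailing-underscore fitted attributes); thin functional
wrappers (`compute_confidence_sets`, `fit_glm`, `find_boundary_edges`,
`bootstrap_sup_distribution`, `run_simulation`, ...) expose each stage
separately.

## Command line

```sh
# confidence sets from subject-level NIfTI contrast maps
copesets compute --data con_4d.nii.gz --mask mask.nii.gz \
    --threshold 2.0 --alpha 0.05 --boot 5000 --out results/cs

# Monte-Carlo coverage experiment from a YAML config
copesets simulate --config sim.yaml --out coverage.csv

# write the standard validation phantoms as NIfTI
copesets fixtures --out phantoms/
```

`compute` writes the three sets as uint8 masks, a nesting-encoded label
map (0 none, 1 lower only, 2 point estimate, 3 upper) and a JSON sidecar
with all settings and the computed `k`.

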