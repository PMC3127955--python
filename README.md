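# anisosmooth

Anisotropic Gaussian scale-space model of perceived orientation: why an
elongated luminance blob looks tilted toward vertical, and how to measure
the visual system's smoothing kernel from adjustment-task data.

## The problem

Elongated Gaussian luminance profiles (GLPs) — elliptical 2-D Gaussian
blobs — induce an illusory orientation bias: the thicker the blob, the more
its perceived orientation is attracted toward vertical, even though the
physical principal axis is unchanged. This package models that illusion as
*anisotropic scale-space smoothing*: the visual system observes the retinal
image at finite resolution, modelled as convolution with an elliptical
Gaussian kernel that is elongated vertically (horizontal radius a_h smaller
than vertical radius a_v).

Because the convolution of two Gaussians is a Gaussian whose covariance is
the sum of the inputs, the perceived profile of a GLP with covariance
Σ_glp under a kernel with covariance Σ_kernel = [[a_h², r], [r, a_v²]] is

    Σ_perceived = Σ_glp + Σ_kernel,

and the predicted orientation bias is the rotation of the principal axis of
Σ_perceived away from that of Σ_glp (counterclockwise positive, wrapped to
(−90°, 90°]). A vertically elongated kernel pulls every oblique orientation
toward 90°, more strongly for rounder (thicker) blobs — exactly the
illusion.

The package provides, as separate library modules with a thin CLI on top:

- **stimuli** — GLP specifications, the factorial adjustment-task design
  (12 orientations × 3 aspect ratios × 2 viewing frames × 3 blocks × 5
  repetitions = 1080 trials per participant), and pixel rendering;
- **scalespace** — elliptical Gaussian kernels, the covariance-addition
  smoothing rule, principal-axis extraction, and an independent numeric
  oracle (discrete convolution + image second moments);
- **bias_model** — bias predictions under five nested kernel models:
  isotropic (0 free parameters), homogeneous (a_h, a_v; 2), homogeneous
  oriented (+ covariance term r; 3), radial heterogeneous (one kernel per
  stimulus thickness; 6), angular heterogeneous (one oriented kernel per
  stimulus-orientation subset; 36 raw, 18 after mirror-pair aggregation);
- **observer_sim** — synthetic adjustment-task observers with
  heteroscedastic, 180°-circular response noise and 1° probe quantization;
- **fitting** — mirror-pair aggregation with circular statistics, weighted
  least-squares model fitting, nested F tests
  F = ((WRSS₁−WRSS₂)/(p₂−p₁)) / (WRSS₂/(n−p₂)), and explained-variance
  accounting against the systematic (saturated-mean) ceiling;
- **cli / pipeline** — `anisosmooth` command with `generate`, `simulate`,
  `fit`, `compare`, `oracle-check`, `report`, and `run` subcommands.

## Worked example

```python
import numpy as np
from anisosmooth import (
    DesignSchedule, KernelSpec, ObserverSpec, aggregate_pairs,
    fit_model, make_glp, nested_f_test, predict_bias, simulate_experiment,
)

kernel = KernelSpec(a_h=0.84, a_v=2.08)          # vertically elongated aperture
glp = make_glp(aspect_ratio=0.5, orientation=22.5)  # thin oblique blob
print(round(predict_bias(glp, kernel), 2))       # 43.35 (degrees, toward vertical)

# simulate one synthetic participant and fit the homogeneous model
design = DesignSchedule(participants=1)
table = simulate_experiment(design, [ObserverSpec(kernel=kernel, seed=7)])
conditions = aggregate_pairs(table)              # 18 mirror-pair cells, n=60 each
fit = fit_model("homogeneous", conditions)
print(np.round(fit.params, 2))                   # [0.48 1.96]

# is per-thickness smoothing significantly better?
radial = fit_model("radial_heterogeneous", conditions)
res = nested_f_test(fit, radial)
print(res.df1, res.df2, round(res.F, 2), round(res.p_value, 3))  # 4 1074 0.5 0.739
```

The predicted bias of +43.35° says the thin 22.5° blob's perceived axis
rotates to ≈66° under this kernel. The homogeneous fit estimates the
kernel radii (0.48, 1.96) from this observer's 1080 noisy quantized
trials — the covariance difference a_v² − a_h² is pinned tightly by the
mean biases while the absolute scale, set from the response dispersions,
scatters more from observer to observer (see `docs/methods.md`); group
means over six observers land close to the generating (0.84, 2.08). The
radial model's improvement over the homogeneous fit is consistent with
chance for this homogeneous-generated observer (F(4, 1074) = 0.5,
p = 0.74).

The same pipeline from the shell:

```sh
anisosmooth run --outdir runs/demo --seed 1        # simulate + fit + compare + report
anisosmooth oracle-check                            # analytic vs numeric agreement
```

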