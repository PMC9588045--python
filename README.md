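# lamina

Analysis toolkit for block-design laminar and retinotopic fMRI studies of
**valence modulation** — the finding that emotionally expressive (fearful,
happy) faces evoke larger responses than neutral faces throughout visual
cortex, with evidence that the effect reaches V1 through diffuse,
superficial-layer feedback from the amygdala.

The package implements the full analysis chain such a study needs and a
seeded synthetic-data generator that reproduces the statistical structure
each stage assumes, so every step is testable against planted ground
truth:

- **`lamina.design` / `lamina.synth`** — three-condition block designs
  (fearful/neutral/happy + fixation) at 3T-BOLD, 7T-BOLD and interleaved
  7T-VASO timings; linear HRF-convolved evoked responses,
  condition-gated shared latent fluctuations between ROIs, AR(1) noise,
  VASO pairs with opposite-signed responses and multiplicative BOLD
  contamination, flat cortical ribbons and eccentricity maps out to
  88 deg.
- **`lamina.glm`** — canonical double-gamma GLM and FIR deconvolution
  (`y = Xb + r`, evoked estimate `yhat = Xb`, residual `r = y − yhat`).
- **`lamina.conncorr`** — residual inter-area correlation: per-condition
  epochs (face block + following fixation), ROI×ROI Pearson matrices,
  fearful−neutral contrasts, Wilcoxon/one-sample-t group tests with
  Bonferroni correction.
- **`lamina.vaso`** — interleaved blood-nulled/not-nulled splitting,
  cubic temporal alignment, BOLD correction by frame-wise division
  (×−1), and the T1-EPI "VASO anatomy" contrast `(1/σ)/μ`.
- **`lamina.laminar`** — equidistant cortical depths (21 bins between the
  WM and CSF boundaries), peak-R² slice profile extraction, and
  uncertainty-weighted penalized-spline smoothing (REML).
- **`lamina.bml`** — the region-based Bayesian multilevel model

      y_crs ~ StudentT(ν, b_c + ξ_cs + η_cr + γ_rs, σ)

  with crossed condition/region/subject varying effects, LKJ(1)
  correlation priors, half-t(3,0,1) SD priors, Gamma(2, 0.1) on ν and a
  data-scaled half-Cauchy on σ, fit with a built-in NUTS sampler;
  split-R̂/ESS diagnostics, posterior predictive checks, P+ (posterior
  probability an effect is positive) and the modulation index
  `(C1 − C2)/(|C1| + |C2|)`.
- **`lamina.roibin`** — R² > 0.1 masks, group one-third-overlap masks,
  iso-eccentricity bins, stimulus-representation and peripheral-V1 ROIs.
- **`lamina.pipeline` / `lamina` CLI** — end-to-end orchestration with
  per-stage seeding and re-runnable, file-isolated stages.

## Worked example

Fit the multilevel model to data simulated from itself (3 conditions,
8 regions, 8 subjects; population effects 0.2/0.5/0.8):

```python
import numpy as np
from lamina.bml import (simulate_dataset, fit_bml, diagnostics,
                        modulation_index, posterior_positive_prob)

y = simulate_dataset(np.random.default_rng(0), b=[0.2, 0.5, 0.8],
                     R=8, S=8, nu=30.0, sigma=0.1, lam=0.05)
post = fit_bml(y, chains=4, iterations=1000, seed=1)
diag = diagnostics(post)
print("max split R-hat:", round(float(diag.rhat.max()), 3))
print("min ESS:", round(float(diag.ess.min())))
b = post.flat("b")
for i, name in enumerate(post.conditions):
    print(f"b[{name}] mean {b[:,i].mean():.3f}  95% CI "
          f"[{np.quantile(b[:,i],0.025):.3f}, {np.quantile(b[:,i],0.975):.3f}]")
idx = modulation_index(b[:, 2], b[:, 1])
print(f"modulation index (c3 vs c2): mean {idx.mean():.3f}, "
      f"P+ {posterior_positive_prob(idx):.3f}")
```

prints

```
max split R-hat: 1.014
min ESS: 457
b[c1] mean 0.203  95% CI [0.033, 0.355]
b[c2] mean 0.484  95% CI [0.408, 0.558]
b[c3] mean 0.836  95% CI [0.724, 0.950]
modulation index (c3 vs c2): mean 0.266, P+ 1.000
```

Every 95% interval covers its simulating truth; the chains satisfy the
convergence bounds (split R̂ ≤ 1.05, ESS ≥ 200); and the c3-vs-c2
modulation index is decisively positive (P+ = 1.0), as planted.

The full synthetic-cohort pipeline (designs → simulated runs → GLM →
residual correlation → VASO → depth profiles → eccentricity bins → BML
reports) runs from the shell:

```sh
lamina all --seed 1 --out results/cohort
```

and writes per-stage tables plus `report.json`; single stages re-run in
place with `lamina simulate|glm|connectivity|vaso|layers|roi|bml`.

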