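# Methods

`lamina` implements a block-design fMRI analysis chain for laminar and
retinotopic studies of valence modulation in visual cortex, exercised end
to end on synthetic data whose statistical structure matches what each
stage assumes. This note documents the models, the defaults and why they
were chosen, and what the synthetic data do and do not emulate.

## Block designs

Three protocols are built in, each with fixed per-condition block counts
and a seeded permutation of the face-condition order (the randomization
scheme is otherwise unconstrained):

| protocol | face block | fixation | repeats/condition | TR | run |
|---|---|---|---|---|---|
| 3T-BOLD | 20 s | 10 s | 3 | 2.0 s | 280 s |
| 7T-BOLD | 18 s | 9 s | 3 | 1.5 s | 252 s |
| 7T-VASO | 19.3 s | 9.65 s | 6 | 4.825 s (effective) | 530.75 s |

Runs start with fixation and alternate face/fixation, so every face block
is followed by a fixation block — the unit on which epoch extraction and
latent gating operate. The 7T-VASO block arithmetic (18 x 19.3 s + 19 x
9.65 s = 530.75 s) is followed exactly; 530.75 s is precisely 110
effective TRs of 4.825 s (2.088 s blood-nulled + 2.737 s not-nulled
readouts).

## Synthetic-data generator

Each ROI-averaged BOLD series is the sum of three components:

1. **Evoked responses**: condition boxcars convolved with the canonical
   double-gamma HRF, scaled by per-(ROI, condition) amplitudes in percent
   signal change. Responses superpose exactly (the generator is a
   shift-invariant linear system by construction), so noiseless output is
   recovered to machine precision by FIR deconvolution.
2. **Condition-gated shared latents**: each configured (ROI pair,
   condition, coupling) entry adds an independent unit-variance AR(1)
   latent, multiplied by the coupling, to both ROIs, but only during the
   epochs (block + following fixation) of its condition. For a single
   latent with coupling `c` over noise of marginal variance `s2`, the
   expected epoch correlation is `c^2 / (c^2 + s2)`.
3. **AR(1) noise**: innovation SD `noise_sd` (default 1.0% signal),
   coefficient 0.3; marginal variance `noise_sd^2 / (1 - ar1^2)`. The
   noise spectrum of real data is not otherwise modeled.

Default amplitudes place visual-cortex responses near 2% and amygdala
responses near 0.3% (an order-of-magnitude difference seen in subcortical
fMRI), with fearful > happy > neutral. Default couplings give every
cortical pair an always-on latent (0.4), the amygdala a weak always-on
loading (0.2), and a fearful-gated amygdala increment (0.6) — the planted
"feedback" signature the correlation analysis is meant to detect.

VASO pairs are generated multiplicatively: the not-nulled series is
`b(t)`, a BOLD-like contamination factor (default 1% response amplitude);
the nulled series is `b(t) * (1 - v(t))` with `v` the planted CBV
response. `v` follows per-depth-band amplitudes (default: a 2% mid-depth
stimulus peak for every condition over depths 0.25-0.65, a 0.6% baseline
superficial response, plus superficial-only increments of 0.6% for
fearful and 0.3% for happy above depth 0.7). Frame-wise division exactly
cancels `b` and the −1 flip makes CBV increases positive. Multiplicative
Gaussian noise (default 0.3%) is added per frame. Not modeled:
inversion-recovery physics, inflow, draining-vein biophysics,
physiological noise — so passing tests demonstrate the correctness of the
processing algebra, not robustness to those confounds.

The synthetic cortical ribbon is flat (one labeled WM boundary row, N
gray rows, one CSF boundary row per axial slice); eccentricity maps grow
geometrically from 0.5 to 88 deg along one axis. Curvature and realistic
retinotopy are deliberately absent: the depth and binning code is tested
against exhaustive geometric oracles instead.

## GLM and deconvolution

The canonical HRF is the standard double-gamma (gamma shape 6/scale 1
minus 1/6 of gamma shape 16/scale 1; peak ~5 s, undershoot ~15 s),
peak-normalized so betas carry percent-signal units. Regressors are
built on a 16x oversampled grid and interpolated at frame times (which
may be offset, as after VASO realignment). Nuisance terms are a constant
and a linear drift only; high-pass filtering belongs to preprocessing,
which is out of scope.

FIR deconvolution uses one delta column per (condition, lag). The window
defaults to one design period (block + following fixation: 30 s at 3T,
27 s at 7T). Longer windows are supported but can make the FIR system
rank deficient for particular pseudo-randomized block orders once the
window exceeds the block spacing (overlapping condition columns become
collinear); the fit rejects such systems rather than silently
regularizing. The hemodynamic undershoot extending past one period is
absorbed by the next epoch's lags, exactly as in overlapping block
designs.

## Inter-area correlation

Residuals (measured minus FIR-predicted series) are cut into epochs —
each face block plus its following fixation block — concatenated across
blocks and runs, and correlated pairwise (Pearson by default; Spearman by
flag). Session matrices are averaged as plain r (Fisher-z by flag).
Baseline correlations are tested per cell against zero with a one-sided
Wilcoxon signed-rank test (zeros discarded); fearful−neutral and
happy−neutral contrasts with a two-tailed one-sample t test. The
Bonferroni denominator defaults to the number of tested cells (the
lower triangle); a per-ROI-count convention is available since the
correction base is a matter of convention.

## VASO processing

Interleaved series are split by parity (nulled-first by default, readout
centers as timestamps), cubic-spline interpolated onto a uniform grid at
half the effective TR, and trimmed by two frames at each end (which also
discards any spline edge extrapolation). BOLD correction divides nulled
by not-nulled frame-wise and multiplies by −1; percent change is taken
against the mean over fixation epochs (the baseline convention is not
otherwise fixed). Non-positive denominators are rejected rather than
clipped — silent clipping would corrupt laminar profiles. The "VASO
anatomy" (T1-EPI) contrast is `(1/sd)/mean` over all pooled frames per
voxel, with a `mean/sd` (tSNR-style) alternative behind a switch because
the defining phrase is ambiguous; zero-variance voxels get NaN sentinels.

## Laminar analysis

Depths are equidistant: `d_wm / (d_wm + d_csf)` with Euclidean distance
transforms to the nearest boundary voxel (no equivolume/curvature
correction), partitioned into K = 21 half-open bins (last bin closed).
K = 21 oversamples the cortical thickness on purpose — bins are a
visualization grid, not independent measurements, which is why
cross-depth inference goes through the spline or multilevel stage.

In-plane upsampling defaults to replication (nearest-neighbour), not
cubic interpolation: defining layers on a fine grid over replicated data
makes the layer average exactly a volume-weighted average of original
voxels, and the code's invariance test relies on that identity. Cubic
interpolation is available for display.

Profile extraction finds the axial slice with the highest mean R^2 in
the ROI and averages per-bin responses over that slice and its two
neighbours; the SE is the across-voxel standard error per bin.

Profile smoothing is a weighted penalized B-spline (P-spline): cubic
basis on uniform extended knots (10 basis functions), second-order
difference penalty, weights 1/SE^2, smoothing parameter by restricted
maximum likelihood, band = +-1 SE of the fitted curve. Uniform unclamped
knots are essential: they put linear trends exactly in the penalty null
space, so straight profiles are reproduced unpenalized. The fit is
cross-checked against R mgcv's P-spline GAM in the test suite.

## Bayesian multilevel model

The region-based model of condition effects is

    y_crs ~ StudentT(nu, b_c + xi_cs + eta_cr + gamma_rs, sigma)
    (xi_1s..xi_Cs)' ~ N(0, Theta),  (eta_1r..eta_Cr)' ~ N(0, Omega),
    gamma_rs ~ N(0, lambda^2)

with priors: flat on `b_c`; LKJ(1) (jointly uniform) on the correlation
parts of Theta and Omega; half-t(3, 0, 1) on all hierarchical SDs (the
prior is stated only for lambda; the same weakly-informative choice is
applied to the SDs of Theta and Omega); Gamma(2, 0.1) on nu; half-Cauchy
on sigma with scale equal to the SD of the input data (scale constant 1,
configurable). The Student-t likelihood absorbs outliers and skew; with
Gaussian data the posterior for `b_c` matches a Gaussian-likelihood fit
of the same structure (tested).

Sampling is by a self-contained NUTS implementation (leapfrog doubling
with slice sampling, dual-averaging step size targeting 0.9 acceptance (the usual conservative choice for hierarchical posteriors),
diagonal mass matrix adapted over expanding warmup windows) on an
unconstrained parameterization: non-centered standardized effects, log
SDs, log nu, and tanh-transformed canonical partial correlations of the
correlation Cholesky factors. Under the C-vine factorization, LKJ(1)
plus the tanh Jacobian reduce to `sum_j a_j log(1 - z_j^2)` with
`a_j = 1 + (C - 2 - j)/2`, which was verified against the known LKJ
marginal-correlation density. All gradients are hand-derived and checked
against central finite differences to ~1e-9 in the test suite; the
sampler itself is validated on correlated Gaussian targets and by
simulation-based interval coverage of the population effects.

Defaults follow the published configuration: 4 chains of 1000 iterations.
The warmup split is not stated; the first 50% of each chain is warmup.
Convergence is monitored by split R-hat (bound 1.05) and effective sample
size (bound 200 draws) over every stored parameter, computed with arviz;
non-convergence warns prominently but still returns the posterior.
Derived quantities per region: P+ (fraction of draws strictly positive)
and the dimensionless modulation index `(C1 - C2)/(|C1| + |C2|)`, defined
as 0 when both arguments are zero. The same machinery fits the
2-condition x 5-eccentricity-bin analysis. Posterior predictive checks
simulate replicate datasets from sampled parameters and flag observations
whose minimum one-sided predictive tail probability falls below 0.01.

Input effects are GLM betas in percent signal change; a
measurement-error variant weighting by t-statistics is out of scope.

## ROI construction

R^2 thresholds are strict (`> 0.1` by default). Group-overlap masks keep
voxels present in at least `ceil(fraction x subjects)` individual masks
(default one third). Eccentricity bins are half-open with a closed outer
edge at 88 deg; the five default edges (0.5, 2, 2.5, 6, 20, 88) separate
the stimulus representation (the 4 x 6 deg face ellipse reaches ~2 deg),
the suppressive penumbra (2.5-6 deg), and three peripheral bands — the
exact five edges are a package convention, not a measured quantity. The
peripheral V1 ROI starts beyond the stimulus representation plus a 0.5
deg guard band and extends to 88 deg.

## Pipeline and problem sizes

`run_end_to_end` chains synth → glm → {conncorr; vaso → laminar} →
roibin → bml, with every stage reading only files written by earlier
stages, so stages can be re-run in place. A single global seed fans out
through `SeedSequence` spawn keys per (stage, subject, run); re-running a
stage reproduces its outputs byte-for-byte.

Default cohort sizes mirror the emulated study (15 subjects for the ROI
analysis, 10 VASO subjects, 14 for the eccentricity analysis). The test
suite exercises the pipeline at reduced sizes (5 subjects, 4 ROIs, small
grids, 2 chains x 200 iterations) and runs the interval-coverage study at
20 replicates (10 regions x 10 subjects, 2 chains x 500 iterations per
fit — interval coverage under the generating model does not depend on the
crossing size); these are the
package's chosen verification sizes, with the full-size fit exercised
once in the acceptance checks (4 x 1000 on the 3 x 15 x 15 problem).

## Known limitations

- The generator's flat ribbon and monotone eccentricity map make the
  geometric oracles exact but do not probe curvature, partial-volume or
  registration errors.
- Equidistant layering differs from equivolume layering on curved
  cortex; on the flat synthetic ribbon they coincide.
- The NUTS implementation uses a diagonal mass matrix; strongly
  correlated posteriors (e.g., nearly unidentified `b_c` vs. effect
  means under very large hierarchical SDs) would mix more slowly than a
  dense-mass or reparameterized sampler.
- Session-level structure (motion, scanner drift beyond linear,
  physiological noise) is not simulated; conclusions about real-data
  robustness require real data.
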