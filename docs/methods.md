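# Methods

## Statistical core

Correlation significance uses the exact null distribution of the sample
Pearson coefficient: t = r√(n−2)/√(1−r²) referred to Student's t with
n−2 df. P-values are two-tailed everywhere unless a caller asks
otherwise; the two-tailed convention reproduces every printed
correlation p in the cohort this pipeline targets (e.g. r = −0.71 at
n = 11 → p = 0.0144). |r| ≥ 1 returns p = 0 with a degeneracy flag
rather than an error, because perfectly collinear columns legitimately
arise in resampled data.

The percentile CI uses linear interpolation between order statistics
(the "type 7" quantile rule, numpy's default) so bootstrap intervals
are continuous in the data and bit-for-bit reproducible.

The mass-univariate GLM solves each response by QR-based least squares
(`lstsq`), with the contrast variance from c′(X′X)⁻¹c·σ̂²; the test
suite cross-checks the betas against an explicit normal-equation solve.
Rank-deficient designs are rejected with the dependent columns named.
The two-sample t-test is pooled-variance (not Welch), matching the GLM
group-contrast formulation used by the standard vertex/voxel packages;
the two are verified equal to 1e−10.

Fisher's z = atanh(r) is applied after clipping r to ±(1 − 1e−7) when
building connectivity maps, because voxels inside the seed sphere
correlate at exactly 1 with the seed mean.

## Surface stage

Smoothing is an iterated area-weighted neighbour diffusion. Treating
one step as a random walk that moves to an edge neighbour with total
probability λ, the per-axis kernel variance added per step is
λ·⟨edge²⟩/2; the step count is the smallest n with λ ≤ 0.5 and λ is
solved exactly so the cumulative variance equals (FWHM/√(8 ln 2))².
On a subdivided icosphere the measured impulse-response FWHM is within
~15–20% of the request, the accuracy cluster-extent thresholds need.
Constants are preserved exactly (the operator is row-stochastic);
isolated vertices are left unchanged with a warning.

The vertex model is thickness ~ intercept + group + sex + age, sex
coded 0/1 and age mean-centred; smoothing is applied to each subject's
map *before* fitting. If the cohort is single-sex the sex column is
dropped with a warning rather than producing a singular fit.

Clusters are connected components over shared-edge adjacency (never
vertex-touching chains), split by effect sign so thicker and thinner
regions cannot merge; extent is the summed per-vertex area (one third
of incident triangle area, so vertex areas tile the surface), measured
on the shared template mesh. The peak is the member of maximal |t|,
ties broken toward the lowest vertex index for determinism. No
whole-brain correction is applied at this stage: the operative rule is
uncorrected vertex p < 0.001 with 30 mm² minimum extent.

## Covariance deviation

The deviation statistic is deliberately a conjunction: a pair is
flagged only when the patient correlation lies outside the control
bootstrap 99% CI *and* is itself significant at α = 0.05. Both
conditions are always reported so a reader can see which one failed.
Controls are resampled with replacement at the patient sample size
(1000 iterations by default); degenerate resamples (zero variance) are
redrawn rather than scored as r = 0, keeping the CI a functional of
observed correlations, and the redraw count is logged. More than 50%
redraws aborts the analysis as unusable data.

No multiplicity correction is applied across the 15 pairs or the
parcel-wise seed profile by default — this mirrors the uncorrected
reference procedure — but a Bonferroni switch exists and the test
suite asserts it can only shrink the flag set.

Randomness policy: one master seed expands into an independent
`SeedSequence` stream per region pair, so adding or removing a region
never perturbs the other pairs' intervals. The cost is that resamples
are not shared across pairs within an iteration; the CI of each pair is
unaffected by this choice.

Calibration, measured by the test suite: with patients and controls
drawn from the same distribution the per-pair flag rate is ~1–2%
(bounded by (1−level) plus the joint condition), and an injected
patient-only correlation of 0.8 at 50 subjects per group is flagged
with essentially full power. At the realistic n = 11 patients, power
is modest — a property of the design, not the implementation.

Covariate correlations (deprivation days, acuity) handle missing
entries pairwise-complete with the count reported, support dropping a
nominated subject, and always return the full leave-one-out list of
correlations. Acuity is stored as the decimal fraction (20/32 → 0.625)
with a logMAR option in config, since either encoding is defensible.

## Functional stage

Preprocessing discards the first 10 volumes, then residualizes each
voxel on [intercept, linear trend, Friston-24, WM, CSF, global mean].
The Friston-24 expansion is [m, m², m_{t−1}, m_{t−1}²] with the lag row
zero-filled. Global-signal regression is on by default (it changes the
sign structure of connectivity; a toggle exists). Volumes are then
smoothed with a 6 mm 3-D Gaussian. Residualization is idempotent —
re-running on its own output changes nothing beyond 1e−8 — and the
returned run keeps the truncated nuisance series to make that checkable.

Seed series are the mean over mask voxels whose centres lie within
3 mm of the seed coordinate (7 voxels on a 3 mm grid when centred on a
voxel); radius 0 degenerates to the nearest mask voxel. Subject maps
are Fisher-z of the voxelwise correlation with the seed series.

Group inference is two-stage: one-sample t-tests per group at
two-tailed p < 0.001 define the significance mask — the *union* of the
two groups by default, so a connection present in either group is
testable (intersection available); the two-sample group test runs
only inside it. The two-sample t-map is converted to z by probability
matching, thresholded at two-tailed p < 0.001, and 18-connected
sign-homogeneous clusters receive corrected p-values. Group-difference
degrees of freedom follow the pooled two-sample formula (n₁+n₂−2) with
no additional covariates. Cluster tables report the group-mean z at
the peak and its back-transform tanh(z̄), labelled as such.

A motion screen (max translation 2.5 mm / rotation 2.5°) is available
as a dataset-level filter before this stage, with exclusions logged.

## Random-field correction

Smoothness is estimated from standardized residuals of the two-sample
model (not raw data): for a Gaussian autocorrelation the lag-1
correlation ρ of unit-variance residuals along an axis gives
σ² = −1/(4 ln ρ) in voxel units and FWHM = √(8 ln 2)·σ. Estimates are
floored at the voxel size — white noise is reported at ~1 voxel FWHM,
and masks thinner than two voxels carry no directional information.
Resels are search volume divided by the FWHM product.

Corrected cluster p-values use the Gaussian-field Euler-characteristic
density ρ₃(z) = (4 ln 2)^{3/2}(2π)^{−2}(z²−1)e^{−z²/2}:
E[clusters] = resels·ρ₃(z) (doubled for two-sided thresholds),
expected suprathreshold volume from the Gaussian tail, and the
classical exponential extent distribution P(n ≥ k) = exp(−βk^{2/3}),
β = (Γ(5/2)/n̄)^{2/3}, giving p = 1 − exp(−E[m]·P(n ≥ k)). t-maps are
converted to z by probability matching before thresholding, so only
Gaussian densities are needed; at the df in scope this approximation is
accurate to a few percent.

Two properties of the classical form are worth knowing. First, it is
*conservative* in the far tail: on simulated null fields the true
P(n ≥ k) decays roughly exponentially in k while the k^{2/3} form
decays slower, so corrected p-values overestimate by a factor of ~2–3
near p = 0.05 and the family-wise false-positive rate at nominal 5%
measures ~2–3% (6 mm FWHM on 2 mm voxels, 32³ grid, 1000 fields). The
0.05-critical cluster *size*, however, agrees with the permutation /
simulation oracle within ~1.3×. Second, at a fixed voxel extent a
rougher field yields a *smaller* corrected p — a given cluster size is
rarer when null clusters are tiny — which is the correct direction for
extent-based (as opposed to peak-based) inference.

A group-label permutation oracle (max-cluster-extent null, rank rule
(1 + #{null ≥ k})/(n_used + 1), exhaustive enumeration when fewer
distinct relabelings exist than requested) is provided both as an
alternative correction mode and as the validation target.

## Synthetic data

The generator's defaults are the study conditions: 11 patients vs 24
controls for thickness (15 controls for the functional runs), six
regions with the reported group means and sds, deprivation durations on
[65, 283] days with mean ≈ 138 (triangular), decimal acuity
log-uniform on [0.16, 1.0], 240 volumes at TR 2.25 s on an MNI-like
3 mm grid. Controls are age-matched within ±2 years and sex-matched to
patients.

The patient inter-region correlation structure is a one-factor model
with the lingual gyrus as hub; the three reported deviant pairs
(−0.71, −0.67, +0.71) appear exactly as matrix entries and the matrix
is positive semi-definite by construction (the reported values are
mutually infeasible if the remaining pairs are forced independent —
their squared sum against the hub exceeds 1 — so a hub structure is
the minimal consistent completion). Controls use uniform loadings
giving 0.2 everywhere.

Thickness noise is white Gaussian smoothed on the mesh with the same
diffusion smoother the analysis uses, then rescaled to the requested
per-vertex sd — cluster inference is meaningless on spatially white
noise. BOLD voxels mix latent unit-variance ROI signals so a target
block attains a chosen population correlation (feasible only when each
block's squared loadings sum below 1, else an error), plus linear
drift, a random-walk motion-coupled component, AR(1) WM/CSF series and
white noise; the global series is the mask mean of the assembled data.

What the generator does *not* emulate: folded cortical geometry and
registration error, MR physics (no T2* decay, no physiological noise
spectra), realistic head-motion artefacts beyond linear coupling, and
spatial non-stationarity of smoothness. Passing tests therefore show
the statistics behave correctly on data satisfying the model
assumptions, not that the pipeline is robust to the artefacts of real
acquisitions.

## Problem sizes and determinism

All generators and analyses are pure functions of (parameters, seed);
repeated pipeline runs with one config produce byte-identical TSVs
(fixed float format, ordered rows). Simulation-based checks use sizes
chosen to keep each one in the seconds-to-minutes range on one CPU:
500 cohorts for null calibration of the deviation test, 100 seeds for
its power, 1000 null fields (32³) for RFT calibration, 50 cohorts of
26 subjects × 200 volumes for FC recovery; the acceptance script uses
200 / 50 / 500 / 20 of the same checks. Estimates at these sizes have
Monte-Carlo sds comfortably inside the asserted margins, except where a
test notes otherwise (the 0.5% bootstrap quantile at 1000 iterations
moves by ~0.03 r units between refinements, so convergence is asserted
on the mean over interval endpoints).

## Known limitations

- Surface inference uses the fixed 30 mm² extent rule, not
  non-stationary surface RFT.
- Gaussian (not t-field) densities after probability matching; exact at
  large df, slightly liberal at very small df.
- The classical extent distribution's tail conservativeness documented
  above; the permutation mode is the remedy when exactness matters.
- The bootstrap resamples controls unconditionally, ignoring the
  age/sex matching structure of the design.
- No frequency filtering or scrubbing in the functional stream.
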