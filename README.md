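# corticovar

Group analysis of cortical thickness and resting-state functional
connectivity for small matched cohorts — the kind of design used to
study adults treated for dense bilateral congenital cataracts, where a
brief period of early visual deprivation leaves long-lasting traces in
cortical structure. The package implements three linked analyses over a
shared statistical core, plus a synthetic-data generator so the whole
pipeline runs end-to-end with no imaging downloads.

## What it computes

**1. Vertex-wise thickness GLM** (`corticovar.surface`). Per-subject
thickness maps on a shared triangulated surface are smoothed with a
10 mm FWHM mesh-diffusion kernel, then each vertex is fit with

    thickness ~ intercept + group + sex + age

and the group (patient − control) contrast is tested with a t statistic
on n − k degrees of freedom. Sign-homogeneous connected components of
vertices with p < 0.001 (uncorrected) are kept when their summed vertex
area reaches 30 mm², and reported as a table of peak coordinate,
extent, peak p and group mean (sd) thickness.

**2. Covariance deviation** (`corticovar.covariance`). For every pair
of regions, the patient-group Pearson correlation r_pat is compared
against a bootstrap null built from controls: 1000 resamples of
n_patients controls drawn with replacement, each yielding a control
correlation, whose empirical 99% central interval serves as the
baseline. A pair is *deviant* iff

    (r_pat outside the control 99% CI)  AND  (p_pat < 0.05),

with p_pat from t = r√(n−2)/√(1−r²) on n−2 df, two-tailed. The same
machinery drives a seed-region profile against all other parcels and
correlations of regional thickness with clinical covariates
(deprivation duration, visual acuity) including leave-one-out
sensitivity.

**3. Seed-based functional connectivity** (`corticovar.fc` +
`corticovar.rft`). BOLD runs are residualized on an intercept, linear
trend, the Friston-24 motion expansion and WM/CSF/global-mean series
(first 10 volumes discarded), then smoothed at 6 mm. Subject maps are
Fisher-z transforms of the correlation between a 3 mm spherical seed
mean series and every voxel. One-sample t-tests per group define where
connectivity exists; inside that mask the pooled two-sample t-map is
thresholded at voxel p < 0.001 and clusters are corrected at p < 0.05
with Gaussian random-field theory (expected Euler characteristic ×
resels, classical extent distribution), validated against a group-label
permutation oracle.

## Worked example

```
$ python examples/correlation_significance.py
pair                                             r   n  p (two-tailed)
left calcarine x left lingual               -0.710  11          0.0144
left lingual x right calcarine              -0.670  11          0.0241
left lingual x right inferior frontal        0.710  11          0.0144
deprivation duration x left calcarine       -0.587  11          0.0576
  ... with the extreme subject removed      -0.449  10          0.1930
visual acuity x left calcarine               0.370  11          0.2627
```

At n = 11 a correlation needs |r| ≳ 0.60 to reach p < 0.05; the
deprivation-duration trend (p = 0.058) disappears when the single most
extreme subject is dropped — exactly the sensitivity the leave-one-out
report is for.

```
$ python examples/thickness_clusters.py
     area    peak_mni  size_mm2      p_value patient_mean_sd control_mean_sd
cluster_0 42, -19, 19     522.6 1.773403e-12     2.95 (0.09)     2.49 (0.12)

peak inside injected patch: True
```

A +0.45 mm patch injected into the patients of a synthetic 11 vs 24
cohort (3× the between-subject noise) is recovered as a single cluster
whose peak lies inside the injected patch; the group means at the peak
bracket the injected difference.

`examples/` contains one such script per capability (covariance
deviation, FC inference, RFT calibration); each prints the numbers it
computes and one line on how to read them.

A thin CLI mirrors the stages:
`corticovar simulate | thickness-glm | covdev | fc | rft-calibrate |
report`, each accepting `--config`, `--seed`, `--out`.

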