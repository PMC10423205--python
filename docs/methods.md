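# Methods

## The model

`hepatoscore` treats liver function as observable through hepatocyte uptake
of a liver-specific MRI contrast agent (gadoxetic acid). Functioning
hepatocytes take the agent up during the hepatobiliary phase (~20 min after
injection) and shorten the local longitudinal relaxation time T1. With a T1
map before contrast (`T1_pre`) and an aligned map in the hepatobiliary phase
(`T1_post`), the per-voxel T1 reduction rate

    rrT1 = (T1_pre − T1_post) / T1_pre

is a dimensionless uptake fraction: 0 for no uptake, approaching 1 for
complete T1 suppression. The MELIF score aggregates rrT1 over the segmented
liver and rescales by patient factors:

    MELIF = 0.694 · height^0.6 / (weight^0.3 · V^0.6) · 100 · A,

with height in m, weight in kg, liver volume V, and A the rrT1 aggregate
over liver voxels. Blood-based comparators are implemented exactly as
published: ALBI = 0.66·log10(bilirubin µmol/L) − 0.085·albumin(g/L) with
grade cut-offs at −2.6 and −1.39; MELD = 3.78·ln(bilirubin mg/dL) +
11.2·ln(INR) + 9.57·ln(creatinine mg/dL) + 6.43; Child–Pugh as the standard
five-component point table (5–15 points, classes A/B/C at 6/9).

### MELIF aggregation and units — an open convention

The printed MELIF equation sums rrT1 over voxels, which makes the score
scale with voxel count and hence with reconstruction resolution; the unit
convention (V in ml vs l) that would reproduce the published score scale
(≈38–60) from images is internal to the original prototype software and not
recoverable from the publication. At the cohort-mean patient (height 1.7 m,
weight 83 kg, V = 1547 ml) the patient factor is h^0.6/(w^0.3·V^0.6) ≈
0.004455, so MELIF ≈ 50 requires a voxel aggregate A ≈ 162 — consistent
with neither a plain sum over ~10^5 voxels (~10^4–10^5) nor a mean (~0.65).
The package therefore implements the literal equation with explicit
`aggregation` ("sum", the printed form, default; or "mean",
resolution-invariant) and `volume_unit` ("ml" default) switches, records
both next to every score, and verifies the imaging path through invariants
(linearity in A, monotonicity in the patient factors, mean-aggregation
invariance under grid refinement) rather than absolute values. Cohort-level
analyses and the reproduction of published AUCs use directly drawn MELIF
scores, which are convention-free.

## T1 fitting (DESPOT1)

T1 maps are fitted from variable-flip-angle SPGR volumes via the linearized
least-squares form: with y = S/sin(α′), x = S/tan(α′) and α′ = B1·α, the
steady-state equation becomes y = E1·x + M0(1−E1), E1 = exp(−TR/T1), so an
ordinary per-voxel line fit over the flip angles yields T1 = −TR/ln(slope).
For two-to-three-angle protocols this is the field's standard estimator;
nonlinear refinement is out of scope. B1 correction is a multiplicative
factor (scalar or map, default 1) on the nominal angles — how B1 was
measured is an acquisition detail outside the package. Voxels with any
non-positive signal or a slope outside (0, 1) are flagged invalid (NaN) and
propagate: a voxel invalid in either T1 map is invalid in the functional
map. Fit quality is the R² of the line fit.

Functional-map plausibility: rr outside the configured window (default
[0, 1]) marks the voxel invalid by default ("exclude"), keeping the MELIF
summand non-negative; a "clamp" policy clips instead and keeps the voxel.
The policy used travels with every score, since the original handling is
unstated. Negative rr (post > pre) is physically unexpected after
hepatocyte uptake, hence the default lower edge of 0. A post-contrast T1 of
exactly 0 is outside the T1 container's domain (T1 must be positive); the
full-reduction case rr → 1 is reached in the limit.

## Synthetic data

### Phantoms

The digital liver is a voxelized ellipsoid (analytic volume oracle;
anatomical realism is a non-goal) with native liver T1 810 ms and
background 1000 ms — typical 3-T literature values, both configurable. The
rr field is rr_mean plus a smooth Gaussian random field (white noise,
Gaussian-filtered at a correlation length in mm, then standardized to zero
mean and unit variance *over the mask* so the in-mask mean equals rr_mean
by construction), optionally scaled inside spherical lesions, and clamped
to [0, 0.95] so the post-contrast T1 stays strictly positive. Voxel
positions are index·spacing at voxel centers; the default spacing is the
protocol's interpolated 1.3×1.3×3.0 mm, with the acquired 3.6×2.5×4.8 mm
as a preset. Forward SPGR simulation adds Rician noise (magnitude of
complex Gaussian noise — the physical model for magnitude MRI), with
Gaussian noise as a config option since at the simulated SNRs the
difference is second-order.

What phantoms do not emulate: real liver shape and vasculature, motion and
breathing artifacts, k-space effects, contrast-agent pharmacokinetics, and
registration error (pre/post maps are generated aligned — the original
registration step is a trained network, out of scope). Tests passing on
phantoms therefore validate the estimator chain, not robustness to those
real-data effects.

### Cohorts

The cohort generator reproduces the study conditions: group sizes and
Normal score marginals as printed for the study population (MELD dichotomy
103/47, cirrhosis 64/86, ALBI grades 33/95/22, with the corresponding MELIF
and ALBI means ± SDs). Two modes are kept separate: **marginal** (per-group
independent Normal draws — sufficient for the AUC reproductions, which
depend only on marginals) and **copula** (Gaussian copula over scores with
a specified correlation matrix — for joint-structure studies; conflating
the two would force unverifiable joint assumptions).

Each patient gets a biologically consistent blood panel by algebraic
back-solve: albumin is drawn from the albumin band of the patient's ALBI
grade (40 ± 2.5, 33 ± 4.2, 23 ± 3.0 g/L, clipped at 10 g/L), bilirubin
solves the ALBI equation exactly, log10(bili) = (ALBI + 0.085·albumin)/0.66;
when MELD is among the drawn scores, creatinine is drawn from 0.6–1.4 mg/dL
and INR solved from the MELD equation (always feasible — an exponential of
a finite number), otherwise INR is drawn from 0.9–1.5 and MELD recomputed
from the panel. One bilirubin serves both scores via the fixed conversion
17.1 µmol/L per mg/dL. Recomputing ALBI from the panel reproduces the drawn
value to machine precision; MELD likewise. Groups that do not pin a score
fall back to the overall study population (MELIF 50 ± 11, ALBI −2.0 ± 0.6);
heights and weights are N(1.70, 0.08) m and N(83, 16) kg; ascites and
encephalopathy default to "none" (the panel then drives Child–Pugh).

All generators are deterministic for a fixed integer seed
(`numpy.random.default_rng`).

## Statistics

- **Pearson correlation**: sample r, two-tailed p from the t distribution
  (n−2 df), 95% CI by Fisher z-transform; interpretation bands weak ≤ 0.3 <
  moderate ≤ 0.5 < strong on |r|.
- **ROC/AUC**: empirical curve over all distinct thresholds; AUC is the
  Mann–Whitney probability with ties counted ½. The clinical direction is
  explicit per score (lower MELIF = impaired; higher ALBI/MELD = impaired)
  and recorded in outputs, keeping AUC ≥ 0.5 by construction on calibrated
  data. The published analysis names a spreadsheet "Wilson/Brown" CI whose
  algorithm is not printed; this package computes Hanley–McNeil CIs by
  default with DeLong as an option, and CIs are reported but never used as
  acceptance values. Interpretation bands are left-closed (0.8 → "good"),
  top band [0.9, 1] closed.
- **Youden cut-off**: maximizes J = sensitivity + specificity − 1 over
  midpoints between adjacent distinct observed scores; ties break toward
  higher sensitivity, then the lower threshold — the data never pin this
  down, so the rule is fixed and documented here.
- **Binormal AUC** Φ(|Δμ|/√(σ₁²+σ₂²)) serves as the closed-form oracle
  linking printed group marginals to expected AUCs.
- **ANOVA**: one-way F with Tukey-HSD-adjusted all-pairs comparisons
  (statsmodels), used across the ALBI-grade strata.
- **Normality**: D'Agostino–Pearson K² (scipy), n ≥ 20 required.
- Significance default is 0.05, two-tailed.

## Pipeline conventions

- MELD is summarized as median (IQR) with inclusive (Tukey-hinge) quartiles
  — the presentation rule is not stated in the source, so it is declared in
  the run manifest. Grouping uses nearest-integer MELD (half away from
  zero), matching the integer scores reported clinically.
- The Child–Pugh score enters the correlation matrix as its 5–15 points
  (the numeric coding actually correlated in the original analysis is
  unstated; points are the natural scale and are flagged in the report).
- Child–Pugh INR bands (1.7/2.3) are used rather than prothrombin-time
  bands, since INR is the recorded field; noted as a deviation risk.
- n = 1 cohorts and single-class comparisons skip the affected analyses
  with a logged warning rather than failing the run.
- Figures are emitted as plot-ready CSV (ROC points, group summaries);
  rendering is cosmetic and out of scope.
- Every run writes a manifest (config hash, seed, package version); reruns
  with the same seed are byte-identical.

## Problem sizes

The reproduction of the published AUCs averages 1000 replicate cohorts per
comparison at the printed group sizes (150, 150, and 128/117 patients);
property suites use 10⁴–10⁵ samples where convergence rates are asserted
(empirical-vs-binormal AUC at n = 10⁵ within 3 standard errors; Fisher-z CI
coverage over 1000 replicates of n = 150; normality-test type-I error over
500 replicates of n = 10⁴). Phantom tests use ~10⁴–10⁶-voxel grids, chosen
so the analytic oracles (ellipsoid volume within 2%, noiseless fit within
1e−6 relative) are sharp.

## Known limitations

- Absolute image-derived MELIF values are convention-dependent (see above);
  only cohort-level, directly drawn scores are compared against published
  numbers.
- Marginal-mode cohorts have no within-group correlation between scores, so
  cross-score correlations on such cohorts are attenuated relative to the
  published patient data; the copula mode exists for that purpose.
- The spatial distribution of rrT1 in real livers is not described in the
  source; the smooth-Gaussian-field model is an assumption.
- The published ALBI AUC for the MELD dichotomy (0.77) exceeds the binormal
  expectation from its own printed group marginals (≈0.74) and is therefore
  not recoverable from marginal simulation; it is not targeted.
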