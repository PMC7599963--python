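# Methods

This note documents the models, numerical choices and limitations of
`dwimicro`. It describes what the code computes and why the defaults
are what they are; every empirical statement here is recomputed by the
test suite or by `scripts/acceptance.py`.

## Signal model and tensor fit

The forward model is the Gaussian (tensor) signal
S(**g**, b) = S₀·exp(−b·**g**ᵀD**g**) with b in s/mm² and D in mm²/s.
Fitting is linear least squares on the log-attenuation with the design
[1, −b gₓ², −b g_y², −b g_z², −2b gₓg_y, −2b gₓg_z, −2b g_yg_z],
followed by one reweighting pass with weights equal to the squared
predicted signal ratio (WLS; plain OLS available behind a flag). The
method is deliberately the common default; an exact nonlinear
least-squares fit is kept in the test suite as an oracle and agrees
with WLS within 2% median on MD at SNR 20.

Numerical guards:

- signal ratios are clipped to [10⁻⁶, 1] before the log — the Rician
  noise floor can push S above S₀, and a log of a non-positive ratio is
  meaningless;
- eigenvalues are floored at ε_λ = 10⁻⁶ mm²/s after decomposition,
  with the number of clamped values logged. The floor exists because
  the closed-form EAP scalars invert eigenvalues, and a single
  near-zero λ₃ otherwise produces unbounded values;
- all-zero voxels are dropped from the mask rather than fitted.

## Apparent EAP scalars

The package computes RTOP/RTAP/RTPP two ways.

**Closed forms** from the eigenvalues (see README) — exact for a
Gaussian propagator, but unstable on real data: the test suite
reproduces the failure mode (at SNR 20 on an anisotropic phantom,
unfloored tensor-route RTOP exceeds 10³× its noise-free value in well
over 0.1% of voxels while the apparent route stays bounded).

**Apparent route**: the directional ADC D(**u**) = −ln(E(**u**))/b is
fit with even real spherical harmonics (order 6 by default: 28
coefficients against 61 directions; order and direction count are
validated against each other), and the radial signal profile is assumed
mono-exponential. This is the minimal model consistent with treating
the shell signal as radially independent; it is implemented from that
assumption, not as a bit-exact port of any external tool, and is
validated by its exact agreement with the closed forms on noise-free
Gaussian signals (median error ≪ 1% at order 6).

Numerical choices:

- **τ = 0.025 s** by default. The effective diffusion time is an
  acquisition property that the data files do not carry; every
  cross-route comparison passes the same τ through both sides, so its
  value cancels everywhere the package makes a claim.
- **Spherical averaging** uses a fixed product quadrature:
  Gauss–Legendre in cos θ (24 nodes) × uniform azimuth (48 nodes),
  1152 points, deterministic and exact for band-limited integrands well
  beyond order 8. The RTAP equator integral uses 48 uniform points on
  the great circle perpendicular to **e₁** (trapezoid rule on a
  periodic function, spectrally accurate).
- The principal direction comes from the tensor fit's first
  eigenvector — both routes are computed from the same data, so this
  is free.
- D(u) values below ε_λ at quadrature nodes are floored and counted.

A subtlety worth recording: for a *single-tensor* signal,
D(**u**) = **u**ᵀD**u** is exactly an order-2 spherical harmonic, so
the SH truncation error is zero at every even order ≥ 2 and
"convergence with order" is unobservable there. The order-convergence
test therefore uses a two-tensor crossing signal, whose ADC profile is
genuinely non-band-limited; truncation error falls strictly from order
2 → 4 → 6 against a dense-quadrature analytic reference.

## Skeleton, projection, inference

**Skeleton.** The mean FA over subjects is thresholded at 0.2; a voxel
survives if it is a local maximum of the lightly smoothed mean FA
(Gaussian, σ = 1 voxel) along the cross-tract plane. The cross-tract
plane is spanned by the two strongest-negative-curvature eigenvectors
of the local Hessian; because the Hessian misidentifies that plane on
tract flanks (inflection regions), the FA gradient direction is tested
as well. The ridge test samples at ±0.75 and ±1.5 voxels along four
azimuths of the plane plus the gradient direction (trilinear
interpolation). This is a self-contained "TBSS-style" rule: on tube and
arc phantoms it recovers the analytic centreline within one voxel;
voxel-level parity with the original TBSS implementation is a non-goal.

**Projection.** For each skeleton voxel, each subject's FA is searched
along both cross-tract directions (half-voxel steps, ±4 mm by default)
and the maximum-FA source voxel is recorded; ties resolve to the
nearest offset. Non-FA measures are projected *from the same source
voxel*, so all seven measures of a subject are sampled consistently.

**Inference.** Two-sample t statistics (pooled variance) per skeleton
voxel, with nuisance covariates handled by Freedman–Lane residual
permutation: data are residualized against the nuisance design, the
residual rows are permuted, and the statistic is recomputed with the
nuisance terms refitted. Enhancement is TFCE,
TFCE(v) = Σ_h e(h,v)^E·h^H·dh with the canonical H = 2, E = 0.5 and
dh = max/100, clusters by 26-connectivity on the skeleton (6-connectivity
fragments thin skeletons). FWE-corrected p-values come from the
permutation distribution of the maximum TFCE statistic with the +1
convention, p(v) = (1 + #{max ≥ TFCE(v)})/(1 + n_perm), so p is never 0
and never below 1/(1+n_perm). Both one-sided contrasts are computed and
each contrast is corrected within itself (no cross-contrast
correction). When the design has no covariates and the number of
distinct relabelings is below the requested permutation count, all
relabelings are enumerated exactly (logged).

The permutation loop evaluates TFCE with an incremental union-find over
descending thresholds on a precomputed skeleton adjacency graph
(numba-compiled); it is verified to match the volumetric per-threshold
relabelling implementation to machine precision, and both match a
10×-finer threshold-sum oracle within 2%.

Two properties of the *discrete* TFCE sum deserve a note. First,
monotonicity (raising one voxel's statistic never lowers any TFCE
value) is exact for the continuous integral but can be violated at the
threshold-discretization scale (~max/n_steps) because dh is tied to the
map maximum; the violations shrink as steps are refined. Second,
corrected p-values are exactly invariant under positive rescaling of
the statistic map (TFCE scales uniformly) and under affine rescaling of
the data (the t statistic is invariant), but not under arbitrary
monotone transforms of the statistic, which re-weight cluster height
against extent.

**ROI report.** Per atlas region: significant volume (corrected
p < α over region ∩ skeleton, times the voxel volume in mm³), minimum
corrected p, and the world-coordinate peak (smallest p; ties to largest
TFCE, then lowest voxel index). Regions whose significant volume does
not exceed 30 mm³ are dropped — the rule is kept in mm³ with the voxel
volume taken from the grid, since skeleton voxel volume depends on the
grid the analysis runs on.

## Cohort statistics

Conventions are pinned by what makes printed summary data reproducible:
pooled-variance two-tailed t (df = n₁+n₂−2, so mean ± SD with n
suffices — recomputing the duration comparison from the printed
summaries gives t(108) = −2.7), Pearson χ² without continuity
correction (reproduces χ²(2) = 2.48 on the printed sex × group counts),
two-sided Fisher exact by the sum-of-smaller-probabilities rule
(p = 0.0076 on the printed aura counts), Mann–Whitney U reported as the
smaller U with a tie-corrected normal approximation for n > 20,
tie-corrected Kruskal–Wallis, and a Kolmogorov–Smirnov (sample
mean/SD) + Levene (center = mean) gate that falls back to rank tests if
either rejects at 0.05 or any sample has n < 5. ROI correlations use
Spearman's ρ with average ranks and Benjamini–Hochberg adjustment
within one (measure, covariate, group) family of regions.

## Synthetic cohort generator

The generator emulates the *structure* of a three-group clinical
cohort, not its anatomy:

- **Phantom**: straight-tube and circular-arc tracts of anisotropic
  tensors (default λ = (1.7, 0.4, 0.4)×10⁻³ mm²/s, tube radius ≥ 2
  voxels so a skeleton exists) in an isotropic background
  (0.7×10⁻³ mm²/s), on a 2 mm grid, with an atlas-style label map. The
  default two-tube phantom keeps one tract as the effect target and one
  as a negative control.
- **Acquisition**: 61 Fibonacci-sphere directions at b = 1000 s/mm² plus
  one baseline — the clinical-routine scheme the package targets.
- **Group effects**: multiplicative factors on λ₁ and/or λ₂,₃ inside
  chosen labels for one patient group. The motivating study reports
  only the direction of group differences, so magnitudes are experiment
  parameters; the default scenario (−10% on λ₁ for the chronic group)
  is chosen to be reliably detectable at n ≈ 25/group, and produces the
  paired signature lower AD / higher RTPP (RTPP ∝ λ₁^(−1/2), so −10%
  on λ₁ is ≈ +5% on RTPP).
- **Inter-subject variability**: one global eigenvalue scale per
  subject, Normal(1, 0.02²) truncated to [0.9, 1.1] — enough
  between-subject variance to make group inference non-trivial without
  burying seeded effects.
- **Noise**: Rician, |S + N(0,σ²) + iN(0,σ²)|, with SNR defined as
  S₀/σ on the baseline volume (the definition matters; it is the b=0
  SNR, not a DW-volume SNR). Default σ = S₀/20.
- **Demographics**: independent truncated-normal/Bernoulli marginals
  per group with defaults matching the study's summary table (ages
  ~36–38 y, durations 14.1 ± 11.1 vs 19.6 ± 10.4 y, headache
  frequencies 3.6 ± 1.9 vs 23.3 ± 6.3 d/month, aura 17% vs 2%, overuse
  0% vs 75%, onset of the chronic phase 24.5 ± 32.9 months). Fields are
  sampled independently (only marginals are published) except that
  migraine days are capped at headache days. Truncation at physical
  bounds (frequencies in [0, 31] d/month, durations ≥ 0) shifts the
  realized mean of near-bound fields below/above the nominal value —
  e.g. a 23.3 ± 6.3 frequency truncated at 31 loses ≈ 1.3 d/month of
  mean; the configured values are the *untruncated* parameters, and
  tests of mean recovery use fields where the shift is negligible.

Everything is a pure function of a single integer seed.

What passing tests on this generator do **not** show: performance under
real anatomy (crossing fibres, partial volume), registration error
(subjects are generated co-registered on one grid — template
registration is explicitly out of scope), preprocessing artifacts
(denoising, eddy/motion, bias fields are assumed already handled), or
the clinical validity of any effect size. The generator demonstrates
that the *machinery* is correct and calibrated, not that migraine has
any particular effect.

## Problem sizes in the standard runs

The test suite and the acceptance script run the statistical components
at the sizes stated in their docstrings: Gaussian equivalence on 1000
random tensors; TFCE oracle agreement on 50 random 16³ maps; null
calibration over 200 simulated cohorts of 15 vs 15 subjects at 500
permutations on a 512-voxel domain (a valid FWE procedure must land in
the binomial band [0.02, 0.09] around α = 0.05); and effect recovery
over 20 simulated studies of 25 vs 25 patients at SNR 20 with 1000
permutations on a 28×28×10 phantom. These sizes were chosen as the
smallest at which each claim is sharp — calibration bands and recovery
rates are binomial statements, and the counts above give them meaning.

## Known limitations

- The apparent scalars inherit the mono-exponential radial assumption;
  at b = 1000 s/mm² they are "apparent" versions of the true EAP
  integrals and their contrast weakens at low b.
- The skeleton rule is designed for ridge-like FA structure; it reduces
  plateaus via smoothing and is not guaranteed voxel-identical to other
  TBSS implementations on real data.
- Rician noise is the only noise model; no spatial noise correlation.
- The tensor fit offers no robust/outlier-rejection variant.
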