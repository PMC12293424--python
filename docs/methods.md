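# Methods

## The model

Each voxel carries a symmetric diffusion tensor D (mm²/s). The acquisition
follows the monoexponential forward model

    S(b, g) = S0 · exp(−b · gᵀ D g),

with magnitude (Rician) noise: the observed signal is
`sqrt((S + n1)² + n2²)` with n1, n2 independent zero-mean Gaussians of
standard deviation `S0 / SNR`. Gaussian and noise-free modes exist for
oracle tests.

The quantity of interest is the ALPS ratio
`mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)`, computed from ROI
means of tensor diagonal elements in a projection-fiber region (principal
axis z) and an association-fiber region (principal axis y). The ratio is
dimensionless, scale-invariant (global tensor scaling cancels), and equals 1
for any isotropic field.

## The phantom

A 48 × 48 × 12 voxel grid at 2 mm isotropic resolution carries two
axis-aligned fiber blocks and an isotropic background. The grid is
deliberately small: the analysis is driven entirely by the ROI geometry, so
whole-brain realism buys nothing but run time. The template affine is
diagonal (voxel size 2 mm, origin (−80, −70, 20) mm), chosen so the standard
template-space ROI coordinates — projection x = −26 mm, association
x = −37 mm, y ∈ {−17, −27, −29} mm, axial slices z ∈ {29, 30, 31} mm, nine
pairs in all — fall inside the blocks with room for the ±1 mm refinement
search. This affine stands in for nonlinear template registration, which is
out of scope.

Baseline diffusivities (defaults; all mm²/s):

| parameter         | value     | meaning                                      |
|-------------------|-----------|----------------------------------------------|
| `lambda_parallel` | 1.7e-3    | diffusivity along the fiber axis             |
| `lambda_perp`     | 0.699e-3  | diffusivity perpendicular to fiber and PVS   |
| `perivascular_dxx`| 0.301e-3  | extra x-diffusivity from perivascular water  |
| `d_background`    | 0.8e-3    | isotropic background                         |
| `S0`              | 1000      | unweighted signal (arbitrary units)          |
| `SNR`             | 30        | S0 over the Gaussian noise sigma at b = 0    |

Only the ratio (0.699e-3 + 0.301e-3)/0.699e-3 = 1.431 is calibrated — it
matches a typical awake ALPS index of 1.43; the absolute levels are ordinary
white-matter values and nothing downstream depends on them (scale
invariance). SNR 30 is a typical 3 T diffusion-weighted b=0 value; no
protocol-specific figure was available.

## Sleep-state modulation

Each sleep time point t multiplies, within the fiber blocks only, the x
diagonal element by (1 + a_t) and the perpendicular element of interest
(Dyy in projection, Dzz in association) by (1 + b_t). The default
trajectory covers six sleep scans at 14.46, 19.46, 25.46, 31.45, 37.45 and
43.45 minutes after the instruction to sleep (the awake scan sits ~9 min
before it):

    a_t (%):  +6.33  +3.51  +10.57  +5.94  +6.39  +4.51
    b_t (%): −11.05 −14.32  −8.04  −3.35  +1.74  −9.53

implying index elevations of 19.54 / 20.81 / 20.24 / 9.61 / 4.57 / 15.52 %
through the exact identity (1 + Δindex) = (1 + Δnum)/(1 + Δden). These are
the published component trajectory of a zolpidem-assisted sleep cohort and
are the generator's fixed study conditions, not tunables. The printed time
labels are treated as protocol-fixed rather than cohort averages.

## Cohorts and between-subject variability

`simulate_cohort` gives each of n subjects one awake scan plus one scan per
trajectory entry. Subject identity enters as four independent log-normal
multiplicative factors (mean 1, coefficient of variation 0.03 by default) on
the four ALPS components of the baseline; the trajectory multiplies on top,
so each subject's fractional index change is exactly the configured one.
The source study reports only standard errors, so the variance model is a
package choice; 3% reproduces awake-index standard errors of the observed
order (~0.05 at n = 9). Seeding uses `numpy.random.SeedSequence.spawn` per
subject: a cohort is bit-identical given its seed.

What the generator does **not** emulate: scanner artifacts (eddy currents,
susceptibility distortion, motion), partial-volume mixtures, spatially
correlated noise, within-subject drift between scans, or genuinely curved
tracts. Passing tests therefore demonstrate the correctness and statistical
behaviour of the analysis chain under the stated model — not robustness of
the index against real-world confounds, which real pipelines remove with
dedicated preprocessing before this analysis begins.

Annotation grids are emitted alongside the scans: 17 epochs per subject
(one awake, sixteen sleep-period scans), values 0/1/N. A packaged
12-subject grid with unreadable and relapse epochs exercises the inclusion
filter (exactly subjects 1–9 pass the default window).

## Tensor fitting

Only the b = 800 s/mm² shell plus the b = 0 volumes enter the fit; low
b-values weight the slow/fast ADC regime that tracks perivascular water,
and under the noiseless monoexponential model the choice of shell is
provably immaterial (a test asserts this), so the restriction is pure
configuration. `ln S = ln S0 − b gᵀ D g` is solved per voxel by weighted
least squares: an OLS pass, then one reweighting with weights equal to the
squared predicted signal (the standard correction for the log transform's
variance distortion). S0 is a joint regression coefficient — one code path,
unbiased under the model — rather than a b=0 average. An OLS mode is kept
for oracle comparisons. Voxels with any non-positive signal are flagged and
excluded from ROI means, never fatal; a rank-deficient design (fewer than 6
independent directions) is an error. b-values below 50 s/mm² count as
unweighted; shell selection uses a ±50 s/mm² tolerance by default.

Eigen-decomposition sorts eigenvalues descending, clamps negative ones to
zero (flagging the voxel), and fixes the primary eigenvector's sign so its
largest-magnitude component is non-negative. The "dominant axis" of V1 is
the argmax of absolute components, ties resolving x before y before z.

## ROI handling

ROIs are axis-aligned cubes in template mm space; voxel membership is the
half-open box [c − e/2, c + e/2) over voxel centers, which makes
edge = voxel size unambiguous (a cube centered on a voxel center contains
exactly that voxel). Nominal edge is 3 mm, the refined extraction edge
2 mm. Refinement replaces the manual visual QC of practice with a
deterministic rule: for each ROI, all nine in-plane shifts of {−1, 0, +1} mm
are scored by the fraction of ROI voxels whose V1 dominant axis matches the
expected fiber axis (z for projection, y for association); the best shift
wins, ties break toward the smaller shift norm and then lexicographically
(x before y); a best score below 0.5 excludes the pair as misaligned.
Reproducibility was preferred over fidelity to manual QC, and the alignment
score also stands in for the vein-intersection check that would require
susceptibility-weighted venograms. Refinement runs once per subject on the
awake eigenvector map and the placement is then frozen across sleep scans,
so temporal index changes reflect diffusivity, not ROI drift. Right-
hemisphere mirrors of the standard pairs exist behind a flag but are
excluded by default (in EEG-MRI practice the right hemisphere is lost to
gel-induced susceptibility artifacts).

## Sleep annotation and inclusion

An epoch's consensus label is the state a strict rater majority (> n/2)
agrees on among {awake, sleep}; anything else — including unreadable-
dominated epochs — becomes N. A subject is included iff the analysis window
(epoch 1 plus the following six, by default) shows awake at its first epoch
and sleep at every other; N anywhere in the window excludes the subject,
the natural reading of "complete disagreement is excluded" at the subject
level. Fleiss' kappa summarises rater agreement; unreadable labels are
either dropped epoch-wise (default) or kept as a category (config flag).
All-unanimous ratings make chance agreement 1 and the statistic 0/0; kappa
is then 1 by convention, with a warning.

## Statistics

With n = 9 subjects and k = 7 time points, everything is rank-based.

* **Friedman test** per ROI pair, tie-corrected (Conover form):
  `T = (k−1) Σ_j (R_j − n(k+1)/2)² / (A − C)` with A the sum of squared
  within-subject midranks and C = nk(k+1)²/4. p comes from χ²(k−1) by
  default; seeded within-subject permutation and exhaustive enumeration
  (tiny designs) are options. Missing cells are an error — incomplete
  series are excluded by the annotation filter, never imputed.
* **Post hoc**: paired Wilcoxon signed-rank of each sleep time point against
  awake. For n ≤ 15 informative pairs the two-sided p is exact from all 2ⁿ
  sign assignments of the midranked |differences|; above that, a normal
  approximation with tie and continuity corrections. At least 5 non-zero
  differences are required. The choice of paired signed-rank as the post hoc
  test is an inference from the reported effect-size convention; it is
  validated against the published FDR arithmetic, not against printed r.
* **Multiplicity**: Benjamini–Hochberg step-up over the six sleep-vs-awake
  comparisons within one ROI pair (that family reproduces the published
  adjusted values exactly from the published raw ones, which is also why BH
  specifically was adopted where only "FDR correction" was stated). Note
  the step-up map is not idempotent — re-adjusting an adjusted vector can
  only raise values.
* **Effect size**: Wilcoxon's r = |z|/√n, signed by the median difference;
  on the exact path z is the normal equivalent of the exact p.
* **ROI selection**: keep pairs with Friedman p < 0.05 whose peak-time index
  elevation carries a strictly positive numerator (x-diffusivity) change —
  an index rise produced purely by a perpendicular decrease is not accepted
  as perivascular. The screen uses per-pair raw Friedman p (matching how
  the published pairs at p = 0.027–0.034 survived); with nine pairs the
  familywise false-selection rate under a global null is therefore ~1 −
  0.95⁹, controlled per pair, not per family.

The component decomposition reports, per sleep time point, the fractional
changes of the numerator, the denominator, and the index of the
cohort-mean quads; the identity (1 + Δindex) = (1 + Δnum)/(1 + Δden) holds
exactly by construction, and the first-order reading Δindex ≈ Δnum − Δden
is accurate to O(Δnum·Δden).

## Numerical choices and degenerate inputs

Tolerances: gradient unit norm 1e-6 on construction, 1e-2 on file read
(with renormalization and a logged warning below that); affines must be
invertible; the ALPS denominator must be positive. Direction sets come from
antipodal electrostatic repulsion (projected gradient descent, 600
iterations, decaying step), deterministic given the seed, and demonstrably
better spread than the best of 10⁴ random designs. Tabular output prints at
6 significant digits so reruns are byte-comparable.

## Problem sizes used in the checks

The automated checks run the full-size phantom (48 × 48 × 12) for the
nine-subject stochastic recovery of the first sleep time point's index
elevation, and a 16 × 16 × 8 phantom with the same geometry for everything
exercising many cohorts (statistics-level studies additionally use a direct
quad-level generator that skips image synthesis). Note the nine standard
pairs at 2 mm resolution touch only six distinct projection voxels — the
z = 30 and z = 31 slices share voxels — so pooling across pairs averages
less noise than the pair count suggests; the stochastic recovery pools
subjects and pairs at the cohort-mean-index level and lands within ~1
percentage point (SD across seeds) of the configured truth.

## Known limitations

* Single-voxel refined ROIs make per-subject indices noisy at SNR 30; the
  pipeline's power statements hold at the cohort level.
* The alignment-score refinement is a proxy for expert QC and vein
  verification; it cannot reproduce decisions driven by anatomy the phantom
  lacks.
* Exact Wilcoxon enumeration is O(2ⁿ) and switches to the normal
  approximation above n = 15.
* The χ² Friedman p is an approximation at n = 9; the permutation option is
  exact in distribution but Monte-Carlo.
* Rician noise induces a small signal-floor bias at strong diffusion
  weighting; at the default SNR and b = 800 its effect on the index is well
  below the sampling noise.
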