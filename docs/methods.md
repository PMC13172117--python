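# Methods

## The model and its assumptions

The pipeline's predictive core is deliberately minimal: a logistic
regression on a single radiomic feature, the 90th percentile of ADC values
(`adc_p90`) inside a region,

    P(cribriform) = 1 / (1 + exp(−(β0 + β1 · adc_p90))),   β1 < 0.

The negative slope encodes the biological assumption that cribriform
Gleason-pattern-4 tissue is densely cellular and therefore restricts water
diffusion more than GP3 or non-cribriform GP4 tissue.  The package never
hard-codes "the" coefficients: models are either fitted on region-level
samples (`fit_crib_model`) or loaded from JSON.  `default_model()`
(β0 = 9, β1 = −0.01 per 1e-6 mm²/s, unstandardised) is a synthetic
demonstration setting whose 0.5-probability crossing sits at 900, between
the cribriform and non-cribriform ADC levels of the phantom defaults.

Percentiles use the linear-interpolation convention (sorted values,
fractional position `0.9·(n−1)`), the dominant default across numerical
ecosystems; feature standardisation is supported but off by default.

### Whole-gland inference

Square windows of 5, 7, 9, 11 and 13 voxels slide with stride 1 over every
slice (windows are 2-D: at 2.7–4 mm slice thickness an isotropic 3-D window
of these sizes would be physically implausible).  A window contributes if it
lies fully inside the slice and at least `min_mask_fraction` (default 0.5)
of its voxels are inside the prostate mask; its feature is the p90 over the
in-mask voxels only.  Overlap is resolved by maximum projection, in two
selectable flavours because the construction is genuinely ambiguous:

* `cover` (default): a voxel keeps the maximum over all valid windows of
  any size containing it;
* `center`: the maximum over the at-most-5 valid windows centred on it.

Centred windows are a subset of covering windows, so `cover` dominates
`center` voxel-wise; both are implemented and tested and neither is claimed
to be canonical.  The patient score is the maximum defined voxel
probability, and classification uses a strict inequality
(score > threshold).

The implementation vectorises the per-window percentile as a
sort-and-gather (NaNs outside the mask sort to the end; gather at the
fractional position given by the in-mask count) and the cover aggregation
as an anchored 2-D maximum filter; both paths are verified exactly against
brute-force window enumeration in the tests.

### Mask erosion

"Remove a single boundary voxel with a cylindrical structuring element in
the xy plane" is implemented as per-slice 2-D erosion with the radius-1
4-connected cross (a cylinder of height one voxel and radius one voxel —
the minimal element that removes exactly one in-plane boundary voxel); the
8-connected square is available as an option.  Erosion applies only to
slices whose two axial neighbours contain prostate; restricted slices are
kept unchanged by default (`restricted="keep"`) with a `"drop"` option,
since the sources describing the procedure say erosion "was restricted",
not that edge slices were discarded.  The operation is anti-extensive but
intentionally not idempotent.

### Segmented IVIM fitting

The two-step estimator: ordinary least squares of log-signal against b over
`b_threshold ≤ b ≤ b_max` (defaults 200 and 1,000 s/mm²) gives the tissue
diffusion coefficient D and an extrapolated intercept S0′; the perfusion
fraction is `f = 1 − S0′/S(0)`, clipped to [0, 1].  D* is not estimated —
the downstream model consumes only ADC, so the minimal estimator suffices.
`b_threshold = 200` matches the smallest "high" b-value of typical prostate
acquisitions (0/200/800 and 0/50/300/800 combinations); very high b-values
(1,400–2,000) are accepted but excluded by `b_max` to avoid non-Gaussian
diffusion bias.  Voxels with non-positive signals at b = 0 or at any fitted
b, fewer than two usable high-b points, or non-finite/negative D are
flagged invalid, never silently zeroed.

### Decision framework

Cambridge Prognostic Groups follow the standard five-tier definitions from
PSA, biopsy grade group and clinical T-stage (the pipeline's scenarios
exercise groups 1–3 only).  Three allocation strategies are simulated —
reference (CPG-1 → AS, everyone else → AT, model ignored), CPG-1+2 and
CPG-1+2+3(GG2) (CPG-1 → AS automatically; the model routes the rest:
AT iff score > threshold).  Outcomes against prostatectomy ground truth
fall into six exhaustive, mutually exclusive categories; missed cribriform
in AS is split at a focus-diameter cutoff of 1.5 mm, the approximate MRI
detectability limit.  Two accounting conventions worth making explicit:

* AT for a cribriform-negative patient with prostatectomy GG ≥ 3 counts as
  *appropriate* (correct AT): such patients are ineligible for AS
  regardless of cribriform status.  This is the only reading under which
  the benchmark cohort's reference-scenario percentages are internally
  consistent.
* Overtreatment ≡ falsely-in-AT; undertreatment ≡ the sum of the three
  falsely-in-AS categories.  Narrative descriptions of such analyses
  sometimes swap the colour labels between the two; the mapping here
  follows the category definitions, which is the arithmetic-consistent
  choice.

Raising the threshold can only move model-routed patients from AT to AS
(strict inequality), so the AT count is non-increasing, overtreatment
non-increasing and undertreatment non-decreasing — enforced as a tested
property.

### Evaluation

ROC-AUC is the Mann–Whitney statistic (ties count one half); PR-AUC uses
the average-precision right-step convention, never interpolated precision.
Confidence intervals are percentile bootstrap (default n = 1,000) with
patient-level resampling; single-class resamples are skipped and counted
rather than retried (retry loops bias the interval by conditioning), and
more than 50% degenerate resamples is an error.  BCa correction and DeLong
variances are out of scope.

## Synthetic data: what it emulates, and what it does not

Phantoms are discretised ellipsoidal prostates (default semi-axes
16 × 13 × 11 mm) on anisotropic grids (default 72 × 72 × 12 voxels at
0.5 × 0.5 × 3 mm) containing non-overlapping spherical lesions of three
classes with Gaussian voxel ADC:

| tissue              | ADC mean ± SD (1e-6 mm²/s) |
|---------------------|-----------------------------|
| background prostate | 1400 ± 200 |
| GP3                 | 1000 ± 150 |
| GP4, non-cribriform |  900 ± 150 |
| GP4, cribriform     |  700 ± 120 |

These levels are invented configuration defaults chosen to preserve the
ordering the model assumes (cribriform lowest); no public dataset exists to
calibrate them, and every value is overridable.  Setting all lesion means
equal to the background gives the zero-contrast null used in the
discrimination tests.

Lesions are spheres rather than arbitrarily oriented ellipsoids, with
centres snapped to voxel centres (slice centres in z).  This is a
deliberate design choice: it makes the lesion's largest in-plane extent
well-defined and equal to the requested diameter within one in-plane voxel
(a tilted ellipsoid's in-plane chord is systematically smaller, and with
3 mm slices the equator can fall between slices).  The recorded
`max_crib_diameter_mm` is always *measured* from the label grid (maximum
pairwise in-plane centre distance plus one voxel), not copied from the
request.

Cohort generation samples clinical variables consistent with a requested
CPG cell (verified against `assign_cpg` after the fact) and supports exact
largest-remainder quotas or multinomial draws over CPG × cribriform cells.
Noise models: none (default — class SDs already provide voxel-level
variability), additive Gaussian, and Rician (magnitude of a complex
Gaussian perturbation).

What phantoms do **not** emulate: zonal anatomy, lesion shape irregularity,
partial-volume and registration error between histology and MRI, field-
strength and protocol heterogeneity, and spatial noise correlation.
Passing discrimination tests on phantoms therefore demonstrates that the
inference machinery is correct and sensitive to the encoded contrast — not
that any particular AUROC is attainable on clinical data.

### The benchmark cohort

`build_fixture_cohort()` returns a fixed 127-record cohort
(CPG-1 n=26, CPG-2 n=72, CPG-3(GG2) n=29; cribriform-positive 3/33/16;
prostatectomy GG ≥ 3 0/12/10) whose joint cribriform × grade-group cells
are the unique solution of the published marginal counts of a
radical-prostatectomy series combined with its reference-scenario outcome
percentages.  Clinical values are representative per cell (e.g. PSA 6.7 /
7.1 / 15.0); cribriform focus diameters default to 2.0 mm since the source
tables do not stratify size — the choice is inert because all
undertreatment subcategories are summed in every reported quantity.

## Numerical choices and degenerate inputs

* Percentile ties/interpolation: linear, everywhere (map engine and
  `extract_p90` agree exactly).
* Logistic fitting: BFGS on the penalised negative log-likelihood with an
  analytic gradient, polished by Newton steps to gradient norm ≤ 1e-8;
  complete separation with zero regularisation raises with an instruction
  to add an L2 penalty.
* Empty masks raise; masks thinner than the smallest window at the mask
  fraction yield an empty-validity map with a warning; probability maps
  hold NaN outside their validity mask so misuse surfaces immediately.
* All stochastic components take explicit seeds (`numpy.random.default_rng`)
  and are bit-reproducible.

## Problem sizes

Unit tests run phantoms at 48 × 48 × 10 voxels (0.7 mm in-plane); the
end-to-end discrimination tests use the default 72 × 72 × 12 grid with a
120-patient cohort (60 cribriform-positive, lesion diameters 3–8 mm) for
the contrast arm and 10 seeds × 12 patients pooled for the zero-contrast
null.  The full test suite completes in under a minute on one CPU.

## Known limitations

* No public coefficients exist for a deployed cribriform model; all model
  parameters here are fitted to synthetic data or user-supplied.
* The segmented IVIM variant matches the standard two-step estimator; exact
  equivalence with any specific prior implementation cannot be asserted.
* Resampling supports axis-aligned grids with a shared origin (nearest
  neighbour); deformable registration is out of scope.
* Decision-curve analysis and longitudinal AS outcome modelling are not
  implemented.
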