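# Methods

This note documents the models, conventions and numerical choices behind
`ctlungvol`, and what the synthetic-data checks do and do not establish
about real CT data.

## Lung definition and volumetry

A lung voxel is one whose CT number lies in the window **[−1000, 0] HU,
inclusive on both ends**, and which lies inside the patient's body.  The
window alone is not a lung definition — the air surrounding the patient has
the same density — so the pipeline first segments the body as the largest
connected component of voxels above a **body threshold (default −500 HU)**,
with interior holes filled **slice-wise in the axial plane**.  Slice-wise
(rather than 3-D) filling is deliberate: a trachea that opens to the
exterior air above the patient is an interior hole in every axial slice but
not in 3-D, and it must stay inside the body mask so the explicit
airway-exclusion step can account for it.

Within the body, in-window voxels are grouped into connected components and
components smaller than a **speck floor (default 1 mL)** are discarded as
noise.  Soft-tissue structures — chest wall, mediastinum, vessels of
soft-tissue density — lie above 0 HU and are excluded by the window itself;
no vessel-specific step exists.

Conducting airways are removed in one of two ways: subtracting an airway
label map, or growing the 6-connected component of a tracheal seed within
the lung mask.  When the grown component exceeds an **airway budget
(default 5% of lung volume)** the growth has leaked into the lung proper —
there is no separable airway — and the mask is returned unchanged.  The
default seed is taken in the most superior air region of the lung mask,
which in an intact scan is the tracheal air column.

Volumes are voxel counts × voxel volume, reported in mL per lobe from a
lobe label map, with aggregates (right/left lung, upper/lower lobes, total)
formed as exact sums, so additivity holds to rounding.  Lung voxels the
label map misses are assigned to the nearest labelled lobe by Euclidean
distance — a fallback for small boundary mismatches, not a segmentation
method.  Lobe segmentation itself is an *input*: clinical lobe maps come
from dedicated software, and this package does not attempt to reproduce
one; only the phantom generator stamps geometric lobes.

Thick-slice reconstruction is emulated by overlap-weighted **mean pooling
along the through-plane axis**.  This reproduces the averaging of a
thick-slice reconstruction without modelling scanner kernels.  Note its
known bias: a 5-mm slab that is only a few percent air still averages below
0 HU, so thick slices dilate the lung by up to half a slab at each
through-plane boundary.  The effect is proportional to surface/volume; for
the default human-scale phantom it is +3–4% per lobe, and it is why the
phantom lobes are deliberately tall (through-plane half-axes ≥ 80 mm).

Axis convention: arrays are (z, y, x) with z = 0 the most superior slice;
spacing is (dz, dy, dx) in mm; volumes in mL; HU bounds inclusive (the
symmetric reading of an ambiguous convention; both bounds configurable).

## Predicted FVC

Spirometry reference equations are linear in height and age within sex:
`FVC_pred (L) = α·height_cm + β·age_years + γ`.  Which published
coefficients apply depends on the population, so equation sets are YAML
configuration; the bundled `placeholder-linear` set has coefficients of the
typical published magnitude (α ≈ 0.05–0.06 L/cm, β ≈ −0.02 L/yr) but is
explicitly not a published standard.  Out-of-range demographics warn but
compute; a non-positive prediction is an error, since standardised volume
would be meaningless.

## Standardisation and scoring

`stdLV(region) = 100 · volume(region in L) / FVC_pred(L)`.  The statistic
is invariant under joint rescaling of volumes and predicted FVC, and lobar
percentages sum to the total's percentage.

GAP points follow the printed brackets literally, with closed-bracket
boundary handling: age ≤ 60 → 0, 61–65 → 1, > 65 → 2; FVC% > 75 → 0,
50–75 → 1 (exactly 75 scores 1), < 50 → 2; DLCO% > 55 → 0, 36–55 → 1
(exactly 55 scores 1), ≤ 35 → 2, cannot-perform → 3; female 0 / male 1.
Stage I/II/III at totals 0–3/4–5/6–8.

The modified GAP replaces FVC% by stdLV% mapped through an ordinary
least-squares line fitted on paired (stdLV%, FVC%) observations and then
scored with the original FVC brackets.  The published description of this
mapping ("correlation analyses") leaves the construction open; OLS inverse
prediction is the explicit choice here, and a direct-threshold alternative
(score stdLV% with the FVC brackets unmapped) is available behind a flag.
With the identity map the modified score reduces exactly to the original —
a property the tests check on an exhaustive category grid.

Median cutoffs use the sample median (mean of middle two for even n).  Tie
conventions: in the three-group LV+CRP classifier, a value exactly at a
cutoff is "not above and not below" and lands in the intermediate group;
for two-group median splits, values ≥ the cutoff form the high group.  The
shipped cutoff constants 108% (diagnosis) and 74% (exacerbation) are
cohort-derived defaults, not universal constants; the median of the cohort
at hand is the primary mode.

## Survival statistics

Kaplan–Meier estimation, the log-rank test (hypergeometric variance,
K − 1 df) and Cox proportional-hazards fitting (Efron tie handling, Wald
95% CIs) are delegated to lifelines; Harrell's C is computed in-package
because the concordant/discordant/tied pair counts are part of the result.
Conventions: median survival is the smallest observed time with
S(t) ≤ 0.5 and is reported as undefined — never an infinite number — when
the curve stays above 0.5; p-values are two-tailed with α = 0.05; no
multiple-testing correction is applied.  Tests verify each statistic
against independent oracles: a hand-computed product-limit table,
a direct observed-minus-expected summation, an O(n²) pair enumeration, and
a 1-D numerical maximisation of the no-ties partial likelihood.

## Synthetic data

**Phantoms.**  Ellipsoid lobes were chosen over anatomical meshes because
closed-form volumes make the accuracy oracle exact — testability over
realism.  The default phantom is human-scale: a 240-mm-diameter soft-tissue
(+40 HU) cylinder over 300 × 300 × 420 mm, five pairwise-disjoint
air-density (−850 HU) lobes totalling ≈ 2.7 L, and an 8-mm-radius tracheal
tube (−1000 HU) open to the exterior air.  A miniature `compact()` variant
(~79 mL) keeps unit tests fast.  Optional Gaussian HU noise requires a
seed.  What phantoms do **not** emulate: fibrotic texture, vessels and
airways beyond one tube, lobar fissure geometry, scanner kernels and beam
physics, or motion.  Passing phantom tests therefore establishes the
correctness of the threshold/masking/counting machinery and the
thick-slice averaging behaviour — not segmentation performance on real,
textured lungs.

**Cohorts.**  Patients are drawn to resemble an IPF population: 85% male,
age ~N(70, 7), stdLV ~N(108, 25)% at diagnosis and ~N(74, 20)% at
exacerbation (centred on the shipped cutoff defaults so default runs
exercise them), CRP log-normal (median 0.17 mg/dL at diagnosis, 5 mg/dL at
exacerbation), FVC% a noisy linear function of stdLV% (noise σ = 22% gives
a correlation near the mid-0.6s).  Survival times follow a Weibull
proportional-hazards model, `h(t|x) = h0(t)·exp(β_lv·(stdLV − μ_lv) +
β_crp·(CRP − m_crp))`, with shape 1.2 and baseline median survival 5.5
years (diagnosis) or 6 months (exacerbation); the default β_lv = ln 0.976
per percentage point is the scale of the hazard ratio the method is meant
to detect, and β_crp = 0.08 (diagnosis) / 0.05 (exacerbation) per mg/dL.
Censoring is independent exponential, with its scale solved by bisection so
the expected censored fraction matches the requested rate (default 0.3).
These are simulation inputs; recovering them (CI coverage ≈ 95%, mean HR
≈ 0.976 at n = 300 over 100 replicates) validates the estimation stack,
not any clinical claim.

## Problem sizes

The default phantom is analysed at 1-mm isotropic voxels (420 × 300 × 300
grid) and after 5-mm reconstruction; the thin/thick concordance suite uses
20 phantoms of varying size at 0.625-mm through-plane and 2-mm in-plane
spacing; hazard-ratio recovery uses 100 cohorts of n = 300; the risk-group
ordering check uses one exacerbation cohort of n = 400.

## Known limitations

- Lobe label maps are trusted as given; no fissure detection exists.
- The inclusive-bound HU convention and all mask parameters are defaults a
  user can change; results quoted here are for the defaults.
- Thick-slice mean pooling carries the partial-volume inflation described
  above; small structures (a real right middle lobe, ~10 mL phantom lobes)
  exceed the quoted tolerances at 5-mm slices.
- The cohort simulator draws covariates independently (no age–FVC or
  sex–height–stdLV correlation structure beyond sex-specific height means).
- Reference-equation coefficients are placeholders until a published set
  appropriate to the cohort is configured.
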