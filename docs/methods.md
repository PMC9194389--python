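# Methods

This note records the models, conventions and parameter choices behind
`spectpa`, in the order the pipeline applies them, together with what the
synthetic data can and cannot establish.

## 1. First-harmonic phase extraction

Each polar-map sample carries a count curve `c_k`, `k = 0…N−1`, over one
R-R cycle (default `N = 8`, matching 8-bin gating; any `N ≥ 4` works).
Counts rise during systole through the partial-volume effect of wall
thickening, so the curve is modelled as

```
c_k = a0 + a1·cos(2πk/N − θ) + ε_k .
```

With uniform sampling of a full cycle the least-squares solution is the
discrete Fourier coefficient at frequency 1: `a0` is the mean and
`(a1, θ)` come from the two quadrature sums. This is exact, not
iterative; a dense grid search over θ is used in the test suite as an
independent oracle and agrees to the grid resolution.

**Phase convention.** The contraction-onset phase is the cycle position
where the fitted harmonic crosses its mean while rising: `φ = θ + 270°
(mod 360)`. Any fixed offset convention would do — PSD and PBW are
invariant under global rotation of all phases (tested) — but a definite
convention makes forward/inverse consistency with the simulator exact.

**Validity mask.** A sample is masked out when `a1 < 0.02·a0` (or
`a0 = 0`). The 2% amplitude floor exists to reject genuinely flat,
non-contracting curves whose phase is meaningless; it is not a noise
filter. If more than half the samples are invalid a warning is logged
and the map is still returned.

## 2. Dyssynchrony indices

Phases of valid samples are histogrammed into 1° circular bins (bin
width configurable, must divide 360; the bin total always equals the
valid-sample count).

* **PSD** — the histogram is conceptually rotated so its circular mean
  sits at 180°, then the linear weighted SD of bin centres is taken;
  implemented equivalently as the root weighted mean square of circular
  deviations from the circular mean. Shift-invariant by construction,
  bounded by 360/√12 ≈ 103.92° (uniform histogram). The reference
  software's exact formula is unpublished; this convention is declared,
  not inferred.
* **PBW** — the width of the smallest contiguous circular window of bins
  containing ≥ 95% of the samples (coverage configurable). Computed by a
  two-pointer scan over all window starts; an exhaustive O(n²) scan is
  the test oracle. The coverage fraction is likewise a declared
  convention: only the name "phase histogram bandwidth" is published.

Whether scarred samples should be excluded from the histogram before
PSD/PBW is unknown for the reference implementation; this package
includes them (they carry a phase whenever their amplitude clears the
floor), and exclusion is available by masking upstream.

## 3. Perfusion, scar, segments

Uptake is the frame-summed count map normalised to its maximum (the
standard surrogate for a separate resting scan, keeping the pipeline
self-contained). Scar is uptake strictly below 50% of the maximum; scar
burden is the scarred fraction of all LV samples, in percent.

The 13-segment model is one apical bullseye plus apical/mid/basal ring
bands split into four 90° sectors (anterior, septal, inferior, lateral;
angle index 0 = anterior). The innermost quarter of the rings (at least
one) is the apex; remaining rings split into three near-equal bands.
Adjacency: circumferential neighbours within a band, radial neighbours
across bands in the same sector, apex adjacent to all four apical
segments. Per segment: circular mean phase of valid samples, scar
percentage, sample count.

## 4. Pattern classification

The global rule is exact from the source: **mild** iff PSD ≤ 40.3° and
PBW ≤ 111.9°, else severe. The severe subtypes were visual reads by two
investigators; this package operationalises them with three explicit,
configurable parameters:

| parameter | default | meaning |
|---|---|---|
| `block_delta_deg` | 90° | minimum circular phase jump between adjacent segments to call a line of block |
| `delay_offset_deg` | 45° | a segment later than the circular mean of segment phases by at least this is "delayed" |
| `monotone_tolerance_deg` | 20° | slack for the septum→lateral monotonicity check |

Precedence among severe subtypes: **heterogeneous** (≥ 2 connected
components of delayed segments) → **U-shaped** (≥ 1 block line and
exactly one delayed cluster) → **homogeneous** (no block line and
septal ≤ anterior/inferior ≤ lateral within tolerance in every band).
Multiple delays dominating a single block line mirrors the published
description of the heterogeneous pattern. A severe study matching no
rule cleanly is labelled by the nearest rule and flagged (`fallback`),
with a logged warning. All decisions are rotation-invariant, and the
block-line *location* is reported but never used for labelling.

The defaults are design choices, not published constants; on the
synthetic archetypes they recover the generating label perfectly without
noise and ≥ 99% with default Poisson noise (measured, seeds 1–3).

## 5. Outcome statistics

* Response: ΔLVEF ≥ 5 points at 6 months. Super-response: follow-up
  LVEF ≥ 50% **or** ΔLVEF > 15 points (strict inequality).
* Odds ratios are cross-products `ad/bc`; CIs are Woolf (log) intervals
  `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` with `z = Φ⁻¹(0.975) ≈ 1.959964`.
  This pairing reproduces every published CI bound to printed precision,
  which is why it was chosen over exact intervals. Zero cells leave the
  OR/CI undefined and flagged — no continuity correction is applied,
  matching the published P = 0.72 for mild vs U-shaped (the
  Yates-corrected statistic gives ≈ 0.97 and cannot be the published
  convention).
* Proportions are compared by Pearson chi-square (df = 1, uncorrected)
  or Fisher's exact test when any expected cell is < 5; pairwise
  comparisons are Bonferroni-adjusted (`p_adj = min(1, m·p)`).
* Logistic regression is Newton maximum likelihood with Wald SEs
  (statsmodels). Continuous predictors can be standardised by their
  sample SD (ddof = 1) for per-SD odds ratios. Perfect or
  quasi-separation (|coef| > 15) raises a diagnostic error. The stepwise
  wrapper screens univariately (P < 0.05 to enter), adds variables in
  ascending univariate-P order (the entry order is unstated in the
  source and is a design choice here), and after each entry drops the
  worst variable with multivariable P > 0.05.
* Survival uses the Kaplan–Meier product-limit estimator and the
  log-rank test (lifelines); survival step tables are the canonical
  output, plots are not required.

Two-sided Fisher sums hypergeometric probabilities ≤ the observed
table's — the most common convention; the source does not specify one.

## 6. Synthetic cohort generator

The generator defines the study conditions; every default is taken from
the published group-level numbers where one exists.

**Phase-field archetypes.** Each field is `base + s·g` with `g` a fixed
zero-mean unit pattern per archetype and `s` a dispersion scale:

* *mild* — wrapped-normal spread around the base phase;
* *U-shaped* — one late 90°-sector territory (+1 in `g`) behind a line
  of block, apex at an intermediate level (+0.35) so propagation wraps
  around it;
* *heterogeneous* — two disjoint late patches (segments {2,6} at +0.85
  and {8,12} at +0.6) over a jittered baseline;
* *homogeneous* — a monotone circular ramp from the septal centre to the
  lateral wall, small jitter.

`s` is calibrated by bisection until the noiseless field's PSD matches
the target (default: the published group medians 23.06/52.98/64.64/
46.25°; achieved within 2°, the attained PBW is logged). PSD grows
linearly in `s` only until phases wrap the cycle, so the bracket is
grown gradually (×1.2) to capture the *first* crossing.

**Label consistency.** A generated exemplar must *be* its label: after
calibration the noiseless field is classified with margined thresholds
(mild: both global thresholds ×0.85; U: block threshold ×1.25;
heterogeneous: delay offset ×1.2; homogeneous: block threshold ×0.8) and
the target is shrunk or grown (bounded attempts) until it passes.
Severe targets are also clipped to each shape's wrap ceiling (U 88°,
heterogeneous 78° PSD) — beyond those the spatial structure scrambles.
Consequently the generated homogeneous/heterogeneous PSD distributions
are mildly compressed relative to their drawn targets; the drawn values
are kept in the patient record.

**Forward count model.** Expected frame counts are
`a0·u·(1 + r·cos(2πk/N − θ))` with Poisson sampling; `u = 1` (viable) or
0.4 (scar), `r = 0.3` (viable) or 0.075 (scar: 4× reduced thickening).
`a0 = 1000` counts per polar-map sample — samples aggregate many
reconstructed voxels, and this level gives ≈ 3° per-sample phase noise
for viable myocardium (≈ 19° in scar), consistent with the few-degree
repeatability of clinical phase analysis. With noise disabled the
expected counts are returned and the analysis inverts the model to
1e-6°. The relative amplitude is set for phase signal-to-noise, *not*
to reproduce the published wall-thickening percentages (a 0.3 amplitude
implies ≈ 86% peak-to-trough thickening, higher than the published
medians); wall thickening plays no role in classification here.

**Patient records.** Group-conditional draws: skewed baseline variables
(PSD, PBW, scar burden, LVEF, LVEDD, QRSd) are log-normal matched to the
published median (IQR) by quantile matching, truncated to plausible
ranges and to the group's side of the mild/severe rule; age is normal
(mean ± SD); sex, V5/V6-S and NYHA follow the published group
frequencies. Super-response and event flags are Bernoulli at the
published group rates (0.656/0.706/0.158/0.333 and
0.156/0.059/0.526/0.50); follow-up times are exponential with mean
37.48 months. Follow-up LVEF is *constructed* to satisfy the drawn
super-response label exactly rather than modelled biophysically — the
analysis only consumes labels and deltas. The published table mixes
mean ± SD and median (IQR) presentations; the per-variable choice above
is this package's resolution of that ambiguity. Everything is
deterministic in `(config, seed)` via one `numpy` Generator.

**What the synthetic data does not show.** No tomographic physics
(attenuation, scatter, reconstruction), no anatomic LV shape, no ECG
waveforms, no correlation between imaging noise and outcome. Passing
tests demonstrate the *algorithms* are correct and internally
consistent under the published summary statistics — not that the
classifier generalises to clinical images.

## 7. Problem sizes and numerical choices

Default geometry 10 rings × 36 angles × 8 frames (360 samples). The
test suite and acceptance script use 100-patient archetype suites
(25/pattern) and n = 2000 logistic-recovery cohorts with 100 seeds;
the full demo runs 74 patients end to end in well under a minute.
Degenerate inputs are errors, not silent results: empty histograms,
all-zero perfusion maps, incomplete segment profiles, non-finite or
negative counts, constant outcomes in regression. Ties in the PBW
window scan resolve to the earliest start, which cannot affect the
width. Circular means of perfectly balanced angle sets (zero resultant)
are rejected rather than fabricated.

## 8. Known limitations

* The severe-subtype rules are this package's formalisation of a visual
  read; the three thresholds are defensible but not validated against
  reader adjudication (none is published).
* PSD/PBW conventions (circular centring; 95% coverage) are declared,
  and may differ from the unpublished reference software in ways that
  shift absolute values by a few degrees.
* The published multivariable adjusted ORs cannot be reproduced without
  patient-level covariates; the stepwise machinery is instead validated
  by parameter recovery on synthetic cohorts.
* The 13-segment layout (1 + 4 + 4 + 4) follows the published polar-map
  figures; the exact ring partition of the reference software is
  unknown.
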