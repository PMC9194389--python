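# spectpa

Gated-SPECT myocardial phase analysis, left-ventricular contraction-pattern
classification, and the outcome statistics that relate the pattern to
response to cardiac resynchronization therapy (CRT).

## The problem

In heart failure with left bundle branch block, CRT (biventricular pacing)
restores mechanical synchrony — but a third of patients do not respond, and
a lucky subset *super*-respond (follow-up LVEF ≥ 50% or an absolute LVEF
increase > 15 points at 6 months). Gated SPECT myocardial perfusion imaging
offers a cheap, reproducible window into mechanical dyssynchrony: each
myocardial sample of the polar map carries a count curve over the cardiac
cycle, and because counts rise as the wall thickens (partial-volume effect),
the **first Fourier harmonic** of that curve times the onset of regional
contraction:

```
c_k ≈ A0 + A1·cos(2πk/N − θ),   k = 0 … N−1 (8-bin gating)
```

The per-sample phase φ (the rising mean-crossing of the fitted harmonic,
in degrees of the cardiac cycle) yields two global dyssynchrony indices:

* **PSD** — phase standard deviation: circular SD of the phase histogram;
* **PBW** — phase histogram bandwidth: width of the smallest circular
  window holding 95% of samples.

A ventricle with **PSD ≤ 40.3° and PBW ≤ 111.9°** has a *mild
dyssynchronous* contraction pattern; anything above either threshold is
*severe* and is subtyped from the 13-segment phase polar map into
**U-shaped** (a ≥ 90° line of block with one late territory wrapping via
the apex), **heterogeneous** (≥ 2 disjoint delayed territories) or
**homogeneous** (a monotone septum-to-lateral ramp). The mild and U-shaped
patterns predict CRT super-response; the heterogeneous pattern predicts
failure.

The package implements the whole chain — harmonic fitting, PSD/PBW, scar
quantification (< 50% of maximal uptake), the 13-segment model, the
rule-based pattern classifier, and the outcome statistics (cross-product
odds ratios with Woolf CIs, chi-square/Fisher with Bonferroni correction,
stepwise logistic regression, Kaplan–Meier/log-rank) — plus a synthetic
cohort generator so every stage is testable end to end without any
patient data.

## Worked example

Reproducing the published contingency analysis from its printed inputs
(group sizes 32/17/19/6; super-response rates 65.6/70.6/15.8/33.3%):

```bash
python examples/03_outcome_statistics.py
```

```
super-responders by group: {'mild': '21/32', 'U-shaped': '12/17', 'heterogeneous': '3/19', 'homogeneous': '2/6'}
overall super-response: 38/74 = 51.4 %

contrast                             OR             95% CI        p  test
mild vs U-shaped                  0.795 [  0.223,   2.841]    0.724  chi2
mild vs heterogeneous            10.182 [  2.430,  42.663]    0.001  chi2
mild vs homogeneous               3.818 [  0.602,  24.222]    0.188  fisher
U-shaped vs heterogeneous        12.800 [  2.545,  64.372]    0.001  chi2
U-shaped vs homogeneous           4.800 [  0.655,  35.198]    0.162  fisher
homogeneous vs heterogeneous      2.667 [  0.327,  21.733]    0.562  fisher
```

The odds of super-response in the mild group are ten times those in the
heterogeneous group (OR 10.182, CI excluding 1); mild and U-shaped are
statistically indistinguishable (P = 0.72).

The imaging side, on synthetic ground truth:

```bash
python examples/02_pattern_classification.py
```

```
truth          label             PSD    PBW blocks clusters  range
MILD           MILD             23.6   92.0      0        0   26.4
U_SHAPED       U_SHAPED         52.9  168.0      3        1  134.6
HETEROGENEOUS  HETEROGENEOUS    64.7  197.0      3        2  153.7
HOMOGENEOUS    HOMOGENEOUS      46.5  152.0      0        1  120.5
```

Each row is one Poisson-noised gated study; the classifier recovers the
generating pattern with the evidence (block lines, delayed clusters,
segmental phase range) it used. `examples/01_phase_analysis.py` shows the
per-sample harmonic fit, and `examples/04_full_demo.py` runs the full
74-patient simulate → analyze → classify → stats pipeline (98.6% label
agreement at the default seed).

A thin CLI wraps the same stages:

```bash
spectpa simulate --seed 1 --out-dir sim/
spectpa analyze  --input-dir sim/gated --out-dir results/
spectpa stats    --cohort sim/cohort.csv --out-dir results/
spectpa demo     --seed 1 --out-dir demo/
```

All tabular I/O is delimited text with headers; gated polar maps are
`ring,angle,frame,counts` CSV, one file per patient.

## Layout

```
src/spectpa/
  phase.py      first-harmonic fits, phase maps, PSD/PBW, wall thickening
  perfusion.py  uptake maps, scar burden, 13-segment model
  patterns.py   mild/severe rule and the four-way pattern classifier
  stats.py      response labels, OR/CI, chi2/Fisher, logistic, KM/log-rank
  simulate.py   archetype phase fields, Poisson forward model, cohorts
  pipeline.py   analyze / stats / demo stages over directories of files
  io.py, cli.py, circular.py
docs/methods.md   model details, conventions, parameter rationale
examples/         one narrative script per capability
```
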