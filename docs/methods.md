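# Methods

This note records the statistical model behind `idhscore`, the conventions
and tunable parameters, and the design choices made where the published
description left the method under-determined.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The diagnostic problem and the composite score

The task is binary: given one patient's preoperative features — age, five
MRI findings and three PET tumour/normal-cortex uptake (T/N) ratios — call a
non-contrast-enhanced astrocytic tumour IDH-mutant astrocytoma or
IDH-wildtype glioblastoma.  The composite diagnosis dichotomizes each
parameter at a fixed cutoff, awards one point per wildtype-indicating
finding, and bands the total:

| card  | rules (1 point each) | mut band | indeterminate | wt band |
|-------|----------------------|----------|---------------|---------|
| mri5  | thalamus invasion; contralateral invasion; ventricle-adjacent; FA ≥ 0.18; MD ≤ 1.28 | 0–2 | — | 3–5 |
| pet3  | MET T/N ≥ 1.29; CHO T/N ≥ 2.02; FDG T/N ≥ 0.82 | 0–1 | — | 2–3 |
| full9 | mri5 ∪ pet3 ∪ {age ≥ 48} | 0–4 | {5} | 6–9 |

MD is carried throughout on the 10⁻³ mm²/s scale (a printed
"1.47 × 10⁻³ mm²/s" is stored as 1.47).  Accuracy is reported two ways:
over *decided* cases (indeterminate totals excluded from the denominator,
the source convention) and overall (indeterminate counted as error);
decided-cases accuracy is primary.

**Threshold inclusivity.**  The source names cutoffs but not their boundary
behaviour.  One worked case — a 48-year-old scoring an age point at the age
cutoff of 48 — fixes the convention: values exactly at a cutoff count as
wildtype-positive.  This inclusive-on-the-wildtype-side rule is applied
uniformly to all six continuous thresholds, since no published boundary
counterexample exists.  The worked cases name only some location findings;
unmentioned flags are taken as absent.

## Synthetic cohort model

No patient-level data are available, so the generator turns the published
per-group summaries into a sampling law:

* **Continuous markers** (age, FA, MD, MET/CHO/FDG T/N): per-group
  independent normals at the printed mean ± SD, truncated to physical
  ranges — age ≥ 18 (adult-type cohort), FA ∈ [0, 1], MD > 0, T/N ≥ 0 —
  by resampling violations.  Normality is the minimal assumption a
  mean ± SD pair supports; the true shapes (T/N ratios are plausibly
  log-normal) are unknowable from the published text.
* **Binary flags** (sex plus seven location flags): independent per-group
  Bernoulli draws at the printed proportions.  Logically linked flags
  (single- vs multiple-lobe) may therefore co-occur; no scored rule uses
  them, and reconciling them is a non-goal.
* **Group sizes** default to the study's 55 mutant / 27 wildtype.

**Truncation shifts.**  Resampling truncation changes the realized moments.
The shift is negligible (≪ 1 Monte-Carlo SE at the test suite's replication
levels) for every bound except two: the age bound (18 y is ~1.8 SD below the
mutant mean, raising the realized mean from 38.0 to ≈ 38.87 and shrinking
the SD from 11.0 to ≈ 10.14) and, mildly, the CHO zero bound (~2.3 SD,
shrinking the SDs by ≈ 0.02).  `moment_check` therefore reports deviations
from both the nominal spec values and the truncation-adjusted targets
(closed-form truncated-normal moments); calibration tests assert against
the adjusted targets, which are the generator's true law.

**Seeding.**  One master seed; every (marker, group) pair draws from its own
substream keyed by a CRC32 of the pair name, so editing one marker's
parameters never perturbs another marker's draws, and cohorts are
bit-reproducible.  `auc_recovery_simulation` exploits this contract to
materialise only the marker under study; its values are identical to those
a full cohort generation would produce at the same seeds.

**Correlation.**  Features are independent within group by default — the
only structure the published marginals can constrain.  A Gaussian-copula
correlation matrix over any subset of the continuous markers can be
supplied for sensitivity analyses (rows violating bounds are redrawn
jointly); the per-marker substream contract does not extend to markers
inside the copula block.

**What passing tests do and do not show.**  Marginal calibration, AUC
recovery and screening power on these cohorts validate the *machinery*
(tests, ROC, scoring) under the published marginal conditions.  They say
nothing about cohort-level composite accuracy on real patients: the
published accuracies (84.1% MRI, 75.6% PET, 87.3% composite over decided
cases) depend on the unpublished joint distribution of the 82 real
patients, so the pipeline computes the analogous tables on synthetic data
but does not assert against those figures.

## Screening tests

Both screens are implemented from first principles (scipy supplies only
special functions and `rankdata`):

* **Pearson χ², 2×2, df = 1, no continuity correction**:
  X² = n(ad − bc)² / (r₁r₂c₁c₂); p from the χ²₁ survival function.
  Uncorrected Pearson reproduces the printed thalamus p = 0.006
  (X² = 7.448 on counts 1/55 vs 5/27, p = 0.0064).  One printed p
  (contralateral invasion, 0.018) is not reproduced by uncorrected Pearson
  (0.0208); the statistical engine behind the original value is
  unspecified, and this implementation reports its own Pearson value rather
  than forcing agreement.  Tables with a zero margin are undefined; the
  bare test raises, while cohort screening reports such constant flags as
  p = 1 (no evidence) so a rare flag absent from a small cohort does not
  abort the screen.
* **Mann–Whitney U**: pair-counting U with ties ½ (computed via average
  ranks).  p-values are exact — full enumeration of the rank-sum null
  distribution by dynamic programming — when n₁n₂ ≤ 400 and the pooled
  sample is tie-free; otherwise the normal approximation with tie-corrected
  variance and a 0.5 continuity correction is used.  The n₁n₂ ≤ 400 bound
  keeps exact enumeration trivially fast at desk scale; with ties the exact
  permutation distribution is data-dependent and the asymptotic path is
  standard practice.
* **Significance** at unadjusted two-sided p < 0.05, matching the source.
  No multiple-testing correction is applied across the fourteen screens —
  a faithful mirror of the source design and a known limitation.

The identity U/(n₁n₂) = empirical AUC (matching orientation) is exact with
ties and is enforced by a cross-module test.

## ROC analysis

* **Positive class** is glioblastoma (IDH-wildtype) throughout: sensitivity
  = wildtype capture, specificity = mutant rejection.  Each marker has an
  orientation, `wt_high` (age, FA, T/N ratios) or `wt_low` (MD).
* **Cutoff selection**: the source names no criterion; Youden's
  J = sens + spec − 1 is adopted as the standard rule behind a single
  reported cutoff/sensitivity/specificity triple.  Candidate thresholds are
  the observed marker values with the wildtype side inclusive, so returned
  cutoffs are attainable data values.  Ties in J are broken
  deterministically: highest specificity first, then the threshold closest
  to the mutant group.
* **Binormal oracle**: Φ(|μ_wt − μ_mut| / √(σ²_mut + σ²_wt)) gives the
  closed-form AUC of the two-normal model and anchors the simulation
  checks, e.g. Φ(0.8) ≈ 0.788 for FA — compare the printed 0.78.
* **CHO discrepancy**: the binormal AUC implied by CHO's printed summaries
  (1.44 ± 0.63 vs 1.98 ± 0.86) is 0.694, while the printed AUC is 0.66.
  The two cannot both hold under any near-normal model; CHO is therefore
  reported but excluded from AUC-recovery assertions.  Printed
  sensitivity/specificity pairs reflect the real cohort's empirical ROC and
  are not recoverable from summary statistics at all; only AUCs are
  validated by simulation.

## Scorecard derivation

`derive_scorecard` replays the construction on any labelled cohort: screen,
keep markers significant at α (default 0.05), convert binary flags to flag
rules and continuous markers to Youden-threshold rules oriented toward the
group with the larger location.  Decision bands generalize the published
ones: totals 0..k split at the midpoint, with the middle total k/2 declared
indeterminate when k is even and a clean split at (k ± 1)/2 when k is odd.
(The published 9-rule card's hand-chosen bands — indeterminate exactly at 5
— are preserved verbatim in `default_scorecard` and are not claimed to
follow from this generalization; its own 5- and 3-rule cards use no
indeterminate total at all, so no single rule reproduces all three.)

Note that any marker whose published proportions differ between groups —
including sex (58.2% vs 37.0% male) — gains power without bound as the
cohort grows, so large synthetic cohorts recover a superset of the nine
published rules.  The published screen's non-significant findings are
statements at n = 55/27, not properties of the underlying proportions.

## Problem sizes and numerical conventions

Replication levels used by the test suite and acceptance machinery — 500
replicate cohorts for AUC recovery, 200 for generator calibration, 2000
null replicates for type-I calibration, n = 2000/group for power checks —
were chosen so Monte-Carlo error sits well inside each assertion's band
while the whole suite stays desk-scale.  Other conventions: cohort CSV is
UTF-8, '.' decimal, booleans 0/1, fixed header; floats survive CSV
round-trips via round-trip parsing; all randomness flows from explicit
integer seeds through numpy `SeedSequence` substreams; degenerate inputs
(zero-SD markers, constant flags, all-indeterminate cohorts, empty files)
are defined behaviours — point masses, p = 1 screens, NaN-with-warning
accuracies, empty cohorts with a warning — rather than errors, except where
an invariant is genuinely violated (zero-margin 2×2 tables, single-class
cohorts, out-of-range feature values, which raise with context).

## Known limitations

* Marginal fidelity only; no joint structure, no scanner effects, no
  anatomical consistency among location flags, no survival outcomes.
* Normal marginals may misrepresent skewed T/N ratios.
* The screening mirrors the source's unadjusted multiplicity.
* Image-derived inputs (ROI drawing, DTI fitting, SUV computation) are
  upstream of this package; features enter as precomputed numbers.
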