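# Methods

## Problem and model

Dietary management is central to chronic kidney disease (CKD) care, and at
steady state a 24-h urine collection measures intake directly: daily sodium
excretion equals sodium intake, urinary urea tracks protein catabolism.  The
obstacle is collection quality — missed voids make a collection incomplete,
including two nights makes it excessive — and an unvalidated ionogram
silently biases every intake estimate by the fraction of urine actually
collected.

`ckdurine` implements completeness validation through creatinine, which is
excreted at a stable rate over the day.  Writing *f* for the (unobserved)
completeness factor of a collection, the measured 24-h creatinine clearance
is

    CrCl_24h = U_cr · V / (P_cr · 1440 min)  =  f · CrCl_true ,

so comparing it with a completeness-independent reference estimates *f*.
Three references are supported:

1. **Fractional creatinine clearance** — the mean of U·V/P over six 30-min
   timed spot-urine periods collected under supervision the same day.  This
   is the primary criterion.
2. **MDRD eGFR** — the 4-variable IDMS-traceable equation
   175·(Scr/88.4)^−1.154·age^−0.203·(0.742 female)·(1.212 black), by default
   de-indexed from mL/min/1.73 m² to absolute mL/min via Du Bois body
   surface area (0.007184·W^0.425·(100·H)^0.725), because the 24-h clearance
   is an unindexed quantity and comparing indexed to unindexed values would
   bias the delta by the BSA/1.73 ratio.  The 186-coefficient original
   equation and the no-de-indexing convention are both selectable.
3. **Expected creatinine excretion** — measured urinary creatinine per kg
   body weight against an expected-median normogram keyed on sex, age band
   and GFR band.  The packaged normogram is a synthetic placeholder with
   plausible magnitudes (its filename says so); published reference values
   should replace it for real cohorts.

The signed relative delta is always reference-relative,
δ = (measured − reference)/reference.  δ < −t classifies the collection
*incomplete*, δ > +t *excess*, |δ| ≤ t *valid* (boundary inclusive, reading
"maximum acceptable delta" as ≤).  Default t = 0.30 with a stringent 0.15
variant.  Reference-relative rather than measured-relative division is the
convention under which δ = f − 1 exactly on noise-free data, making the
completeness factor a closed-form oracle.  A visit missing the inputs a
criterion needs is *unassessable* — reported as a distinct outcome and
excluded from prevalence denominators, never coerced to invalid.

## Diet estimation

From a validated ionogram (per day):

* NaCl intake [g] = natriuresis [mmol] / 17;
* protein intake [g/kg] = urea [mmol] × 0.2 / weight [kg], reported both per
  actual kg and per ideal kg (22 kg/m² × height²) so follow-up comparisons
  survive weight change.  The simplified urea-only coefficient is the
  default; the full Maroni form 6.25·(urea-N + 0.031·weight) is available
  via `use_maroni` for comparison;
* osmole excretion [mosm] = osmolarity [mosm/L] × volume [L]; diuresis
  itself proxies water intake;
* calcium, phosphate and ammonium pass through as excretions.

Flags: anemia Hb < 13/12 g/dL (male/female); secondary hyperparathyroidism
PTH > 65 pg/mL (assay upper normal — the flag cut-off is a package choice,
as assays differ); BP above target if systolic > 130 or diastolic > 80 mmHg
(strict inequalities, matching a "BP > 130/80" prevalence); protein
compliance intake < 1 g/kg/day; salt compliance ≤ 6 g/day.  The salt target
is a guideline default and prominently configurable, since recommended
targets vary (5–6 g/day across guidelines).  Missing inputs yield missing
flags, never `False`.

## Statistics

Group comparison (valid-at-all-visits vs valid-at-none patients at
baseline): Mann–Whitney for continuous variables, Pearson χ² without
continuity correction for binary ones.  Mann–Whitney takes the exact
enumeration path when both groups have ≤ 8 observations and no ties, else
the tie-corrected normal approximation with continuity correction.
Repeated measures across visits: the Friedman rank test with average ranks
and the classical tie correction, p from χ²(k−1); it is implemented
in-package because the contract covers k = 2 treatments (where it reduces to
the sign test) and the fully-tied degenerate case (statistic 0, p = 1 by
convention — no information), with scipy's k ≥ 3 implementation serving as
an independent cross-check in the tests.  Binary longitudinal variables are
tested by Friedman on the 0/1 indicators, which is Cochran's Q under another
name.  Summaries are median (IQR) with type-7 (linear-interpolation)
quartiles — the most common convention; none is universal.  α = 0.05
two-sided throughout, no multiplicity correction; rows with a missing visit
value are dropped listwise for Friedman and counted.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every guarantee is verified.  Per patient it draws demographics
(49% male, height N(1.70, 0.09) m truncated, baseline age N(60.8, 12.5)
truncated to [20, 94], BMI lognormal median 26.5), a baseline mGFR
(lognormal median 42.3 mL/min/1.73 m², log-sd 0.436, truncated at the
hyperfiltration ceiling of 140) declining 2.6 per year, and latent true
intakes (salt lognormal median 8.3 g/day; protein median 1.29 g/kg/day with
a 0.956/year multiplicative decline emulating dietary counselling).  All
lognormal log-sds are back-solved from target interquartile ranges as
ln(q3/q1)/1.349.

True daily creatinine excretion is the normogram value for the patient's
sex/age/GFR cell times a per-patient lognormal muscle-mass factor; serum
creatinine then follows from mass balance, P = excretion/(clearance·1.44),
with clearance = absolute GFR × (1 + secretion offset).  This makes the
generator and the expected-creatinine criterion share one creatinine
production model — deliberate, so that with the muscle factor at 1 the
criterion's oracle is exact; with realistic spread (CV 20% in the preset)
the criterion degrades the way a real normogram does.  Spot periods are six
30-min draws whose per-period clearance equals true clearance (times noise).

Collection errors: each visit is incomplete with probability 0.21 × e^v,
excess with 0.144 × e^v, where e = 0.785 per visit models patient education
and v counts visits from 0.  Completeness factors are uniform on
(0.40, 0.70), (1.30, 1.80) and (0.80, 1.20) respectively — the valid range
deliberately wider than ±15% so the stringent threshold reclassifies part
of the valid set, as observed in practice.  Completeness acts
multiplicatively and identically on every solute and on volume (a missed
void loses all solutes proportionally; intra-day excretion rhythm is
ignored, consistent with the stable-excretion assumption).  Osmolarity is
stored as a concentration, so it is invariant to f while the derived osmole
*excretion* scales with f — as in real data.  Optional lognormal measurement
noise applies per analyte.  All randomness flows from one seeded
`numpy.random.Generator`; identical seeds give byte-identical cohorts.

The `paper_preset` adds measurement CV 5%, muscle-mass CV 20% and a +10%
creatinine secretion offset (24-h creatinine clearance exceeds filtration
physiologically).  With these conditions the fractional-criterion prevalence
runs ≈65% → ≈75% → ≈80% across visits with ≈21% incomplete and ≈13% excess
at baseline, the stringent threshold gives ≈47% at visit 1, and the
expected-creatinine criterion ≈58% — the regime the method is designed for.
The eGFR-referenced criterion lands near 30–35% valid here: the normogram's
creatinine production is ~40% above what MDRD implies at the same serum
creatinine, so that criterion's deltas shift positive.  Real cohorts show
the same direction (24-h clearance well above eGFR) though less strongly;
the offset and normogram are both configurable if a user wants to explore
that trade-off.

## What the generator does and does not emulate

It reproduces the *structure* the analysis relies on: steady-state
excretion driven by latent intakes, completeness errors acting
proportionally, creatinine production tied to sex/age/GFR, longitudinal
decline and education effects.  It does not model dropout or death,
within-patient correlation of collection errors across visits (error rolls
are independent given the education trend, so "no valid collection at any
visit" is rarer than in real cohorts), day-to-day intake variation, intra-day
excretion rhythm, or any physiological kidney model.  Passing tests
therefore demonstrate correctness of the computational chain under the
stated assumptions — not that 24-h collections are reliable in any
particular clinic.

## Numerical choices and degenerate inputs

* Day length fixed at 1440 min; no rescaling for off-duration collections.
* Validity boundary inclusive; threshold 0 degenerates to exact equality.
* The delta denominator is the reference, never the measured value.
* Friedman with every block fully tied returns statistic 0, p = 1.
* χ² with a zero marginal, empty samples, non-positive clearances and
  ages < 18 for MDRD raise domain errors rather than returning NaN.
* CSV round-trips write floats with `repr`, the shortest exact
  representation, so read∘write is bit-exact.
* Problem sizes in the test suite (cohorts of 30–400 patients, 2000-replicate
  null calibration at 150×3) are chosen so the whole suite completes in
  seconds while binomial/median sampling error stays well inside the asserted
  bands.

## Known limitations

The packaged expected-creatinine normogram is synthetic; conclusions under
that criterion are only as good as the table supplied.  The eGFR criterion
inherits all MDRD biases (muscle mass, ethnicity coefficient).  Diet
estimates assume steady state and no extra-renal losses; they are daily
snapshots, blind to week/season variation.  The two-group comparison and
longitudinal tables perform no multiplicity correction by design.
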