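# Methods

## Scope and model

`reeval` validates resting-energy-expenditure (REE) predictive equations
against indirect-calorimetry measurements in adult hospital patients.
The unit conventions are fixed package-wide: weight kg, height m
(equations quoted per cm convert internally), age years, REE kcal/day,
sex F=0 / M=1, energy conversion 1 kcal = 4.184 kJ and 1 MJ = 1000 kJ
exactly (the thermochemical calorie; the 4.1868 alternative differs by
0.1%, below the whole-kcal reporting precision).

### Cohort model and inclusion filters

A patient record carries anthropometry, demographics, measured REE and
the filter fields (ICU flag, pregnancy flag, measurement duration,
measurement index, self-report flags). Inclusion requires complete
height/weight/age/sex/REE, age ≥ 18, no ICU stay, no pregnancy, a
measurement of at least 15 minutes, and only the first measurement per
patient (minimal measurement index, ties by file order). Exclusions are
counted sequentially in that order, so a record failing several rules is
counted once, by the earliest rule; this makes the exclusion log
unambiguous. Filtering is idempotent. Self-reported weight/height are
accepted but flagged so analyses can optionally exclude them.

BMI is weight/height² with no internal rounding; classes are
lower-inclusive, upper-exclusive: underweight <18.5, normal [18.5, 25),
overweight [25, 30), obese ≥ 30 kg/m². A BMI of exactly 18.5 is normal
weight. REE per kg in the descriptive summary is the mean of per-patient
ratios, not the ratio of means — the two differ materially in cohorts
whose weight spans a factor of three, and the mean-of-ratios convention
is the one consistent with published cohort descriptives of this kind.

### Equation registry

Equations are data, not code: `data/equations.yaml` describes each one
by form (`linear`, `banded_linear`, `bmi_banded_linear`, `power`,
`per_kg_fixed`, `sex_fixed`), output unit, height unit, required fields
and coefficients, with a citation tag naming the primary source of the
transcription. Age bands are [lower, upper); for each sex they must tile
the adult range with no gap or overlap (validated at load), and ages
above the top band use the top band — the WHO/Schofield/Henry sources
define an open-ended ">60" band, so this is the only consistent reading.
Band-boundary convention: age 30 falls in the 30–60 band.

Two equations carry exact published coefficients and double as test
anchors: the combined hospital-patient equation (one linear form below
BMI 25, the Weijs–Vansant overweight/obese form at or above 25 — the
dispatcher is a `bmi_banded_linear` entry switching at 25, and BMI
exactly 25 takes the ≥25 branch) and its two branches individually. The
Müller BMI-specific equation likewise selects its coefficient set by BMI
class. All other coefficients (Harris–Benedict 1918, Roza 1984, WHO
1985, Schofield 1985, Henry 2005, Korth 2007, Müller 2004, Mifflin 1990,
Livingston 2005 power form a·W^p − c·age, Bernstein 1983) are registry
data: tests check their structure and unit conversion, never assert them
as ground truth.

The fixed factors encode clinical prescriptions of *total* energy: the
per-kg factors (25 and 30 kcal/kg/day) are divided by the 1.3
activity/stress factor by default to yield REE. The sex-fixed
prescription (2000 kcal F / 2500 kcal M) keeps the divisor OFF by
default: the published mean of 2253 kcal/day over 253 F + 260 M is the
undivided average, so the undivided behaviour is what reproduces the
reference arithmetic. Both behaviours are flag-selectable
(`apply_divisor`), and the inconsistency between the narrative
description of the fixed factors and their tabulated values is resolved
in favour of the tabulated arithmetic. Predictions below 500 or above
5000 kcal/day (or negative) are flagged, never clamped — validation
statistics must see the raw value.

### Scoring

Accuracy bands use the ratio predicted/measured: under <0.90, accurate
in [0.90, 1.10], over >1.10, with both boundaries inclusive (the common
reading of "between 90 and 110%"), judged at a 1e-9 relative tolerance
so that exact boundary ratios are classified deterministically. Bias is
the mean of per-patient percentage errors (not the ratio of means, which
disagrees with the tabulated fixed-factor bias). RMSE is in kcal/day.
Reports round to whole % and whole kcal/day; unrounded values are kept
internally. Performance tables order equations by descending total
accuracy with ties broken by name, preceded by the measured-REE
reference row; strata appear in the order total, <18.5, 18.5–25, 25–30,
≥30. Patients an equation cannot evaluate are skipped with a logged
reason and reduce that stratum's n.

The weight-adjustment re-evaluation clamps BMI into [18.5, 30]
(w′ = 18.5·h² or 30·h²; idempotent) and re-scores the WHO weight-height
and Harris–Benedict 1918 equations — the two named in the source
figure; the `equations` argument widens the set — in the underweight
and obese strata. Strata are defined by the *original* BMI: the
comparison is between the same patients with and without adjustment.

### Equation development

OLS of measured REE on weight, height, age and sex within a BMI
subgroup, fit via statsmodels. Height enters in centimetres even though
the data model stores metres: the published equations of this family are
quoted per cm, and fitting in cm makes coefficients directly comparable.
No variable selection, weighting or robust variants — the single
reported model is a plain OLS fit. A minimum of 10 patients and a
full-rank design are enforced; rank deficiency (single sex, constant
age) raises a specific error. The fitted equation converts to a registry
spec, so it can be scored and serialized like any shipped equation.

## Synthetic cohort generator

The generator emulates a 513-patient adult general-hospital cohort with
four BMI classes at proportions 0.27/0.41/0.15/0.17, group-specific sex
mix (44/58/53/41% male), inpatient share (57/55/35/17%), age
(51.3±17.0, 54.1±15.2, 55.3±15.2, 50.9±14.2 y), height (1.72±0.10,
1.74±0.09, 1.74±0.10, 1.71±0.12 m) and BMI (16.6±1.5, 21.3±1.8,
27.3±1.4, 36.3±5.4 kg/m²). Per patient: class by the proportions, sex
and setting Bernoulli, age truncated normal ≥18, height truncated
normal in [1.40, 2.10] m, BMI truncated normal within its class bounds,
weight derived as BMI·height². Sampling BMI rather than weight
guarantees class membership; group weight means then emerge
approximately (a mean-of-products, so they can deviate a little from
the published weight means). Measured REE is a truth model — by default
the combined hospital-patient equation — plus Gaussian noise,
SD 200 kcal/day (on the order of the best published equation's RMSE of
~286 kcal/day minus its structural misfit), floored at 500 kcal/day.

Truncated draws are *location-matched*: the underlying normal's location
is solved (Brent's method on the truncated-normal mean) so that the
post-truncation mean equals the published group mean. A naive truncated
normal centred on the published mean would inflate the obese BMI mean by
about 1.3 kg/m² (3.4%), because the class's lower bound at 30 sits only
1.2 SD below the mean; location matching removes that bias, and at
n = 10,000 per-group sample means of age, height and BMI recover the
profile values within 2%.

What the generator does **not** emulate: within-group correlations
(height–age, sex–height — unreported, so independence is assumed),
diagnosis mix, device differences, fasting state, or any non-Gaussian
REE residual structure. Consequently, passing validation on synthetic
cohorts demonstrates that the *machinery* (filters, predictions,
statistics, fitting) is correct, not that any equation is accurate in
real patients; the published per-equation accuracy percentages depend on
the unpublished patient-level data and are not reproduced here. One
visible artefact: because the truth model is itself weight-linear, the
clamped-weight comparison can *improve* another equation's accuracy on
synthetic data by cancelling its bias, a behaviour the real cohort did
not show; the analysis driver prints an explicit note when this occurs.

A companion routine plants controlled protocol violations (incomplete
fields, minors, ICU, pregnancy, short measurements, repeat measurements)
in an otherwise clean registry so the filter accounting can be tested
exactly — e.g. 593 records with 80 planted incomplete ones filter to
exactly 513.

## Numerical and reproducibility choices

- All randomness flows from one `numpy` Generator seeded by the caller;
  same seed, same cohort, byte-identical reports.
- The registry file's SHA-256 is recorded and logged by the CLI.
- Problem sizes in the tests and drivers: cohorts of 513 (the published
  size) for pipeline runs, 10,000 for marginal-recovery checks, 50-patient
  noise-free cohorts for exact OLS recovery, 20 replicates at n = 200 for
  the 3-standard-error coverage check. These sizes give stable statistics
  while keeping the full suite fast.
- Degenerate inputs: empty cohorts are legal for filtering (all-zero
  log) but raise for bias/RMSE; empty strata yield flagged n=0 rows,
  not exceptions; negative predictions propagate with a flag.

## Known limitations

- Literature coefficients were transcribed from the primary sources;
  where a source defines several variants (Henry/Schofield band
  structures, WHO's treatment of the elderly), the shipped file is one
  documented choice and alternatives can be supplied as a custom YAML.
- Bland–Altman limits of agreement and confidence intervals on accuracy
  percentages are out of scope, as are equations requiring body
  composition, temperature or ventilator settings.
- The independent-samples comparisons between in/outpatients and sexes
  are not implemented (no reference values exist to check them against).
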