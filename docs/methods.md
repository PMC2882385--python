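# Methods

## The analysis the package implements

The package computes hospital-level standardized in-hospital mortality from
discharge-level administrative records. The chain is: (1) convert each
record's co-existing ICD-10 diagnoses to a Charlson comorbidity band;
(2) encode the record into a fixed 24-column design (MDC, sex, ordinal age,
Charlson band, admission-status flags, performance status,
Fletcher-Hugh-Jones class); (3) split records into development and
validation halves and fit a maximum-likelihood logistic regression of the
death flag on the development half; (4) evaluate discrimination (c-index)
and decile calibration on the validation half; (5) aggregate predicted risks
per hospital into expected rates, SMRs and standardized rates, group
hospitals by per-hospital c-index, and cross-tabulate raw vs standardized
mortality quartiles; (6) compare high- and low-fit hospital groups with
Welch t-tests (continuous characteristics) and Fisher exact tests (binary
flags).

Because the real nationwide discharge dataset is not redistributable, the
package ships a synthetic generator whose defaults emulate the published
study conditions, and all tests run against generated cohorts.

## Model and encoding choices

- **Age** enters as a single ordinal linear term over the six bands
  (0 = under 50 … 5 = 90+), i.e. a constant odds ratio per band step. The
  published model prints one odds ratio (1.45) for the whole age row, which
  identifies the linear-term reading; per-band dummies would print six.
- **Charlson score** enters as four band dummies (1–2, 3–6, 7–12, 13+)
  against band 0, not as the raw score.
- **Admission-status flags** are four separate non-exclusive binaries: a
  record can be both an emergency and an ambulance arrival.
- **Missingness**: performance status and breathlessness class are recorded
  only for cancer and chronic pulmonary disease respectively, so "missing"
  is folded into the lowest-grade reference level at the factor-level
  definition; no imputation happens anywhere.
- **Split**: per-record Bernoulli(½) assignment (an *approximate* 50/50
  split), seeded; an exact permutation split is available via
  `split(..., method="exact")`.
- The intercept of the fitted model is reported at full precision in the
  exported JSON.

## Charlson scoring

Quan's ICD-10 coding algorithm defines the 17 condition categories as code
prefixes (3–4 characters after normalization: uppercase, dots stripped);
matching is prefix matching with 4-character prefixes taking precedence.
Weights are the original Charlson 1/2/3/6 scheme — the five score bands
reaching "13 and over" are only consistent with the original weights, not
with later re-weightings. Three hierarchy rules are applied before summing
(metastatic solid tumor suppresses other malignancy; moderate/severe liver
disease suppresses mild liver disease; complicated diabetes suppresses
uncomplicated diabetes): without them a metastatic cancer record carrying
both C78 and C50 would score 8 instead of 6 and band inflation would
distort the model's comorbidity coefficients. Unrecognized codes are
ignored but countable via a diagnostics tally. Only co-existing diagnoses
feed the score — the primary diagnosis is represented by the MDC term. The
coding table is a package TSV resource guarded by a sha256 checksum.

## The synthetic generator

What it emulates, and the defaults (all configurable in
`GeneratorConfig` / `CovariateMarginals`):

- **Covariate marginals**: the development-cohort proportions of the source
  study (e.g. male 53.0%, emergency 42.3%, Charlson band 0 69.5%, age 90+
  1.6%), stored as exact count ratios.
- **Outcome model**: deaths are Bernoulli draws from the logistic model with
  the published odds ratios as generating coefficients. The intercept is not
  published; it is calibrated by Brent root-finding so that the mean
  predicted risk over ≥10⁵ covariate draws from the admission-weighted
  hospital panel hits the target overall mortality (default 0.037) within
  5×10⁻⁴.
- **Hospital sizes**: negative binomial with mean 4011.5 and dispersion
  r ≈ 2.5, matching the published panel mean/SD (4011.5 / 2539.4) through
  r = m²/(s²−m).
- **Case-mix heterogeneity**: per-hospital MDC distributions are Dirichlet
  draws around the global marginals with concentration 22, chosen so the
  between-hospital SD of MDC shares matches the published hospital table
  (e.g. digestive 21.2% ± 8.5% → p(1−p)/(c+1) ≈ SD²).
- **Hospital profiles**: a fraction of hospitals (default 5.3%) are
  single-specialty — one MDC drawn proportionally to prevalence receives a
  share uniform in (0.55, 0.90), always exceeding the >50% specialization
  rule. Another fraction (default 9.2%) are convalescent-mixed: their
  circulatory/nervous Dirichlet weights are boosted (×3) and their age
  marginal is tilted exponentially toward older bands (tilt 0.35, pushing
  the 70+ share from ~33% to ~50%). An extra convalescent-only frailty SD
  exists (`convalescent_frailty_sd`, default 0) to emulate the poorer model
  fit of mixed acute/long-term-care hospitals.
- **Hospital effects**: optional i.i.d. normal log-odds frailty
  (`hospital_effect_sd`, default 0) added to every record's linear
  predictor, so a hospital's true SMR is an analytic function of its
  frailty.
- **Comorbidity codes**: each record's Charlson band is sampled from the
  band marginals and then materialized as ≤6 concrete ICD-10 codes whose
  score provably falls in that band (greedy decomposition of a random
  target score over hierarchy-free conditions of weights 6/3/2/1). Scoring
  therefore genuinely exercises the code-level mapper, and the round trip
  is exact by construction.
- **Randomness**: one global seed; each hospital draws from a substream
  keyed by a CRC32 counter of its id, so individual hospitals' record
  streams do not change when the panel is reordered, and identical
  config+seed reproduces byte-identical output.

What it deliberately does **not** emulate: within-record covariate
correlation. Only marginals are published, so covariates are sampled
independently by default; an optional MDC-conditional age table
(`covariate_marginals.age_by_mdc`) is provided for users who want, e.g.,
older circulatory cohorts, but it is off by default. Length of stay,
procedure codes, secondary major diagnoses and readmission linkage are out
of scope.

Consequence for interpreting green tests: passing coefficient-recovery and
calibration tests show the estimation machinery is correct under the stated
generating process; they do not certify discrimination levels on real data.
Under covariate independence the *generating* model's own c-index is ≈0.81,
which upper-bounds any refit on such cohorts, whereas the published
real-data c-index (0.882) additionally reflects co-occurrence of old age,
emergency admission and high comorbidity. The discrimination check in the
acceptance suite asserts the published-scale 0.85–0.92 band and accordingly
fails by design under the default generator; it documents exactly this gap.

## Numerical and statistical choices

- **Logistic fit**: statsmodels Newton MLE; convergence is checked and
  non-convergence raises with iteration diagnostics. Before fitting, binary
  columns whose active level contains only deaths or only survivors raise a
  perfect-separation error naming the column — with the 24-column design
  this needs roughly ≥10⁴ records at 3.7% mortality so the rare indicators
  (PS grade 4, Charlson 13+, ~0.5% prevalence) carry mixed outcomes.
- **c-index**: midrank formulation, O(n log n), ties counted ½; exactly
  equal to the brute-force pairwise count (tested). Single-class inputs
  raise — this drives the zero-mortality hospital exclusion.
- **Decile calibration**: stable sort then ten near-equal groups; records
  with identical predictions may straddle adjacent deciles. Observed rates
  get Wilson 95% intervals (preferred over Wald because hospital-level and
  low-decile rates sit near zero).
- **Quartile reclassification**: quartile cuts at the 25th/50th/75th
  percentiles; intervals are left-closed/right-open, so a rate exactly at a
  cut belongs to the upper quartile.
- **OE table**: hospitals binned by expected rate in percent,
  [lower, upper) with open first/last bins; the bin CI is the t-based
  interval of the mean OE across hospitals (undefined for n < 2; empty bins
  are emitted with n = 0).
- **Group tests**: Welch t with Satterthwaite df by default (a pooled
  variance flag exists); Fisher two-sided by summation of hypergeometric
  probabilities ≤ the observed table's. No multiplicity correction — the
  report flags each test at p < 0.05, and says so.
- **Per-hospital c-index** uses all of a hospital's records scored by the
  development-half model (not just the validation half), maximizing
  stability for small hospitals; pooled use is also what the hospital-level
  benchmarking tables assume.

## Problem sizes used by the test suite and acceptance script

Chosen as the smallest cohorts at which the checked quantities are
statistically decisive: coefficient recovery and discrimination use one
shared ~500k-record cohort (125 hospitals, mean 4000 admissions, no
specialty/convalescent profiles, zero frailty); null benchmarking uses 200
hospitals × 2000 admissions; frailty recovery (Spearman > 0.8) uses 100
hospitals × 2000 admissions at frailty SD 0.3; the Fisher oracle enumerates
every 2×2 table with margins ≤ 10; the c-index oracle uses 100 random tied
instances of n = 500.

## Known limitations

- Covariate independence (above) caps synthetic discrimination; correlation
  tables are opt-in and unvalidated against any real joint distribution.
- The 18→10 MDC recategorization lookup of the source data is not public;
  the generator works directly on the 10 analytic categories.
- SMRs are raw ratios — no shrinkage, overdispersion control limits or
  funnel plots; small hospitals have noisy SMRs and c-indices.
- The Fisher and t comparisons treat hospitals as independent units and
  ignore within-hospital clustering beyond the per-hospital aggregation.
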