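"""Reference covariate prevalences and odds ratios for the case-mix model.

These constants describe the published generic in-hospital mortality model
for Japanese DPC (Diagnosis Procedure Combination) discharge data and the
covariate mix of the ~940k-record development cohort it was estimated on.
They are the defaults for the synthetic discharge generator: covariate
marginals are the development-cohort proportions, and the generating
coefficients are the log odds ratios of the published model.

Prevalences are stored as exact count ratios so probability vectors sum to 1
to machine precision.
"""

from __future__ import annotations

import math

#: Size of the development cohort the marginals are taken from.
N_DEVELOPMENT = 939_409

#: Ten analytic Major Diagnostic Categories (18 DPC MDCs recategorized by
#: mortality).  ``musculoskeletal_other`` is the model's reference category.
MDC_PREVALENCE = {
    "digestive": 194_257 / N_DEVELOPMENT,
    "respiratory": 100_591 / N_DEVELOPMENT,
    "blood_immune": 22_741 / N_DEVELOPMENT,
    "kidney": 73_240 / N_DEVELOPMENT,
    "nervous": 65_096 / N_DEVELOPMENT,
    "circulatory": 91_892 / N_DEVELOPMENT,
    "female_breast": 82_732 / N_DEVELOPMENT,
    "endocrine": 31_528 / N_DEVELOPMENT,
    "skin_eye_pediatric": 139_642 / N_DEVELOPMENT,
    "musculoskeletal_other": 137_690 / N_DEVELOPMENT,
}

#: Age bands under50, 50-59, 60-69, 70-79, 80-89, 90+ (ordinals 0..5).
AGE_PREVALENCE = (
    306_473 / N_DEVELOPMENT,
    134_905 / N_DEVELOPMENT,
    186_102 / N_DEVELOPMENT,
    208_171 / N_DEVELOPMENT,
    88_922 / N_DEVELOPMENT,
    14_836 / N_DEVELOPMENT,
)

MALE_PREVALENCE = 497_564 / N_DEVELOPMENT

#: Charlson score bands of the co-existing diagnoses.
CHARLSON_BAND_PREVALENCE = {
    "0": 652_986 / N_DEVELOPMENT,
    "1-2": 209_063 / N_DEVELOPMENT,
    "3-6": 53_781 / N_DEVELOPMENT,
    "7-12": 17_645 / N_DEVELOPMENT,
    "13-": 5_934 / N_DEVELOPMENT,
}

#: Non-exclusive admission-status flags (a record can be emergency AND
#: arrive by ambulance).
ADMISSION_FLAG_PREVALENCE = {
    "emergency": 397_650 / N_DEVELOPMENT,
    "ambulance": 116_987 / N_DEVELOPMENT,
    "exam_hospitalization": 62_673 / N_DEVELOPMENT,
    "planned_short": 44_434 / N_DEVELOPMENT,
}

#: ECOG performance status, collapsed as the model encodes it: grade 0/1 and
#: missing together form the reference level (recorded only for cancer).
PS_PREVALENCE = {
    "grade0_1_missing": 921_721 / N_DEVELOPMENT,
    "grade2": 7_544 / N_DEVELOPMENT,
    "grade3": 5_103 / N_DEVELOPMENT,
    "grade4": 5_041 / N_DEVELOPMENT,
}

#: Fletcher-Hugh-Jones breathlessness class, collapsed likewise (class 1/2
#: and missing are the reference; recorded only for chronic pulmonary
#: disease).
FHJ_PREVALENCE = {
    "class1_2_missing": 912_266 / N_DEVELOPMENT,
    "class3_4": 16_082 / N_DEVELOPMENT,
    "class5": 11_061 / N_DEVELOPMENT,
}

#: Overall in-hospital mortality of the cohort.
OVERALL_MORTALITY = 0.037

#: Published odds ratios of the case-mix logistic model, keyed by design
#: column.  Age enters as a single ordinal linear term (OR per band step);
#: reference levels (musculoskeletal/other MDC, Charlson 0, PS grade 0/1 or
#: missing, FHJ class 1/2 or missing) carry no column.
REFERENCE_ODDS_RATIOS = {
    "mdc_digestive": 1.81,
    "mdc_respiratory": 1.56,
    "mdc_blood_immune": 5.49,
    "mdc_kidney": 1.40,
    "mdc_nervous": 1.80,
    "mdc_circulatory": 1.76,
    "mdc_female_breast": 1.16,
    "mdc_endocrine": 0.62,
    "mdc_skin_eye_pediatric": 0.39,
    "male": 1.23,
    "age_ordinal": 1.45,
    "charlson_1_2": 1.23,
    "charlson_3_6": 3.17,
    "charlson_7_12": 5.92,
    "charlson_13_plus": 10.30,
    "emergency": 2.80,
    "ambulance": 2.39,
    "exam_hospitalization": 0.11,
    "planned_short": 0.25,
    "ps_grade2": 3.00,
    "ps_grade3": 7.29,
    "ps_grade4": 23.98,
    "fhj_class3_4": 1.47,
    "fhj_class5": 5.26,
}

REFERENCE_LOG_ODDS = {k: math.log(v) for k, v in REFERENCE_ODDS_RATIOS.items()}

#: Hospital panel summaries: admissions per hospital over the four-month
#: window (mean/SD across 468 hospitals) and hospital-type fractions.
HOSPITAL_ADMISSIONS_MEAN = 4011.5
HOSPITAL_ADMISSIONS_SD = 2539.4
#: Negative-binomial dispersion r = m^2 / (s^2 - m) matching the mean/SD.
HOSPITAL_ADMISSIONS_DISPERSION = HOSPITAL_ADMISSIONS_MEAN**2 / (
    HOSPITAL_ADMISSIONS_SD**2 - HOSPITAL_ADMISSIONS_MEAN
)

SPECIALIZED_FRACTION = 25 / 469
CONVALESCENT_FRACTION = 43 / 469
PUBLIC_FRACTION = 130 / 468
UNIVERSITY_FRACTION = 77 / 468
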