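"""Default preoperative variable catalogue.

The pipeline operates on a fixed panel of 60 preoperative clinical,
anthropometric and biochemical variables recorded one month before
Roux-en-Y gastric bypass (just before the pre-surgical very-low-calorie
diet, VLCD). Binary comorbidity/medication variables are 0/1 coded
(0 = absent, 1 = present); everything else is continuous on its clinical
scale.

Each catalogue entry also carries a marginal distribution (Normal mean/SD
for continuous variables, Bernoulli p for binary ones) used by the
synthetic cohort generator. Marginals for age, weight, BMI, waist
circumference, blood pressure, glucose, HOMA-IR, lipids and the major
comorbidity prevalences are calibrated to the published baseline
characteristics of the cohort this pipeline was designed around; the
remaining analytes use typical reference-interval values for a severely
obese adult population.
"""

from __future__ import annotations

from .cohort import VariableSpec

#: index (1-based), name, kind, units, marginal.
#: For continuous variables the marginal is (mean, sd);
#: for binary variables it is the Bernoulli probability of a 1.
_CATALOGUE: list[tuple[int, str, str, str, tuple[float, float] | float]] = [
    (1, "Gender", "binary", "1=male", 0.364),
    (2, "Age", "continuous", "years", (45.6, 9.6)),
    (3, "Dyslipidemia", "binary", "", 0.644),
    (4, "Hypertension", "binary", "", 0.627),
    (5, "Diabetes", "binary", "", 0.542),
    (6, "Impaired fasting glucose", "binary", "", 0.25),
    (7, "Hepatic steatosis", "binary", "", 0.60),
    (8, "Obstructive sleep apnea", "binary", "", 0.45),
    (9, "Arthrosis", "binary", "", 0.30),
    (10, "Hyperuricemia", "binary", "", 0.25),
    (11, "Anxiety-depressive disorder", "binary", "", 0.30),
    (12, "Hypothyroidism", "binary", "", 0.15),
    (13, "Smoking habit", "binary", "", 0.25),
    (14, "Minutes of physical exercise per week", "continuous", "min/week", (90.0, 80.0)),
    (15, "Metformin", "binary", "", 0.40),
    (16, "Insulin treatment", "binary", "", 0.20),
    (17, "Other non-insulin agents", "binary", "", 0.20),
    (18, "Height", "continuous", "cm", (166.0, 9.0)),
    (19, "Pre-VLCD weight", "continuous", "kg", (130.1, 23.5)),
    (20, "Preoperative weight", "continuous", "kg", (123.6, 22.5)),
    (21, "Pre-VLCD BMI", "continuous", "kg/m2", (46.7, 6.3)),
    (22, "Preoperative BMI", "continuous", "kg/m2", (44.4, 6.1)),
    (23, "Waist circumference before surgery", "continuous", "cm", (136.0, 14.3)),
    (24, "Systolic blood pressure before surgery", "continuous", "mmHg", (142.7, 17.0)),
    (25, "Diastolic blood pressure before surgery", "continuous", "mmHg", (88.3, 9.4)),
    (26, "Fasting glucose", "continuous", "mg/dL", (103.4, 36.8)),
    (27, "HbA1c", "continuous", "%", (6.2, 1.3)),
    (28, "Insulin levels", "continuous", "uU/mL", (22.0, 15.0)),
    (29, "HOMA-IR", "continuous", "", (5.8, 5.1)),
    (30, "Triglycerides", "continuous", "mg/dL", (117.8, 49.9)),
    (31, "Total cholesterol", "continuous", "mg/dL", (159.6, 35.6)),
    (32, "LDL-cholesterol", "continuous", "mg/dL", (95.0, 30.0)),
    (33, "HDL-cholesterol", "continuous", "mg/dL", (42.0, 11.0)),
    (34, "Non-HDL cholesterol", "continuous", "mg/dL", (118.0, 34.0)),
    (35, "Free fatty acids", "continuous", "mmol/L", (0.6, 0.25)),
    (36, "Apolipoprotein A", "continuous", "mg/dL", (130.0, 25.0)),
    (37, "Apolipoprotein B", "continuous", "mg/dL", (90.0, 24.0)),
    (38, "AST", "continuous", "U/L", (25.0, 12.0)),
    (39, "ALT", "continuous", "U/L", (32.0, 18.0)),
    (40, "GGT", "continuous", "U/L", (35.0, 25.0)),
    (41, "Uric acid", "continuous", "mg/dL", (6.0, 1.5)),
    (42, "Sodium", "continuous", "mmol/L", (140.0, 2.5)),
    (43, "Potassium", "continuous", "mmol/L", (4.3, 0.35)),
    (44, "Chlorine", "continuous", "mmol/L", (103.0, 3.0)),
    (45, "Creatinine", "continuous", "mg/dL", (0.8, 0.2)),
    (46, "Urea", "continuous", "mg/dL", (33.0, 10.0)),
    (47, "Free Thyroxine", "continuous", "ng/dL", (1.2, 0.2)),
    (48, "Thyrotropin", "continuous", "uU/mL", (2.5, 1.5)),
    (49, "Fibrinogen", "continuous", "mg/dL", (400.0, 80.0)),
    (50, "C reactive protein", "continuous", "mg/L", (8.0, 7.0)),
    (51, "Complement component 3", "continuous", "mg/dL", (135.0, 25.0)),
    (52, "Complement component 4", "continuous", "mg/dL", (30.0, 9.0)),
    (53, "Lipoprotein a", "continuous", "mg/dL", (30.0, 30.0)),
    (54, "Homocysteine", "continuous", "umol/L", (11.0, 4.0)),
    (55, "Folic acid", "continuous", "ng/mL", (7.0, 3.5)),
    (56, "Vitamin B12", "continuous", "pg/mL", (400.0, 150.0)),
    (57, "Vitamin D", "continuous", "ng/mL", (20.0, 9.0)),
    (58, "Leukocytes", "continuous", "10^3/uL", (7.8, 2.0)),
    (59, "Hemoglobin", "continuous", "g/dL", (14.0, 1.4)),
    (60, "Platelets", "continuous", "10^3/uL", (260.0, 60.0)),
]

#: 1-based index of the gender variable, the weighting reference (alpha = 0).
GENDER_INDEX = 1

#: 1-based index of the pre-VLCD (basal) weight variable.
BASAL_WEIGHT_INDEX = 19

#: Default informative panel for the synthetic generator: the nine variables
#: that attained consensus-high weighting exponents in the study this
#: pipeline reimplements (sleep apnea, osteoarthritis, insulin treatment,
#: preoperative weight, HOMA-IR, Apo A, uric acid, C3, vitamin B12).
DEFAULT_INFORMATIVE = (8, 9, 16, 20, 29, 36, 41, 51, 56)


def default_schema() -> list[VariableSpec]:
    """The 60-variable panel as :class:`~barilearn.cohort.VariableSpec` list."""
    return [
        VariableSpec(name=name, index=idx, kind=kind, units=units)
        for idx, name, kind, units, _ in _CATALOGUE
    ]


def default_marginals() -> dict[int, tuple[float, float] | float]:
    """Per-variable marginal parameters keyed by 1-based index.

    Continuous variables map to ``(mean, sd)``, binary variables to the
    Bernoulli probability of a 1.
    """
    return {idx: marg for idx, _, _, _, marg in _CATALOGUE}
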