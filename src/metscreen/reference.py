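"""Published reference statistics for a large Colombian youth cohort.

Stratum-wise descriptive statistics (mean, SD) and screening-performance
values reported for a cross-sectional cohort of 4673 Colombian children,
adolescents and young adults (ages 9-25) in which TMI and FMI thresholds
for metabolic-syndrome screening were first proposed.  These numbers
parameterize the default synthetic-cohort strata and serve as worked-example
inputs; the raw cohort itself is not public.

Trait keys follow :data:`metscreen.cohort.NUMERIC_COLUMNS`.
``reported_indices`` are the descriptive means the source table prints for
indices derived from the traits (BMI, TMI, FMI, mean arterial pressure);
the adult strata's printed MAP is consistent with the arithmetic mean of
SBP and DBP, the paediatric strata's with DBP + (SBP - DBP)/3.
"""
from __future__ import annotations

#: (sex, age-group label) -> stratum statistics
STRATA: dict[tuple[str, str], dict] = {
    ("female", "children"): {
        "n": 582,
        "means": {
            "age": 10.8, "weight": 38.2, "height": 1.43, "waist": 60.1,
            "body_fat_pct": 23.6, "sbp": 109.6, "dbp": 67.1,
            "triglycerides": 96.0, "hdl": 48.4, "ldl": 86.0,
            "total_cholesterol": 151.3, "glucose": 83.3,
        },
        "sds": {
            "age": 1.1, "weight": 8.8, "height": 0.09, "waist": 7.1,
            "body_fat_pct": 5.8, "sbp": 13.8, "dbp": 8.6,
            "triglycerides": 60.4, "hdl": 13.0, "ldl": 26.6,
            "total_cholesterol": 29.3, "glucose": 15.0,
        },
        "reported_indices": {"bmi": 18.5, "tmi": 13.0, "fmi": 3.2, "map": 81.2},
        "mets_n": 85,
        "mets_pct": 14.6,
    },
    ("male", "children"): {
        "n": 465,
        "means": {
            "age": 10.7, "weight": 37.6, "height": 1.42, "waist": 62.2,
            "body_fat_pct": 19.3, "sbp": 111.0, "dbp": 66.6,
            "triglycerides": 86.8, "hdl": 51.5, "ldl": 86.6,
            "total_cholesterol": 152.1, "glucose": 85.3,
        },
        "sds": {
            "age": 1.1, "weight": 9.6, "height": 0.10, "waist": 7.7,
            "body_fat_pct": 6.5, "sbp": 13.7, "dbp": 8.9,
            "triglycerides": 44.7, "hdl": 13.1, "ldl": 30.0,
            "total_cholesterol": 30.3, "glucose": 16.2,
        },
        "reported_indices": {"bmi": 18.4, "tmi": 12.9, "fmi": 2.6, "map": 81.4},
        "mets_n": 60,
        "mets_pct": 12.9,
    },
    ("female", "adolescents"): {
        "n": 986,
        "means": {
            "age": 14.6, "weight": 50.9, "height": 1.55, "waist": 65.9,
            "body_fat_pct": 25.7, "sbp": 110.6, "dbp": 69.4,
            "triglycerides": 96.7, "hdl": 46.9, "ldl": 84.6,
            "total_cholesterol": 148.3, "glucose": 80.5,
        },
        "sds": {
            "age": 1.3, "weight": 8.6, "height": 0.06, "waist": 6.8,
            "body_fat_pct": 6.0, "sbp": 11.5, "dbp": 8.6,
            "triglycerides": 50.2, "hdl": 11.7, "ldl": 29.4,
            "total_cholesterol": 31.3, "glucose": 16.1,
        },
        "reported_indices": {"bmi": 21.0, "tmi": 13.6, "fmi": 3.6, "map": 83.1},
        "mets_n": 80,
        "mets_pct": 8.1,
    },
    ("male", "adolescents"): {
        "n": 844,
        "means": {
            "age": 14.7, "weight": 53.0, "height": 1.63, "waist": 67.5,
            "body_fat_pct": 15.1, "sbp": 114.4, "dbp": 68.9,
            "triglycerides": 84.4, "hdl": 44.4, "ldl": 78.6,
            "total_cholesterol": 132.9, "glucose": 82.3,
        },
        "sds": {
            "age": 1.3, "weight": 10.4, "height": 0.10, "waist": 6.8,
            "body_fat_pct": 5.9, "sbp": 14.0, "dbp": 9.4,
            "triglycerides": 35.8, "hdl": 11.2, "ldl": 35.9,
            "total_cholesterol": 30.3, "glucose": 15.5,
        },
        "reported_indices": {"bmi": 19.9, "tmi": 12.2, "fmi": 1.9, "map": 84.0},
        "mets_n": 56,
        "mets_pct": 6.5,
    },
    ("female", "young_adults"): {
        "n": 1104,
        "means": {
            "age": 21.9, "weight": 58.7, "height": 1.59, "waist": 71.5,
            "body_fat_pct": 27.0, "sbp": 111.2, "dbp": 71.7,
            "triglycerides": 88.5, "hdl": 43.9, "ldl": 87.9,
            "total_cholesterol": 146.3, "glucose": 86.0,
        },
        "sds": {
            "age": 1.9, "weight": 10.3, "height": 0.05, "waist": 8.0,
            "body_fat_pct": 7.2, "sbp": 11.1, "dbp": 9.3,
            "triglycerides": 45.3, "hdl": 12.8, "ldl": 26.1,
            "total_cholesterol": 33.3, "glucose": 11.5,
        },
        "reported_indices": {"bmi": 23.2, "tmi": 14.6, "fmi": 4.0, "map": 91.5},
        "mets_n": 82,
        "mets_pct": 7.4,
    },
    ("male", "young_adults"): {
        "n": 692,
        "means": {
            "age": 22.6, "weight": 68.9, "height": 1.72, "waist": 78.2,
            "body_fat_pct": 15.6, "sbp": 120.2, "dbp": 74.1,
            "triglycerides": 93.7, "hdl": 39.5, "ldl": 81.0,
            "total_cholesterol": 132.7, "glucose": 85.5,
        },
        "sds": {
            "age": 1.2, "weight": 12.1, "height": 0.06, "waist": 8.0,
            "body_fat_pct": 6.5, "sbp": 12.9, "dbp": 11.4,
            "triglycerides": 48.5, "hdl": 10.6, "ldl": 26.0,
            "total_cholesterol": 30.2, "glucose": 11.7,
        },
        "reported_indices": {"bmi": 23.1, "tmi": 13.4, "fmi": 2.2, "map": 97.2},
        "mets_n": 166,
        "mets_pct": 9.2,
    },
}

#: total cohort size across the six strata
TOTAL_N = sum(s["n"] for s in STRATA.values())

#: reported ROC screening points: (sex, age-group, index) ->
#: AUC, 95% CI, Youden-selected cutoff (index units), sensitivity and
#: specificity (whole percent), and the printed likelihood ratios.
REPORTED_SCREENING: dict[tuple[str, str, str], dict] = {
    ("female", "children", "tmi"): {
        "auc": 0.674, "ci": (0.608, 0.740), "cutoff": 12.13,
        "sens_pct": 80, "spec_pct": 61, "lr_pos": 2.04, "lr_neg": 0.33,
    },
    ("female", "children", "fmi"): {
        "auc": 0.698, "ci": (0.634, 0.763), "cutoff": 2.59,
        "sens_pct": 85, "spec_pct": 59, "lr_pos": 2.05, "lr_neg": 0.26,
    },
    ("male", "children", "tmi"): {
        "auc": 0.755, "ci": (0.677, 0.833), "cutoff": 12.10,
        "sens_pct": 85, "spec_pct": 59, "lr_pos": 2.05, "lr_neg": 0.26,
    },
    ("male", "children", "fmi"): {
        "auc": 0.752, "ci": (0.676, 0.828), "cutoff": 1.98,
        "sens_pct": 82, "spec_pct": 60, "lr_pos": 2.04, "lr_neg": 0.31,
    },
    ("female", "adolescents", "tmi"): {
        "auc": 0.684, "ci": (0.619, 0.748), "cutoff": 12.48,
        "sens_pct": 86, "spec_pct": 70, "lr_pos": 2.87, "lr_neg": 0.20,
    },
    ("female", "adolescents", "fmi"): {
        "auc": 0.699, "ci": (0.635, 0.762), "cutoff": 3.12,
        "sens_pct": 87, "spec_pct": 66, "lr_pos": 2.55, "lr_neg": 0.19,
    },
    ("male", "adolescents", "tmi"): {
        "auc": 0.729, "ci": (0.654, 0.797), "cutoff": 11.19,
        "sens_pct": 93, "spec_pct": 70, "lr_pos": 3.09, "lr_neg": 0.10,
    },
    ("male", "adolescents", "fmi"): {
        "auc": 0.745, "ci": (0.675, 0.816), "cutoff": 1.46,
        "sens_pct": 84, "spec_pct": 60, "lr_pos": 2.10, "lr_neg": 0.27,
    },
    ("female", "young_adults", "tmi"): {
        "auc": 0.854, "ci": (0.805, 0.903), "cutoff": 13.21,
        "sens_pct": 94, "spec_pct": 67, "lr_pos": 2.81, "lr_neg": 0.09,
    },
    ("female", "young_adults", "fmi"): {
        "auc": 0.882, "ci": (0.840, 0.924), "cutoff": 3.27,
        "sens_pct": 95, "spec_pct": 62, "lr_pos": 2.52, "lr_neg": 0.08,
    },
    ("male", "young_adults", "tmi"): {
        "auc": 0.814, "ci": (0.759, 0.869), "cutoff": 12.19,
        "sens_pct": 94, "spec_pct": 70, "lr_pos": 3.11, "lr_neg": 0.09,
    },
    ("male", "young_adults", "fmi"): {
        "auc": 0.848, "ci": (0.800, 0.896), "cutoff": 1.65,
        "sens_pct": 93, "spec_pct": 57, "lr_pos": 2.14, "lr_neg": 0.13,
    },
}
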