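"""Bundled reference cohort summary statistics.

These are the published group-level summaries (group sizes, means, SDs,
omnibus F statistics, ROC operating points and paired-AUC Z values) of the
reference L1 cortical-bone study cohort.  They serve two roles:

* default parameterisation of the synthetic cohort generator, and
* the comparison bank for summary-replay validation (recomputing F
  statistics and working-model AUCs from the printed triplets).

All dictionaries are plain data; no values here are ever computed.
"""

from __future__ import annotations

#: canonical parameter keys, in report order
PARAMETERS = (
    "average_density",
    "average_thickness",
    "average_area",
    "total_volume",
)

#: display units per parameter (volume is tabulated in thousands of mm^3)
PARAMETER_UNITS = {
    "average_density": "HU/mm^3",
    "average_thickness": "mm",
    "average_area": "mm^2",
    "total_volume": "mm^3 x 10^3",
}

# ---------------------------------------------------------------------------
# Screening flow (STROBE): 326 screened, 157 excluded in five categories.
# ---------------------------------------------------------------------------

SCREENING_FLOW = {
    "screened": 326,
    "excluded": {
        "spinal_fracture_or_tumor": 32,
        "bone_metabolic_disease_or_drugs": 45,
        "spinal_surgery": 21,
        "image_quality": 38,
        "incomplete_coverage": 21,
    },
    "included": 169,
}

DEMOGRAPHICS = {
    "n_included": 169,
    "n_male": 96,
    "n_female": 73,
    "age_mean": 63.23,
    "age_sd": 8.41,
    "age_min": 50,
    "age_max": 87,
}

AGE_STRATA = ("50-59", "60-69", "70+")

#: per-sex age-stratum counts (order matches AGE_STRATA)
AGE_STRATUM_COUNTS = {
    "all": (71, 55, 43),
    "female": (29, 23, 21),
    "male": (42, 32, 22),
}

# ---------------------------------------------------------------------------
# Morphometry summaries by age stratum.  Each row maps a parameter to
# ((mean, sd) per stratum); "f" holds the published omnibus F statistics.
# ---------------------------------------------------------------------------

AGE_GROUPS_ALL = {
    "labels": AGE_STRATA,
    "n": (71, 55, 43),
    "mean_sd": {
        "average_density": ((432.35, 109.70), (410.11, 91.81), (431.77, 96.28)),
        "average_thickness": ((1.83, 0.66), (1.60, 0.70), (1.27, 0.68)),
        "average_area": ((390.63, 226.90), (328.60, 227.18), (245.05, 169.77)),
        "total_volume": ((10.46, 6.31), (8.37, 6.11), (6.31, 4.47)),
    },
    "f": {
        "average_density": 0.885,
        "average_thickness": 9.194,
        "average_area": 6.217,
        "total_volume": 6.944,
    },
}

AGE_GROUPS_FEMALE = {
    "labels": AGE_STRATA,
    "n": (29, 23, 21),
    "mean_sd": {
        "average_density": ((437.37, 128.00), (397.26, 93.28), (427.30, 83.11)),
        "average_thickness": ((1.81, 0.60), (1.48, 0.76), (1.01, 0.62)),
        "average_area": ((383.13, 239.53), (254.60, 187.96), (216.85, 192.25)),
        "total_volume": ((10.04, 6.42), (6.20, 4.64), (5.39, 4.91)),
    },
    "f": {
        "average_density": 0.956,
        "average_thickness": 8.965,
        "average_area": 4.383,
        "total_volume": 5.292,
    },
}

AGE_GROUPS_MALE = {
    "labels": AGE_STRATA,
    "n": (42, 32, 22),
    "mean_sd": {
        "average_density": ((428.88, 96.58), (419.36, 91.10), (436.03, 109.18)),
        "average_thickness": ((1.84, 0.70), (1.68, 0.65), (1.51, 0.65)),
        "average_area": ((395.80, 220.56), (381.79, 240.51), (271.97, 144.53)),
        "total_volume": ((10.76, 6.30), (9.94, 6.62), (7.18, 3.91)),
    },
    "f": {
        "average_density": 0.198,
        "average_thickness": 1.743,
        "average_area": 2.627,
        "total_volume": 2.643,
    },
}

# ---------------------------------------------------------------------------
# Morphometry summaries by vBMD class (normal / osteopenia / osteoporosis).
# ---------------------------------------------------------------------------

BMD_CLASSES = ("normal", "osteopenia", "osteoporosis")

BMD_GROUPS_ALL = {
    "labels": BMD_CLASSES,
    "n": (59, 58, 52),
    "mean_sd": {
        "average_density": ((446.95, 114.98), (414.49, 94.66), (411.71, 86.70)),
        "average_thickness": ((1.85, 0.70), (1.75, 0.61), (1.19, 0.63)),
        "average_area": ((416.75, 217.28), (365.61, 221.03), (202.91, 159.19)),
        "total_volume": ((11.11, 5.87), (9.56, 6.11), (5.09, 4.25)),
    },
    "f": {
        "average_density": 2.200,
        "average_thickness": 16.436,
        "average_area": 16.507,
        "total_volume": 17.482,
    },
}

#: osteoporosis vs non-osteoporosis split by sex (non-OP = normal + osteopenia)
OP_SPLIT = {
    "all": {"osteoporosis": 52, "non_osteoporosis": 117},
    "female": {"osteoporosis": 32, "non_osteoporosis": 41},
    "male": {"osteoporosis": 20, "non_osteoporosis": 76},
}

# ---------------------------------------------------------------------------
# ROC operating points (AUC, 95% CI, Youden cutoff, specificity %, sensitivity %)
# for discriminating osteoporosis.  Cutoff for total_volume is in 10^3 mm^3.
# ---------------------------------------------------------------------------

ROC_ALL = {
    "average_thickness": {"auc": 0.75, "ci": (0.68, 0.81), "cutoff": 1.20,
                          "specificity": 59.62, "sensitivity": 80.34},
    "average_area": {"auc": 0.80, "ci": (0.73, 0.85), "cutoff": 209.70,
                     "specificity": 71.15, "sensitivity": 83.76},
    "total_volume": {"auc": 0.80, "ci": (0.74, 0.86), "cutoff": 5.49,
                     "specificity": 73.08, "sensitivity": 82.05},
}

ROC_FEMALE = {
    "average_thickness": {"auc": 0.72, "ci": (0.60, 0.82), "cutoff": 1.10,
                          "specificity": 56.25, "sensitivity": 78.05},
    "average_area": {"auc": 0.75, "ci": (0.64, 0.85), "cutoff": 202.40,
                     "specificity": 75.00, "sensitivity": 78.05},
    "total_volume": {"auc": 0.76, "ci": (0.65, 0.85), "cutoff": 4.46,
                     "specificity": 71.87, "sensitivity": 82.93},
}

ROC_MALE = {
    "average_thickness": {"auc": 0.77, "ci": (0.67, 0.85), "cutoff": 1.20,
                          "specificity": 65.00, "sensitivity": 82.89},
    "average_area": {"auc": 0.83, "ci": (0.74, 0.90), "cutoff": 283.40,
                     "specificity": 90.00, "sensitivity": 69.74},
    "total_volume": {"auc": 0.84, "ci": (0.75, 0.91), "cutoff": 6.00,
                     "specificity": 80.00, "sensitivity": 81.58},
}

# ---------------------------------------------------------------------------
# Paired-AUC comparison (Z statistic, two-sided p) per study group.
# ---------------------------------------------------------------------------

DELONG_COMPARISONS = {
    "all": {
        ("average_thickness", "average_area"): {"z": 1.064, "p": 0.287},
        ("average_thickness", "total_volume"): {"z": 1.224, "p": 0.221},
        ("average_area", "total_volume"): {"z": 1.382, "p": 0.167},
    },
    "female": {
        ("average_thickness", "average_area"): {"z": 0.548, "p": 0.584},
        ("average_thickness", "total_volume"): {"z": 0.652, "p": 0.515},
        ("average_area", "total_volume"): {"z": 0.955, "p": 0.339},
    },
    "male": {
        ("average_thickness", "average_area"): {"z": 0.884, "p": 0.377},
        ("average_thickness", "total_volume"): {"z": 1.003, "p": 0.316},
        ("average_area", "total_volume"): {"z": 0.826, "p": 0.409},
    },
}


def group_summaries(table: dict, parameter: str):
    """Return the (label, n, mean, sd) rows of one parameter of a summary table.

    Avoids importing :mod:`cortiqct.cohort_stats` here; callers typically wrap
    the tuples in :class:`~cortiqct.cohort_stats.GroupSummary`.
    """
    rows = []
    for label, n, (mean, sd) in zip(table["labels"], table["n"],
                                    table["mean_sd"][parameter]):
        rows.append((label, n, mean, sd))
    return rows
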