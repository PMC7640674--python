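"""Published summary tables from the motivating statin-outcome preference survey.

The survey elicited the relative importance of 13 statin-associated
benefit/harm outcomes with an object-case best-worst scaling (MaxDiff)
instrument: 13 choice sets of four outcomes from a (13, 4, 1) balanced
incomplete block design, answered by 913 general-population respondents
(449 urban, 464 rural) and 172 primary-care providers.

This module holds the published aggregate results and sample
characteristics as plain data:

* :data:`COUNTING_TABLES` -- per-stratum best/worst tallies with the
  published 2-dp mean B-W scores and ranks,
* :data:`LOGIT_COEFFICIENTS` -- per-stratum maxdiff conditional-logit
  coefficients (myopathy as reference) with 95% CIs,
* :data:`PROFILE_MARGINALS` -- covariate category frequencies used as
  defaults by the respondent simulator.

They serve two purposes: defaults for the synthetic-data generator
(so simulations have the study's structure) and fixed inputs for
arithmetic-consistency checks of the counting module.
"""

from __future__ import annotations

import pandas as pd

#: Catalog order: the order the outcomes are introduced in the survey
#: instrument (the statin benefit/harm outcome list).
ITEMS: tuple[str, ...] = (
    "moderate_mi",
    "severe_mi",
    "moderate_stroke",
    "severe_stroke",
    "unstable_angina",
    "heart_failure",
    "liver_injury",
    "myopathy",
    "type2_diabetes",
    "acute_kidney_failure",
    "cancer",
    "nausea_headache",
    "treatment_discontinuation",
)

ITEM_LABELS: dict[str, str] = {
    "moderate_mi": "Moderate myocardial infarction",
    "severe_mi": "Severe myocardial infarction",
    "moderate_stroke": "Moderate stroke",
    "severe_stroke": "Severe stroke",
    "unstable_angina": "Unstable angina",
    "heart_failure": "Heart failure",
    "liver_injury": "Liver injury",
    "myopathy": "Myopathy",
    "type2_diabetes": "Type 2 diabetes",
    "acute_kidney_failure": "Acute kidney failure",
    "cancer": "Cancer",
    "nausea_headache": "Nausea/headache",
    "treatment_discontinuation": "Treatment discontinuation due to side effects",
}

#: Respondents per stratum.
STRATUM_N: dict[str, int] = {
    "provider": 172,
    "total": 913,
    "urban": 449,
    "rural": 464,
}

# Published counting tables: item -> (total_best, total_worst,
# published 2-dp mean B-W, published rank).  In every stratum the column
# sums must satisfy sum(total_best) = sum(total_worst) = 13 * n
# (each of n respondents contributes one best and one worst per block).
# Two cells of the published table violate that identity as typeset and
# were reconstructed from it together with the printed B-W score:
#   - total/cancer total_best: 2568 (typeset 2868 gives a column sum of
#     11869+300 and contradicts the printed B-W score of 2458),
#   - rural/unstable_angina total_best: 81 (the typeset digits are not
#     parseable as any pair consistent with B-W = -547 except 81/628,
#     which also restores the column sum 6032 = 464*13).
_RAW_COUNTS: dict[str, dict[str, tuple[int, int, float, int]]] = {
    "provider": {
        "severe_stroke": (594, 0, 3.45, 1),
        "severe_mi": (467, 1, 2.71, 2),
        "cancer": (485, 24, 2.68, 3),
        "moderate_stroke": (212, 27, 1.07, 4),
        "moderate_mi": (114, 61, 0.31, 5),
        "liver_injury": (92, 85, 0.04, 6),
        "acute_kidney_failure": (99, 126, -0.16, 7),
        "heart_failure": (101, 142, -0.24, 8),
        "type2_diabetes": (45, 111, -0.38, 9),
        "unstable_angina": (16, 218, -1.17, 10),
        "treatment_discontinuation": (4, 422, -2.43, 11),
        "nausea_headache": (3, 459, -2.65, 12),
        "myopathy": (4, 560, -3.23, 13),
    },
    "total": {
        "severe_stroke": (3119, 39, 3.37, 1),
        "severe_mi": (2510, 29, 2.71, 2),
        "cancer": (2568, 110, 2.69, 3),
        "moderate_stroke": (1040, 134, 0.99, 4),
        "moderate_mi": (593, 289, 0.33, 5),
        "type2_diabetes": (326, 498, -0.19, 6),
        "liver_injury": (374, 594, -0.24, 7),
        "acute_kidney_failure": (496, 725, -0.25, 8),
        "heart_failure": (589, 836, -0.27, 9),
        "unstable_angina": (152, 1238, -1.19, 10),
        "treatment_discontinuation": (36, 2083, -2.24, 11),
        "nausea_headache": (25, 2483, -2.69, 12),
        "myopathy": (41, 2811, -3.03, 13),
    },
    "urban": {
        "severe_stroke": (1526, 17, 3.36, 1),
        "severe_mi": (1198, 16, 2.63, 3),
        "cancer": (1301, 38, 2.81, 2),
        "moderate_stroke": (540, 53, 1.08, 4),
        "moderate_mi": (300, 119, 0.40, 5),
        "liver_injury": (204, 278, -0.16, 6),
        "acute_kidney_failure": (250, 350, -0.22, 7),
        "type2_diabetes": (147, 270, -0.27, 8),
        "heart_failure": (275, 419, -0.32, 9),
        "unstable_angina": (71, 610, -1.20, 10),
        "treatment_discontinuation": (8, 1005, -2.22, 11),
        "nausea_headache": (9, 1271, -2.81, 12),
        "myopathy": (8, 1391, -3.08, 13),
    },
    "rural": {
        "severe_stroke": (1593, 22, 3.38, 1),
        "severe_mi": (1312, 13, 2.80, 2),
        "cancer": (1267, 72, 2.57, 3),
        "moderate_stroke": (500, 81, 0.90, 4),
        "moderate_mi": (293, 170, 0.26, 5),
        "type2_diabetes": (179, 228, -0.11, 6),
        "heart_failure": (314, 417, -0.22, 7),
        "acute_kidney_failure": (246, 375, -0.28, 8),
        "liver_injury": (170, 316, -0.31, 9),
        "unstable_angina": (81, 628, -1.18, 10),
        "treatment_discontinuation": (28, 1078, -2.26, 11),
        "nausea_headache": (16, 1212, -2.58, 12),
        "myopathy": (33, 1420, -2.99, 13),
    },
}


def _counts_frame(stratum: str) -> pd.DataFrame:
    rows = _RAW_COUNTS[stratum]
    df = pd.DataFrame.from_records(
        [(item, *rows[item]) for item in ITEMS],
        columns=["item", "total_best", "total_worst", "published_mean_bw", "published_rank"],
    ).set_index("item")
    df.attrs["stratum"] = stratum
    df.attrs["n_respondents"] = STRATUM_N[stratum]
    return df


#: Per-stratum published counting tables, items in catalog order.
COUNTING_TABLES: dict[str, pd.DataFrame] = {s: _counts_frame(s) for s in _RAW_COUNTS}

# Published maxdiff conditional-logit coefficients, myopathy = 0 reference:
# item -> (coefficient, ci_low, ci_high).
LOGIT_COEFFICIENTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "provider": {
        "severe_stroke": (7.85, 7.45, 8.23),
        "severe_mi": (6.73, 6.37, 7.08),
        "cancer": (6.62, 6.26, 6.97),
        "moderate_stroke": (5.41, 5.08, 5.75),
        "moderate_mi": (4.46, 4.13, 4.78),
        "heart_failure": (4.11, 3.79, 4.42),
        "acute_kidney_failure": (4.16, 3.84, 4.48),
        "type2_diabetes": (3.60, 3.28, 3.92),
        "liver_injury": (4.04, 3.72, 4.36),
        "unstable_angina": (2.42, 2.15, 2.70),
        "treatment_discontinuation": (0.90, 0.67, 1.13),
        "nausea_headache": (0.67, 0.44, 0.90),
        "myopathy": (0.0, 0.0, 0.0),
    },
    "total": {
        "severe_stroke": (6.81, 6.66, 6.96),
        "severe_mi": (5.86, 5.72, 5.99),
        "cancer": (5.76, 5.63, 5.90),
        "moderate_stroke": (4.52, 4.39, 4.65),
        "moderate_mi": (3.69, 3.57, 3.82),
        "heart_failure": (3.28, 3.16, 3.40),
        "acute_kidney_failure": (3.27, 3.15, 3.39),
        "type2_diabetes": (3.18, 3.06, 3.30),
        "liver_injury": (2.93, 2.81, 3.05),
        "unstable_angina": (1.94, 1.84, 2.05),
        "treatment_discontinuation": (0.80, 0.71, 0.90),
        "nausea_headache": (0.36, 0.27, 0.46),
        "myopathy": (0.0, 0.0, 0.0),
    },
    "urban": {
        "severe_stroke": (7.13, 6.90, 7.35),
        "severe_mi": (6.06, 5.86, 6.26),
        "cancer": (6.28, 6.07, 6.48),
        "moderate_stroke": (4.91, 4.72, 5.10),
        "moderate_mi": (4.05, 3.86, 4.23),
        "heart_failure": (3.51, 3.33, 3.68),
        "acute_kidney_failure": (3.58, 3.40, 3.76),
        "type2_diabetes": (3.32, 3.13, 3.50),
        "liver_injury": (3.26, 3.08, 3.44),
        "unstable_angina": (2.08, 1.90, 2.23),
        "treatment_discontinuation": (0.90, 0.76, 1.04),
        "nausea_headache": (0.30, 0.16, 0.44),
        "myopathy": (0.0, 0.0, 0.0),
    },
    "rural": {
        "severe_stroke": (6.58, 6.37, 6.78),
        "severe_mi": (5.73, 5.54, 5.92),
        "cancer": (5.34, 5.16, 5.52),
        "moderate_stroke": (4.20, 4.03, 4.37),
        "moderate_mi": (3.41, 3.25, 3.57),
        "heart_failure": (3.11, 2.95, 3.26),
        "acute_kidney_failure": (3.02, 2.86, 3.18),
        "type2_diabetes": (3.08, 2.92, 3.25),
        "liver_injury": (2.67, 2.51, 2.82),
        "unstable_angina": (1.84, 1.70, 1.98),
        "treatment_discontinuation": (0.72, 0.59, 0.85),
        "nausea_headache": (0.42, 0.28, 0.55),
        "myopathy": (0.0, 0.0, 0.0),
    },
}


def utilities_for(stratum: str = "total") -> dict[str, float]:
    """Latent item utilities for the simulator: the published logit
    coefficients of the given stratum (myopathy fixed at 0)."""
    return {item: LOGIT_COEFFICIENTS[stratum][item][0] for item in ITEMS}


# Covariate category frequencies per stratum (sample characteristics
# table).  Ages are (mean, sd, lower truncation): the general-population
# sample was recruited at ages 40+, providers are working-age adults.
PROFILE_MARGINALS: dict[str, dict] = {
    "provider": {
        "sex": {"male": 0.1744, "female": 0.8256},
        "age": (35.37, 7.58, 20.0),
        "education": {"none": 0.0, "primary": 0.0581, "middle": 0.1977, "high_plus": 0.7442},
        "statin_use": {"never": 0.9535, "current": 0.02325, "past": 0.02325},
        "morbidity": {"no": 0.9186, "yes": 0.0814},
        "fh_heart_disease": {"yes": 0.2384, "no": 0.7616, "unknown": 0.0},
        "fh_diabetes": {"yes": 0.2907, "no": 0.7093, "unknown": 0.0},
    },
    "urban": {
        "sex": {"male": 0.4477, "female": 0.5523},
        "age": (50.26, 8.28, 40.0),
        "education": {"none": 0.0245, "primary": 0.3742, "middle": 0.3341, "high_plus": 0.2672},
        "statin_use": {"never": 0.7929, "current": 0.1381, "past": 0.0690},
        "morbidity": {"no": 0.6682, "yes": 0.3318},
        "fh_heart_disease": {"yes": 0.3073, "no": 0.6882, "unknown": 0.0045},
        "fh_diabetes": {"yes": 0.3385, "no": 0.6593, "unknown": 0.0022},
    },
    "rural": {
        "sex": {"male": 0.4871, "female": 0.5129},
        "age": (49.31, 7.99, 40.0),
        "education": {"none": 0.0388, "primary": 0.6099, "middle": 0.2629, "high_plus": 0.0884},
        "statin_use": {"never": 0.8254, "current": 0.1315, "past": 0.0431},
        "morbidity": {"no": 0.7134, "yes": 0.2866},
        "fh_heart_disease": {"yes": 0.25, "no": 0.7435, "unknown": 0.0065},
        "fh_diabetes": {"yes": 0.3082, "no": 0.6896, "unknown": 0.0022},
    },
}
# The pooled general population ("total") uses the urban/rural mixture
# weights 449:464 at simulation time rather than separate marginals.
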