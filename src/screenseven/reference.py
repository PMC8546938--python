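"""Published summary statistics of the development study (n = 1245).

These printed marginals, subgroup high-PSE percentages, and crude odds
ratios are the calibration inputs of the synthetic-cohort generator and
the validation targets of the association analysis.  Per covariate level:
(N, column %, high-PSE row %); the first listed level is the reference.
"""

from __future__ import annotations

N_TOTAL = 1245
N_HIGH = 280
PREVALENCE_HIGH = 0.225
MEDIAN_TOTAL = 4
IQR_TOTAL = (3, 6)
SUBSCALE_MEDIANS = {"rules": 2, "routines": 0, "conditions": 2}
CUTOFF = 7
CUTOFF_PERCENTILE = 85.0

#: covariate -> level -> (N, column %, high-PSE row %)
MARGINALS: dict[str, dict[str, tuple[int, float, float]]] = {
    "maternal_age_band": {
        "lt30": (313, 25.1, 28.8),
        "ge30": (932, 74.9, 20.4),
    },
    "paternal_age_band": {
        "lt30": (126, 10.1, 20.6),
        "ge30": (1119, 89.9, 22.7),
    },
    "maternal_education_band": {
        "le12y": (297, 23.9, 36.4),
        "gt12y": (948, 76.1, 18.1),
    },
    "paternal_education_band": {
        "le12y": (226, 18.2, 33.6),
        "gt12y": (1019, 81.8, 20.0),
    },
    "maternal_occupation": {
        "working": (603, 48.4, 15.8),
        "not_working": (642, 51.6, 28.8),
    },
    "income": {
        "high": (696, 55.9, 21.0),
        "middle": (321, 25.8, 25.2),
        "low": (228, 18.3, 23.2),
    },
    "family_type": {
        "nuclear": (1076, 86.4, 21.1),
        "single_or_extended": (169, 13.6, 31.4),
    },
    "family_size_band": {
        "lt5": (940, 75.5, 19.3),
        "ge5": (305, 24.5, 32.5),
    },
    "settlement": {
        "urban": (930, 74.7, 20.3),
        "rural": (315, 25.3, 28.9),
    },
    "province": {
        "Afyon": (205, 16.5, 17.6),
        "Ankara": (861, 69.1, 23.8),
        "Mersin": (179, 14.4, 21.8),
    },
    "age_group": {
        "m24_48": (647, 52.0, 24.6),
        "m49_72": (598, 48.0, 20.2),
    },
    "sex": {
        "female": (610, 49.0, 20.8),
        "male": (635, 51.0, 24.1),
    },
    "daycare": {
        "mother": (561, 45.1, 30.1),
        "grandparent": (200, 16.1, 21.5),
        "childminder": (58, 4.6, 20.7),
        "kindergarten": (426, 34.2, 13.1),
    },
    "n_siblings_band": {
        "0": (442, 35.5, 17.4),
        "1": (580, 46.6, 21.7),
        "ge2": (223, 17.9, 34.5),
    },
    "postponing_needs": {
        "never": (846, 67.9, 16.1),
        "sometimes": (280, 22.5, 30.7),
        "frequently": (119, 9.6, 48.7),
    },
    "own_devices_band": {
        "0": (979, 78.6, 23.6),
        "1": (238, 19.1, 19.3),
        "ge2": (28, 2.3, 10.7),
    },
    "uses_touchscreen": {
        "no": (403, 32.4, 16.4),
        "yes": (842, 67.6, 25.4),
    },
    "video_gaming_band": {
        "none": (915, 73.5, 22.2),
        "lt1h": (239, 19.2, 18.8),
        "ge1h": (91, 7.3, 35.2),
    },
}

#: covariate -> level -> (crude OR, CI low, CI high) for non-reference levels
CRUDE_ORS: dict[str, dict[str, tuple[float, float, float]]] = {
    "maternal_age_band": {"ge30": (0.63, 0.47, 0.85)},
    "paternal_age_band": {"ge30": (1.13, 0.72, 1.79)},
    "maternal_education_band": {"gt12y": (0.39, 0.29, 0.52)},
    "paternal_education_band": {"gt12y": (0.49, 0.36, 0.68)},
    "maternal_occupation": {"not_working": (2.17, 1.64, 2.86)},
    "income": {"middle": (1.27, 0.93, 1.74), "low": (1.14, 0.80, 1.63)},
    "family_type": {"single_or_extended": (1.71, 1.20, 2.44)},
    "family_size_band": {"ge5": (2.02, 1.51, 2.69)},
    "settlement": {"rural": (1.59, 1.19, 2.13)},
    "province": {"Ankara": (1.47, 0.99, 2.17), "Mersin": (1.31, 0.79, 2.17)},
    "age_group": {"m49_72": (0.78, 0.60, 1.02)},
    "sex": {"male": (1.21, 0.92, 1.58)},
    "daycare": {
        "grandparent": (0.64, 0.43, 1.19),
        "childminder": (0.61, 0.31, 1.17),
        "kindergarten": (0.35, 0.25, 0.49),
    },
    "n_siblings_band": {"1": (1.32, 0.96, 1.80), "ge2": (2.50, 1.73, 3.62)},
    "postponing_needs": {
        "sometimes": (2.31, 1.69, 3.16),
        "frequently": (4.96, 3.31, 7.43),
    },
    "own_devices_band": {"1": (0.78, 0.55, 1.11), "ge2": (0.39, 0.12, 1.30)},
    "uses_touchscreen": {"yes": (1.74, 1.28, 2.36)},
    "video_gaming_band": {"lt1h": (0.81, 0.57, 1.17), "ge1h": (1.90, 1.20, 3.00)},
}

#: Share of children with missing anthropometric z-scores.
MISSING_ANTHRO_RATE = 0.226
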