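"""Reference tables from a published UAV survey of grassland desertification.

A published field survey of the Mu Us Sandy Land classified 30 nadir UAV
visible-light images (6 per desertification grade) by supervised SVM
classification and reported, per image, the reference FVC, the assigned
grade and the classification accuracy (OA, kappa).  It also reported, per
grade and per accuracy metric, a one-way ANOVA over the 19 vegetation
indices (TSS, df, MS, F, p).  These printed values are inputs here: the
FVC/grade rows exercise the grade-assignment bands, and the ANOVA rows are
audited for internal arithmetic consistency (MS = TSS/df, F = MS ratio).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["survey_images", "survey_anova_rows"]

# image_id, fvc_percent, grade, oa_percent, kappa
_SURVEY_IMAGES = [
    (1, 4.3243, "Severe", 99.1168, 0.9821),
    (2, 1.5050, "Severe", 99.011, 0.9783),
    (3, 4.0864, "Severe", 99.6525, 0.9922),
    (4, 3.3052, "Severe", 99.9252, 0.9966),
    (5, 3.3717, "Severe", 98.7145, 0.9642),
    (6, 2.8890, "Severe", 99.7404, 0.9939),
    (7, 13.2679, "High", 98.9788, 0.9671),
    (8, 18.3795, "High", 99.5751, 0.9725),
    (9, 6.7185, "High", 99.5239, 0.9879),
    (10, 16.2495, "High", 99.7815, 0.9956),
    (11, 15.9524, "High", 99.54, 0.9902),
    (12, 9.4557, "High", 98.8213, 0.9764),
    (13, 32.6411, "Moderate", 99.8111, 0.9676),
    (14, 43.2160, "Moderate", 99.9583, 0.99),
    (15, 31.7365, "Moderate", 99.5985, 0.9747),
    (16, 45.6735, "Moderate", 99.833, 0.982),
    (17, 31.8236, "Moderate", 99.6005, 0.9892),
    (18, 26.3766, "Moderate", 99.5415, 0.9894),
    (19, 53.0043, "Slight", 99.5556, 0.9855),
    (20, 55.3886, "Slight", 99.6876, 0.9937),
    (21, 51.5241, "Slight", 99.931, 0.9985),
    (22, 51.5331, "Slight", 99.8963, 0.9928),
    (23, 54.7885, "Slight", 99.6876, 0.9937),
    (24, 51.5424, "Slight", 99.9765, 0.9946),
    (25, 86.2322, "Non-desertification", 99.874, 0.9606),
    (26, 96.5132, "Non-desertification", 99.8873, 0.9619),
    (27, 83.4444, "Non-desertification", 99.4857, 0.9808),
    (28, 89.2501, "Non-desertification", 99.9279, 0.9674),
    (29, 71.6581, "Non-desertification", 99.5638, 0.9833),
    (30, 76.3327, "Non-desertification", 99.8111, 0.9676),
]

# grade, metric, tss_between, tss_within, tss_total, printed MS (between,
# within), printed F, printed p.  df are 18 / 95 / 113 in every block.
_SURVEY_ANOVA = [
    ("Severe", "oa_percent", 14840.249, 14083.024, 28923.272, 824.458, 148.242, 5.562, 0.000),
    ("Severe", "kappa", 5.895, 5.730, 11.625, 0.328, 0.060, 5.430, 0.000),
    ("Severe", "re", 1459.716, 1635.607, 3095.324, 81.095, 17.217, 4.710, 0.000),
    ("High", "oa_percent", 3454.562, 5136.480, 8591.042, 191.920, 54.068, 3.550, 0.000),
    ("High", "kappa", 3.914, 2.639, 6.553, 0.217, 0.028, 7.829, 0.000),
    ("High", "re", 23.606, 48.222, 71.828, 1.311, 0.508, 2.584, 0.002),
    ("Moderate", "oa_percent", 6957.370, 4364.848, 11322.218, 386.521, 45.946, 8.413, 0.000),
    ("Moderate", "kappa", 4.774, 1.531, 6.305, 0.265, 0.016, 16.451, 0.000),
    ("Moderate", "re", 2.998, 3.387, 6.385, 0.167, 0.036, 4.671, 0.000),
    ("Slight", "oa_percent", 11608.489, 2621.216, 14229.705, 644.916, 27.592, 23.374, 0.000),
    ("Slight", "kappa", 4.392, 0.871, 5.262, 0.244, 0.009, 26.617, 0.000),
    ("Slight", "re", 1.785, 0.674, 2.459, 0.099, 0.007, 13.981, 0.000),
    ("Non-desertification", "oa_percent", 18799.030, 98285.865, 117084.895, 1044.391, 1034.588, 1.009, 0.457),
    ("Non-desertification", "kappa", 5.465, 16.485, 21.950, 0.304, 0.174, 1.750, 0.044),
    ("Non-desertification", "re", 2.203, 6.871, 9.074, 0.122, 0.072, 1.692, 0.054),
]

#: (grade, metric) blocks whose printed F disagrees with the F recomputed
#: from the printed TSS/df by more than 2 units in the 3rd decimal — an
#: artefact of rounding in the printed TSS, flagged rather than asserted
#: (recomputed vs printed: 16.457/16.451, 26.613/26.617, 13.978/13.981).
ANOVA_AUDIT_FLAGGED = {("Moderate", "kappa"), ("Slight", "kappa"), ("Slight", "re")}

SURVEY_DF = (18, 95, 113)  # between / within / total, 19 indices x 6 images


def survey_images() -> pd.DataFrame:
    """Per-image reference FVC, grade and supervised-classification accuracy."""
    return pd.DataFrame(
        _SURVEY_IMAGES,
        columns=["image_id", "fvc_percent", "grade", "oa_percent", "kappa"],
    )


def survey_anova_rows() -> pd.DataFrame:
    """Per grade/metric printed ANOVA entries (TSS, printed MS/F/p)."""
    return pd.DataFrame(
        _SURVEY_ANOVA,
        columns=[
            "grade", "metric", "tss_between", "tss_within", "tss_total",
            "ms_between_printed", "ms_within_printed", "f_printed", "p_printed",
        ],
    )
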