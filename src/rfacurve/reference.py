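"""Bundled reference values from the published ex vivo bovine-liver study.

These numbers are a transcription of the study's printed summary tables and
are shipped so that comparison runs and the synthetic cohort presets work
without access to the original article or its deposited dataset.

Units: delta / dr / ar in percent, volumes in cm^3, impedances in ohms,
times in seconds.  All confidence intervals are the printed 95% intervals,
with n = 10 samples per group (50 ablations in total).

Known internal conflicts in the source (transcribed as printed, both values
kept here for the record):

* AR for SALINE23 appears as 167.7 in the running text but 187.67 in the
  group-means table; the table value is used as the default.
* DR at the refrigerated temperature level appears as 28.04 in the text but
  28.05 in the factor-means table; the table value is used as the default.
"""

from __future__ import annotations

GROUPS = ("PURERF", "SALINE23", "SALINE5", "DEI23", "DEI5")
INDICES = ("delta", "dr", "ar")

#: group -> (solution, temperature).  PURERF is the radiofrequency-only
#: control: no infused solution, hence no solution temperature.
GROUP_FACTORS: dict[str, tuple[str, str]] = {
    "PURERF": ("none", "none"),
    "SALINE23": ("saline", "ambient"),
    "SALINE5": ("saline", "refrigerated"),
    "DEI23": ("deionized", "ambient"),
    "DEI5": ("deionized", "refrigerated"),
}

#: Estimated marginal group means with 95% CI: index -> group -> (mean, lo, hi)
GROUP_MEANS: dict[str, dict[str, tuple[float, float, float]]] = {
    "delta": {
        "DEI23": (29.76, 18.04, 41.48),
        "DEI5": (23.10, 11.38, 34.82),
        "PURERF": (29.02, 17.30, 40.73),
        "SALINE23": (28.36, 16.64, 40.08),
        "SALINE5": (16.05, 4.33, 27.77),
    },
    "dr": {
        "DEI23": (29.18, 25.71, 32.64),
        "DEI5": (24.90, 21.43, 28.37),
        "PURERF": (22.41, 18.94, 25.88),
        "SALINE23": (21.09, 17.62, 24.56),
        "SALINE5": (31.19, 27.72, 34.66),
    },
    "ar": {
        "DEI23": (542.13, 387.56, 696.69),
        "DEI5": (284.60, 130.03, 439.16),
        "PURERF": (545.33, 390.76, 699.89),
        "SALINE23": (187.67, 33.11, 342.24),
        "SALINE5": (482.96, 328.40, 637.53),
    },
}

#: Factor-level marginal means with 95% CI (PURERF printed alongside each
#: factor as a standalone reference level): index -> factor -> level -> (mean, lo, hi)
FACTOR_MEANS: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "delta": {
        "solution": {
            "deionized": (26.43, 18.07, 34.78),
            "PURERF": (29.02, 17.20, 40.83),
            "saline": (22.21, 13.85, 30.56),
        },
        "temperature": {
            "ambient": (29.06, 20.89, 37.23),
            "refrigerated": (19.58, 11.41, 27.74),
            "PURERF": (29.02, 17.47, 40.57),
        },
    },
    "dr": {
        "solution": {
            "deionized": (27.04, 24.15, 29.92),
            "PURERF": (22.41, 18.33, 26.49),
            "saline": (26.14, 23.25, 29.03),
        },
        "temperature": {
            "ambient": (25.13, 22.30, 27.96),
            "refrigerated": (28.05, 25.22, 30.88),
            "PURERF": (22.41, 18.41, 26.41),
        },
    },
    "ar": {
        "solution": {
            "deionized": (413.36, 292.06, 534.67),
            "PURERF": (545.33, 373.78, 716.88),
            "saline": (335.32, 214.01, 456.62),
        },
        "temperature": {
            "ambient": (364.90, 242.58, 487.22),
            "refrigerated": (383.78, 261.46, 506.10),
            "PURERF": (545.33, 372.34, 718.31),
        },
    },
}

#: Ablation volume summaries: group -> (mean, sd, ci_lo, ci_hi), cm^3.
VOLUME_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "DEI23": (13.83, 4.73, 6.06, 20.0),
    "DEI5": (14.19, 4.20, 8.59, 19.7),
    "PURERF": (10.05, 2.67, 6.58, 13.5),
    "SALINE23": (16.78, 3.79, 11.4, 21.6),
    "SALINE5": (25.08, 12.40, 13.2, 47.5),
}

#: Published Spearman correlations between AR and ablation volume per group.
#: PURERF, DEI23 and SALINE5 are reported with p < 0.05; for DEI5 and
#: SALINE23 only "a direct relationship in all groups" is reported, so a
#: moderate positive default is used for synthesis.
SPEARMAN_AR_VOLUME: dict[str, float] = {
    "PURERF": 0.72,
    "DEI23": 0.73,
    "SALINE5": 0.78,
    "DEI5": 0.40,
    "SALINE23": 0.30,
}

#: Range of initial impedances observed across the 50 ablations, ohms.
INITIAL_IMPEDANCE_RANGE: tuple[float, float] = (66.0, 117.0)

#: Samples per group in the ex vivo cohort.
N_PER_GROUP = 10

TEXT_TABLE_CONFLICTS = (
    ("ar", "SALINE23", 167.7, 187.67),
    ("dr_refrigerated", "temperature", 28.04, 28.05),
)


def group_sd(index: str, group: str, n: int = N_PER_GROUP) -> float:
    """Per-sample standard deviation reconstructed from a printed 95% CI.

    The printed intervals are mean +/- 1.96 * sd / sqrt(n); inverting gives
    sd = (upper - mean) / 1.96 * sqrt(n).  This is an approximation (the
    study's intervals pool variance across groups), flagged as such in the
    package documentation.
    """
    mean, _, hi = GROUP_MEANS[index][group]
    return (hi - mean) / 1.96 * n**0.5
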