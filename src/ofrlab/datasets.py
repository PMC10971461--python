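"""Reference cohort: published per-subject OFR summary statistics.

A worked-example dataset of 12 school-age subjects — six stereo-normal
controls (HC1–HC6) and six stereo-deficient patients (P1–P6) — from a
dichoptic OFR study.  For each subject and stimulus condition (correlated /
anticorrelated) the printed values are: mean ± SD (N) of the vertical
movement-epoch eye displacement for upward and downward drift, the derived
OFR ± SD, the OFR SEM, and the correlated-vs-anticorrelated bootstrap
comparison p-value.

Direction-test and comparison p-values reported only as a bound ("<0.001")
are stored at the bound with ``p_comparison_censored`` set.  Values are
printed to three decimals, so derived columns recomputed from the per-
direction columns agree only to about ±0.001; the OFR and combined-SD columns
are consistent at that level for every row, while the printed SEM column is
consistent for only a subset of rows (frozen in ``SEM_CONSISTENT_ROWS``; the
remaining SEMs were evidently derived some other way, e.g. from a bootstrap).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort", "reference_comparison_pvalues", "SEM_CONSISTENT_ROWS"]

# subject, group, condition, mean_up, sd_up, n_up, mean_dw, sd_dw, n_dw,
# printed ofr, printed ofr_sd, printed ofr_sem
_ROWS = [
    ("HC1", "control", "correlated", 0.227, 0.234, 12, -0.133, 0.096, 13, 0.360, 0.253, 0.073),
    ("HC2", "control", "correlated", 0.220, 0.088, 6, -0.174, 0.105, 13, 0.394, 0.137, 0.045),
    ("HC3", "control", "correlated", 0.424, 0.157, 10, -0.277, 0.183, 11, 0.700, 0.241, 0.073),
    ("HC4", "control", "correlated", 0.293, 0.101, 13, -0.242, 0.186, 15, 0.534, 0.212, 0.057),
    ("HC5", "control", "correlated", 0.216, 0.131, 12, -0.204, 0.132, 11, 0.420, 0.186, 0.056),
    ("HC6", "control", "correlated", 0.157, 0.125, 16, -0.123, 0.152, 11, 0.280, 0.197, 0.054),
    ("P1", "patient", "correlated", 0.192, 0.119, 18, -0.116, 0.104, 18, 0.309, 0.158, 0.038),
    ("P2", "patient", "correlated", 0.124, 0.177, 14, -0.423, 0.276, 14, 0.547, 0.328, 0.088),
    ("P3", "patient", "correlated", 0.187, 0.104, 12, -0.173, 0.117, 9, 0.360, 0.157, 0.049),
    ("P4", "patient", "correlated", 0.090, 0.184, 12, -0.117, 0.141, 16, 0.207, 0.232, 0.065),
    ("P5", "patient", "correlated", 0.278, 0.136, 11, -0.157, 0.216, 10, 0.435, 0.255, 0.079),
    ("P6", "patient", "correlated", 0.126, 0.101, 14, -0.236, 0.176, 17, 0.362, 0.202, 0.049),
    ("HC1", "control", "anticorrelated", 0.102, 0.111, 9, -0.127, 0.041, 12, 0.230, 0.118, 0.038),
    ("HC2", "control", "anticorrelated", 0.168, 0.175, 11, 0.001, 0.149, 12, 0.167, 0.230, 0.064),
    ("HC3", "control", "anticorrelated", 0.158, 0.120, 8, -0.291, 0.171, 12, 0.450, 0.209, 0.065),
    ("HC4", "control", "anticorrelated", 0.232, 0.154, 10, -0.124, 0.049, 6, 0.356, 0.161, 0.054),
    ("HC5", "control", "anticorrelated", 0.100, 0.165, 15, -0.045, 0.188, 14, 0.145, 0.250, 0.065),
    ("HC6", "control", "anticorrelated", 0.158, 0.086, 16, 0.047, 0.289, 12, 0.111, 0.301, 0.084),
    ("P1", "patient", "anticorrelated", 0.163, 0.115, 17, -0.255, 0.141, 22, 0.418, 0.182, 0.040),
    ("P2", "patient", "anticorrelated", 0.155, 0.256, 12, -0.353, 0.172, 13, 0.508, 0.308, 0.089),
    ("P3", "patient", "anticorrelated", 0.143, 0.132, 9, -0.211, 0.127, 10, 0.354, 0.183, 0.059),
    ("P4", "patient", "anticorrelated", 0.131, 0.132, 13, -0.127, 0.091, 15, 0.258, 0.160, 0.043),
    ("P5", "patient", "anticorrelated", 0.288, 0.138, 6, -0.278, 0.094, 7, 0.566, 0.167, 0.069),
    ("P6", "patient", "anticorrelated", 0.187, 0.104, 17, -0.206, 0.117, 14, 0.393, 0.157, 0.042),
]

# comparison p (correlated vs anticorrelated OFR); censored: printed "<0.001"
_COMPARISON_P = {
    "HC1": (0.048, False), "HC2": (0.010, False), "HC3": (0.016, False),
    "HC4": (0.014, False), "HC5": (0.001, True), "HC6": (0.088, False),
    "P1": (0.092, False), "P2": (0.738, False), "P3": (0.936, False),
    "P4": (0.554, False), "P5": (0.184, False), "P6": (0.632, False),
}

#: (subject, condition) rows whose printed SEM agrees with
#: sqrt(sd_up^2/n_up + sd_dw^2/n_dw) within +/-0.001 (printed precision).
SEM_CONSISTENT_ROWS = frozenset({
    ("HC1", "correlated"), ("P1", "correlated"), ("P2", "correlated"),
    ("P3", "correlated"), ("P5", "correlated"),
    ("HC1", "anticorrelated"), ("HC3", "anticorrelated"), ("HC5", "anticorrelated"),
    ("P3", "anticorrelated"), ("P4", "anticorrelated"),
})


def reference_cohort() -> pd.DataFrame:
    """Return the cohort summary table, one row per subject x condition."""
    df = pd.DataFrame(_ROWS, columns=[
        "subject", "group", "condition",
        "mean_up", "sd_up", "n_up", "mean_dw", "sd_dw", "n_dw",
        "ofr_printed", "ofr_sd_printed", "ofr_sem_printed",
    ])
    df["p_comparison"] = df["subject"].map(lambda s: _COMPARISON_P[s][0])
    df["p_comparison_censored"] = df["subject"].map(lambda s: _COMPARISON_P[s][1])
    return df


def reference_comparison_pvalues() -> pd.DataFrame:
    """Per-subject comparison p-values (one row per subject, with group)."""
    rows = [
        {"subject": s, "group": "control" if s.startswith("HC") else "patient",
         "p_comparison": p, "censored": c}
        for s, (p, c) in _COMPARISON_P.items()
    ]
    return pd.DataFrame(rows)
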