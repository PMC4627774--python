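"""Demographics of the clinical validation cohort.

Per-subject descriptors of the 12 Parkinson's disease (PD) patients and 12
age-matched healthy elderly (HE) controls of the validation study: age, MMSE
(cognition, 0-30), and for the PD sample disease duration (years), UPDRS III
motor score, modified Hoehn & Yahr stage, and Freezing of Gait Questionnaire
score.  Used for descriptive statistics and the between-group Welch t-tests
that establish age/MMSE matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import descriptive_table

__all__ = ["he_sample", "pd_sample", "cohort_demographics", "demographic_summary"]

_HE = {
    "age": [63.4, 51.0, 68.5, 66.1, 67.6, 64.9, 59.1, 60.5, 65.8, 79.9, 52.0, 58.2],
    "gender": ["M", "M", "M", "F", "M", "M", "M", "F", "F", "M", "M", "F"],
    "mmse": [30, 30, 29, 29, 30, 30, 29, 26, 29, 29, 30, 30],
}

_PD = {
    "age": [58.8, 72.1, 77.5, 63.4, 65.5, 81.0, 61.8, 63.5, 63.2, 49.8, 60.6, 62.3],
    "gender": ["M", "M", "M", "F", "F", "M", "F", "M", "M", "M", "F", "F"],
    "mmse": [30, 30, 28, 24, 29, 30, 30, 28, 29, 30, 30, 28],
    "duration": [7, 3, 8, 14, 6, 2, 2, 4, 8, 5, 4, 3],
    "updrs3": [20, 33, 16, 24, 28, 37, 36, 14, 8, 38, 21, 22],
    "hy": [4, 2.5, 3, 2.5, 2.5, 2.5, 2, 1.5, 3, 2.5, 2.5, 3],
    "fogq": [22, 10, 6, 5, 2, 1, 0, 2, 8, 9, 1, 10],
}


def he_sample() -> pd.DataFrame:
    """Healthy-elderly control sample, one row per subject."""
    return pd.DataFrame(_HE)


def pd_sample() -> pd.DataFrame:
    """PD patient sample with clinical scale scores, one row per subject."""
    return pd.DataFrame(_PD)


def cohort_demographics() -> pd.DataFrame:
    """Both samples stacked long with a ``group`` column."""
    he = he_sample().assign(group="HE")
    pdd = pd_sample().assign(group="PD")
    return pd.concat([he, pdd], ignore_index=True)


def demographic_summary() -> pd.DataFrame:
    """Mean/SD per group and variable, plus Welch t-test p for age and MMSE.

    Returns a tidy frame with columns group, variable, n, mean, sd, and (for
    variables present in both groups) the two-sided Welch p-value.
    """
    he, pdd = he_sample(), pd_sample()
    rows = []
    for group, df in (("HE", he), ("PD", pdd)):
        for var in df.columns:
            if df[var].dtype.kind not in "if":
                continue
            v = df[var].to_numpy(dtype=float)
            rows.append(
                {"group": group, "variable": var, "n": len(v),
                 "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "p": np.nan}
            )
    out = pd.DataFrame(rows)
    for var in ("age", "mmse"):
        t = descriptive_table({"PD": pdd[var].to_numpy(float), "HE": he[var].to_numpy(float)})
        out.loc[out["variable"] == var, "p"] = t.attrs["p"]
    return out
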