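"""Shared fixtures: small simulated cohorts and an independent ANOVA oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from stridelab.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (4+4 subjects) at the default noise level."""
    cfg = CohortConfig(n_per_group={"PD": 4, "HE": 4})
    return generate_cohort(cfg, seed=20251001)


@pytest.fixture(scope="session")
def clean_cohort():
    """A tiny cohort with no sensor noise and no reference-device jitter."""
    cfg = CohortConfig(
        n_per_group={"PD": 3, "HE": 3},
        snr_db=100.0,
        timing_jitter=0.0,
        length_jitter=0.0,
    )
    return generate_cohort(cfg, seed=42)


def anova_ss_oracle(df: pd.DataFrame, between: str | None, within: list[str]) -> dict:
    """Brute-force sequential-SS decomposition via nested least squares.

    Independent of the package's moment-formula implementation: each model in
    a fixed hierarchy is a dense one-hot design matrix, and a term's SS is the
    drop in residual sum of squares when the term's columns are added.  For
    balanced (proportional) repeated-measures data the sequential SS equal the
    classical decomposition.
    """
    df = df.copy()
    y = df["value"].to_numpy(float)

    def onehot(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.ones((len(df), 1))
        keys = df[cols].astype(str).agg("|".join, axis=1)
        levels = sorted(keys.unique())
        return (keys.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    # hierarchy: grand mean; between; subject; then within main effects,
    # their interactions with between/subject; finally the within-within terms
    terms: list[tuple[str, list[str]]] = []
    if between:
        terms.append(("Group", [between]))
    terms.append(("Error (between)", ["subject"]))
    for w in within:
        terms.append((w, [w]))
        if between:
            terms.append((f"Group x {w}", [between, w]))
        terms.append((f"Error ({w})", ["subject", w]))
    if len(within) == 2:
        w1, w2 = within
        terms.append((f"{w1} x {w2}", [w1, w2]))
        if between:
            terms.append((f"Group x {w1} x {w2}", [between, w1, w2]))
        terms.append((f"Error ({w1} x {w2})", ["subject", w1, w2]))

    out: dict[str, float] = {}
    X = onehot([])
    base = rss(X)
    ss_total = float(((y - y.mean()) ** 2).sum())
    for name, cols in terms:
        X = np.column_stack([X, onehot(cols)])
        new = rss(X)
        out[name] = base - new
        base = new
    out["total"] = ss_total
    return out


def random_balanced_table(
    rng: np.random.Generator,
    n_per_group: int = 5,
    groups=("PD", "HE"),
    conditions=("self", "100", "110"),
    devices=("smartmove", "reference"),
) -> pd.DataFrame:
    rows = []
    for g in groups:
        for s in range(n_per_group):
            subj = f"{g}{s:02d}"
            for c, d in itertools.product(conditions, devices):
                rows.append(
                    {"subject": subj, "group": g, "condition": c, "device": d,
                     "measure": "m", "value": float(rng.normal(1.0, 0.3))}
                )
    return pd.DataFrame(rows)
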