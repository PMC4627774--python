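"""Mixed-factorial ANOVA with classical eta-squared effect sizes.

Device validation is framed statistically: the novel source of variance
(measurement Device) is entered into an ANOVA alongside the expected sources
(clinical Group, cueing condition RAC), and each term's classical eta-squared

    eta^2 = SS_effect / SS_total

quantifies the proportion of total variance it captures.  Conventionally,
eta^2 of about .02 is a small effect, .13 medium, .26 large.  A device whose
main effect and interactions stay below the small threshold while Group/RAC
effects are medium-to-large is measuring the phenomenon, not itself.

Three designs are supported, all with one observation per subject per cell:

* ``group_rac_device`` — Group (between) x RAC (3, within) x Device (2, within)
* ``group_device``     — Group (between) x Device (within), single condition
* ``rac_device``       — RAC x Device, both within, single group

The decomposition is the classical univariate repeated-measures one, with
subjects nested in Group: the between-subjects stratum splits into Group and
subject(Group); each within-subject effect is tested against its own
interaction-with-subject(Group) error stratum.  No sphericity correction is
applied by default.  The eta-squared denominator is the grand total SS
including all error strata (not partial eta-squared), so SS_effect / eta^2 is
one constant per table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "DESIGNS",
    "AnovaTable",
    "BalanceError",
    "DesignInfeasibleError",
    "casewise_delete",
    "mixed_anova",
    "eta_squared",
    "classify_effect_size",
    "descriptive_table",
    "read_subject_level_xlsx",
]

DESIGNS = ("group_rac_device", "group_device", "rac_device")

OUTCOME_COLUMNS = ["subject", "group", "condition", "device", "measure", "value"]


class BalanceError(ValueError):
    """Design cells are not fully crossed after casewise deletion."""


class DesignInfeasibleError(ValueError):
    """No subject has complete data for the requested design."""


@dataclass(frozen=True)
class AnovaTable:
    """Per-effect SS/df/MS/F/p/eta^2 plus error strata and the grand total."""

    table: pd.DataFrame
    ss_total: float
    design: str

    def __post_init__(self) -> None:
        ss_sum = float(self.table["SS"].sum())
        if not np.isclose(ss_sum, self.ss_total, rtol=1e-9, atol=1e-12):
            raise AssertionError(
                f"SS partition incomplete: sum {ss_sum} != total {self.ss_total}"
            )
        eff = self.table.dropna(subset=["eta2"])
        if len(eff):
            if (eff["eta2"] < 0).any() or (eff["eta2"] > 1).any():
                raise AssertionError("eta^2 outside [0, 1]")

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("Effect").loc[name]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["p"] = out["p"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
        out["eta2"] = out["eta2"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
        out.to_csv(path, index=False)


def eta_squared(ss_effect: float, ss_total: float) -> float:
    """Classical eta-squared: the fraction of total SS captured by an effect."""
    if ss_total <= 0:
        raise ValueError("ss_total must be > 0")
    if not 0 <= ss_effect <= ss_total * (1 + 1e-12):
        raise ValueError("ss_effect must lie in [0, ss_total]")
    return min(ss_effect / ss_total, 1.0)


def classify_effect_size(eta2: float) -> str:
    """Map eta^2 to the conventional label (.02 small, .13 medium, .26 large)."""
    if not 0 <= eta2 <= 1:
        raise ValueError("eta2 must lie in [0, 1]")
    if eta2 < 0.02:
        return "negligible"
    if eta2 < 0.13:
        return "small"
    if eta2 < 0.26:
        return "medium"
    return "large"


def _required_levels(table: pd.DataFrame, design: str) -> dict[str, list]:
    within = {"device": sorted(table["device"].unique())}
    if design in ("group_rac_device", "rac_device"):
        within["condition"] = sorted(table["condition"].unique())
    return within


def casewise_delete(table: pd.DataFrame, design: str) -> tuple[pd.DataFrame, list]:
    """Remove every subject missing any condition x device cell of the design.

    Repeated-measures ANOVA permits no missing values; rather than impute, the
    whole subject is dropped.  Returns the reduced table and the removed
    subject ids.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    within = _required_levels(table, design)
    cols = list(within)
    n_cells = int(np.prod([len(v) for v in within.values()]))
    counts = table.groupby("subject")[cols].apply(
        lambda df: df.drop_duplicates().shape[0]
    )
    complete = counts[counts == n_cells].index
    removed = sorted(set(table["subject"]) - set(complete))
    kept = table[table["subject"].isin(complete)].copy()
    if kept.empty:
        raise DesignInfeasibleError("casewise deletion removed every subject")
    return kept, removed


def _pivot(table: pd.DataFrame, design: str) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Return Y[s, j, k], per-subject group codes, and within-level lists.

    j indexes the first within factor (condition where applicable, else a
    singleton), k indexes device.
    """
    within = _required_levels(table, design)
    cond_levels = within.get("condition", [None])
    dev_levels = within["device"]
    idx_cols = ["condition", "device"] if "condition" in within else ["device"]
    wide = table.pivot_table(
        index=["subject", "group"], columns=idx_cols, values="value", aggfunc="mean"
    )
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.get_level_values("subject").tolist()
        raise BalanceError(f"missing cells for subjects {bad}; run casewise_delete first")
    subjects = wide.index.get_level_values("subject").to_numpy()
    groups = wide.index.get_level_values("group").to_numpy()
    a, b = len(cond_levels), len(dev_levels)
    Y = np.empty((len(subjects), a, b))
    for jj, cl in enumerate(cond_levels):
        for kk, dl in enumerate(dev_levels):
            key = (cl, dl) if cl is not None else dl
            Y[:, jj, kk] = wide[key].to_numpy()
    return Y, groups, cond_levels, dev_levels


def _f_row(ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff if df_eff > 0 else np.nan
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if not np.isfinite(ms_err) or ms_err <= 0:
        # zero error variance: F undefined (flagged as inf when the effect is real)
        f = np.inf if ss_eff > 1e-300 else np.nan
        p = 0.0 if ss_eff > 1e-300 else np.nan
        return ms_eff, f, p
    f = ms_eff / ms_err
    p = float(sp_stats.f.sf(f, df_eff, df_err))
    return ms_eff, f, p


def mixed_anova(table: pd.DataFrame, design: str, measure: str | None = None) -> AnovaTable:
    """Univariate mixed-factorial repeated-measures ANOVA.

    Parameters
    ----------
    table : DataFrame
        Long format with columns subject, group, condition, device, value
        (and optionally measure).  One value per subject per cell; the table
        must be balanced — run :func:`casewise_delete` first.
    design : {"group_rac_device", "group_device", "rac_device"}
        ``group_device`` expects a single condition (e.g. self-paced only);
        ``rac_device`` expects a single group and omits all Group terms.
    measure : str, optional
        Filter ``table`` to one measure before analysis.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    df = table.copy()
    if measure is not None:
        df = df[df["measure"] == measure]
    if df.empty:
        raise DesignInfeasibleError("empty outcome table")
    if design == "rac_device" and df["group"].nunique() > 1:
        raise ValueError("rac_device design requires a single group; filter first")
    if design == "group_device" and df["condition"].nunique() > 1:
        raise ValueError("group_device design requires a single condition; filter first")

    Y, groups, cond_levels, dev_levels = _pivot(df, design)
    has_group = design != "rac_device"
    has_cond = design != "group_device"

    rows = _decompose(Y, groups if has_group else None)

    # human-readable effect names per design
    rename = {"W1": "RAC", "W2": "Device"}
    if not has_cond:
        # only device varies within; it sits in the W2 slot by construction
        rename = {"W2": "Device"}
    out_rows = []
    for r in rows:
        name = r["Effect"]
        for key, label in rename.items():
            name = name.replace(key, label)
        name = name.replace("Group x ", "Group × ").replace(" x ", " × ")
        out_rows.append({**r, "Effect": name})
    tab = pd.DataFrame(out_rows)
    ss_total = float(tab["SS"].sum())
    tab["eta2"] = np.where(tab["is_effect"], tab["SS"] / ss_total, np.nan)
    tab["effect_size"] = [
        classify_effect_size(e) if np.isfinite(e) else "" for e in tab["eta2"]
    ]
    tab = tab.drop(columns=["is_effect"])
    return AnovaTable(table=tab, ss_total=ss_total, design=design)


def _decompose(Y: np.ndarray, groups: np.ndarray | None) -> list[dict]:
    """Classical moment-based SS decomposition for Y[s, j, k].

    ``groups`` gives each subject's between-group label, or ``None`` for a
    single-group (fully within) design.  Handles singleton within factors by
    collapsing the corresponding terms.
    """
    N, a, b = Y.shape
    if groups is None:
        groups = np.zeros(N, dtype=int)
    g_levels, g_idx = np.unique(groups, return_inverse=True)
    G = len(g_levels)
    n_g = np.bincount(g_idx)

    GM = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_g = np.array([Y[g_idx == g].mean() for g in range(G)])
    m_j = Y.mean(axis=(0, 2))
    m_k = Y.mean(axis=(0, 1))
    m_jk = Y.mean(axis=0)
    m_gj = np.stack([Y[g_idx == g].mean(axis=(0, 2)) for g in range(G)])
    m_gk = np.stack([Y[g_idx == g].mean(axis=(0, 1)) for g in range(G)])
    m_gjk = np.stack([Y[g_idx == g].mean(axis=0) for g in range(G)])
    m_sj = Y.mean(axis=2)
    m_sk = Y.mean(axis=1)

    ss_total = float(((Y - GM) ** 2).sum())

    rows: list[dict] = []

    def add(effect, ss, df, error=None, is_effect=True):
        rows.append({"Effect": effect, "SS": float(ss), "df": int(df),
                     "error": error, "is_effect": is_effect})

    # between-subjects stratum
    if G > 1:
        ss_group = a * b * float((n_g * (m_g - GM) ** 2).sum())
        ss_subj = a * b * float(((m_s - m_g[g_idx]) ** 2).sum())
        add("Group", ss_group, G - 1, error="Error (between)")
        add("Error (between)", ss_subj, N - G, is_effect=False)
    else:
        ss_subj = a * b * float(((m_s - GM) ** 2).sum())
        add("Error (between)", ss_subj, N - 1, is_effect=False)

    accounted = sum(r["SS"] for r in rows)

    if a > 1:
        ss_w1 = N * b * float(((m_j - GM) ** 2).sum())
        add("W1", ss_w1, a - 1, error="Error (W1)")
        if G > 1:
            dev = m_gj - m_g[:, None] - m_j[None, :] + GM
            ss_gw1 = b * float((n_g[:, None] * dev**2).sum())
            add("Group x W1", ss_gw1, (G - 1) * (a - 1), error="Error (W1)")
        dev = m_sj - m_s[:, None] - m_gj[g_idx] + m_g[g_idx, None]
        ss_w1s = b * float((dev**2).sum())
        add("Error (W1)", ss_w1s, (a - 1) * (N - G), is_effect=False)
        accounted = sum(r["SS"] for r in rows)

    if b > 1:
        ss_w2 = N * a * float(((m_k - GM) ** 2).sum())
        add("W2", ss_w2, b - 1, error="Error (W2)")
        if G > 1:
            dev = m_gk - m_g[:, None] - m_k[None, :] + GM
            ss_gw2 = a * float((n_g[:, None] * dev**2).sum())
            add("Group x W2", ss_gw2, (G - 1) * (b - 1), error="Error (W2)")
        dev = m_sk - m_s[:, None] - m_gk[g_idx] + m_g[g_idx, None]
        ss_w2s = a * float((dev**2).sum())
        add("Error (W2)", ss_w2s, (b - 1) * (N - G), is_effect=False)
        accounted = sum(r["SS"] for r in rows)

    if a > 1 and b > 1:
        dev = m_jk - m_j[:, None] - m_k[None, :] + GM
        ss_w12 = N * float((dev**2).sum())
        add("W1 x W2", ss_w12, (a - 1) * (b - 1), error="Error (W1 x W2)")
        if G > 1:
            dev = (
                m_gjk
                - m_gj[:, :, None]
                - m_gk[:, None, :]
                - m_jk[None, :, :]
                + m_g[:, None, None]
                + m_j[None, :, None]
                + m_k[None, None, :]
                - GM
            )
            ss_gw12 = float((n_g[:, None, None] * dev**2).sum())
            add("Group x W1 x W2", ss_gw12, (G - 1) * (a - 1) * (b - 1),
                error="Error (W1 x W2)")
        accounted = sum(r["SS"] for r in rows)
        ss_w12s = ss_total - accounted
        add("Error (W1 x W2)", max(ss_w12s, 0.0), (a - 1) * (b - 1) * (N - G),
            is_effect=False)

    # F, p per effect against its stratum error
    by_name = {r["Effect"]: r for r in rows}
    for r in rows:
        if r["is_effect"]:
            err = by_name[r["error"]]
            ms, f, p = _f_row(r["SS"], r["df"], err["SS"], err["df"])
            r.update(MS=ms, F=f, p=p)
        else:
            r.update(MS=r["SS"] / r["df"] if r["df"] > 0 else np.nan,
                     F=np.nan, p=np.nan)
        r.pop("error", None)
    return rows


def descriptive_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group mean and sample SD plus a Welch two-sample t-test.

    ``groups`` maps two group labels to value arrays.  Returns a one-row
    DataFrame per group with mean/SD/n, and attaches ``t``/``p`` (two-sided,
    unequal-variance) as DataFrame attrs.  With zero variance in both groups
    the t statistic is flagged as NaN.
    """
    if len(groups) != 2:
        raise ValueError("descriptive_table expects exactly two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
    (name_a, va), (name_b, vb) = [(k, np.asarray(v, float)) for k, v in groups.items()]
    rows = []
    for name, v in ((name_a, va), (name_b, vb)):
        rows.append({"group": name, "n": len(v), "mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=1))})
    out = pd.DataFrame(rows)
    if np.std(va, ddof=1) == 0 and np.std(vb, ddof=1) == 0:
        t, p = np.nan, np.nan
    else:
        t, p = sp_stats.ttest_ind(va, vb, equal_var=False)
    out.attrs["t"] = float(t) if np.isfinite(t) else np.nan
    out.attrs["p"] = float(p) if np.isfinite(p) else np.nan
    return out


# --- subject-level XLSX ingestion -------------------------------------------

_CONDITION_TOKENS = {
    "self": "self", "selfpaced": "self", "sp": "self", "uncued": "self",
    "100": "100", "rac100": "100", "100rac": "100",
    "110": "110", "rac110": "110", "110rac": "110",
}
_DEVICE_TOKENS = {
    "smartmove": "smartmove", "sm": "smartmove", "phone": "smartmove", "app": "smartmove",
    "footswitch": "reference", "fsw": "reference", "fs": "reference",
    "gaitrite": "reference", "walkway": "reference", "mat": "reference",
}
_MEASURE_TOKENS = {"m": "delta_M", "mean": "delta_M", "cv": "delta_CV"}


def _parse_outcome_column(name: str) -> tuple[str, str, str] | None:
    """Map a wide-format column header to (condition, device, measure)."""
    tokens = [t for t in re.split(r"[^A-Za-z0-9]+", str(name).lower()) if t]
    cond = dev = meas = None
    for t in tokens:
        if t in _CONDITION_TOKENS:
            cond = _CONDITION_TOKENS[t]
        elif t in _DEVICE_TOKENS:
            dev = _DEVICE_TOKENS[t]
        elif t in _MEASURE_TOKENS:
            meas = _MEASURE_TOKENS[t]
    if cond and dev:
        return cond, dev, meas or "delta_M"
    return None


def read_subject_level_xlsx(path, measure_hint: str | None = None) -> pd.DataFrame:
    """Read a wide subject-level outcome workbook into the long outcome format.

    Expects one row per subject with a subject-id column, a group column
    (PD/HE), and one numeric column per condition x device (x measure) cell
    whose header names the levels (e.g. ``self_smartmove_CV``).  Column
    layout is auto-detected from header tokens; unrecognizable layouts raise
    a loud error rather than guessing.
    """
    wide = pd.read_excel(path)
    cols = list(wide.columns)
    subj_col = next(
        (c for c in cols if str(c).strip().lower() in ("subject", "subj", "id", "participant")),
        cols[0],
    )
    group_col = next((c for c in cols if str(c).strip().lower() == "group"), None)
    records = []
    parsed_any = False
    for c in cols:
        if c in (subj_col, group_col):
            continue
        parsed = _parse_outcome_column(c)
        if parsed is None:
            continue
        parsed_any = True
        cond, dev, meas = parsed
        if measure_hint:
            meas = measure_hint
        for _, row in wide.iterrows():
            group = str(row[group_col]) if group_col else _infer_group(row[subj_col])
            records.append(
                {"subject": str(row[subj_col]), "group": group, "condition": cond,
                 "device": dev, "measure": meas, "value": float(row[c])}
            )
    if not parsed_any:
        raise ValueError(
            f"{path}: could not auto-detect condition/device columns from headers "
            f"{cols}; expected tokens like 'self'/'100'/'110' and "
            f"'smartmove'/'footswitch'/'gaitrite'"
        )
    return pd.DataFrame.from_records(records)


def _infer_group(subject_id) -> str:
    s = str(subject_id).upper()
    if s.startswith("PD"):
        return "PD"
    if s.startswith("HE") or s.startswith("HC"):
        return "HE"
    raise ValueError(f"cannot infer group from subject id {subject_id!r}; add a group column")
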