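"""Group comparison, correlation and ROC statistics for density cohorts.

Two-sample t-tests (Welch by default), Pearson correlation with the
t-transform p-value, and empirical ROC analysis with tie-corrected AUC
(equivalent to the Mann-Whitney statistic U/(n1*n2)), DeLong 95% CI,
Youden-optimal cutoff and likelihood ratios — the statistical surface
reported for case/control OCTA density cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    group_means: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.t * self.mean_diff < 0:
            raise ValueError("sign(t) must equal sign(mean_diff)")


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("Pearson r outside [-1, 1]")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    direction: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("AUC outside its own confidence interval")


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _as_clean_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def t_test(a, b, variant: str = "welch") -> TTestResult:
    """Two-sample t-test; Welch (unequal variance) by default.

    Student df = n1+n2-2; Welch df by the Welch-Satterthwaite formula.
    Two zero-variance samples with equal means give t=0, p=1 by convention.
    """
    a = _as_clean_array(a, "a")
    b = _as_clean_array(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    mean_diff = mean_a - mean_b
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if mean_a == mean_b:
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0, (mean_a, mean_b))
        t = np.inf * np.sign(mean_diff)
        return TTestResult(float(t), float(len(a) + len(b) - 2), 0.0, mean_diff, (mean_a, mean_b))
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    if variant == "student":
        df = float(len(a) + len(b) - 2)
    else:
        na, nb = len(a), len(b)
        df = float(
            (va / na + vb / nb) ** 2
            / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        )
    return TTestResult(float(res.statistic), df, float(res.pvalue), mean_diff, (mean_a, mean_b))


def pearson(x, y) -> CorrResult:
    """Pearson correlation with a two-sided p-value (t-transform, n-2 df)."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_points(values: np.ndarray, is_case: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve: one row per distinct threshold (positive iff
    value >= threshold), with sensitivity and specificity columns."""
    order = np.argsort(values)[::-1]
    v, y = values[order], is_case[order]
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    rows = [{"threshold": np.inf, "sensitivity": 0.0, "specificity": 1.0}]
    tp = fp = 0
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and v[j] == v[i]:  # process ties together
            tp += int(y[j])
            fp += int(~y[j])
            j += 1
        rows.append(
            {"threshold": float(v[i]), "sensitivity": tp / n_case,
             "specificity": 1.0 - fp / n_ctrl}
        )
        i = j
    return pd.DataFrame(rows)


def _auc_trapezoid(points: pd.DataFrame) -> float:
    fpr = 1.0 - points["specificity"].to_numpy()
    tpr = points["sensitivity"].to_numpy()
    return float(np.trapezoid(tpr, fpr))


def delong_ci(values: np.ndarray, is_case: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """DeLong variance estimate and CI for the AUC of case-high scores.

    Uses the placement values (structural components): V10[i] = mean over
    controls of psi(case_i, ctrl_j), V01[j] analogous, with
    psi = 1[x>y] + 0.5*1[x=y].  The CI is truncated to [0, 1].
    """
    cases = values[is_case]
    ctrls = values[~is_case]
    m, n = len(cases), len(ctrls)
    psi = (cases[:, None] > ctrls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == ctrls[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def roc(values, labels, direction: str = "auto", case_label=None) -> RocResult:
    """Empirical ROC analysis of a marker against case/control labels.

    AUC is tie-corrected (trapezoid over the empirical curve, identical to
    Mann-Whitney U/(n1*n2)); the 95% CI is DeLong's; the operating cutoff
    maximizes Youden's J, reporting sensitivity, specificity, LR+ and LR-.
    ``direction`` orients the marker: ``case_high`` treats large values as
    case-like, ``case_low`` small values, ``auto`` picks whichever gives
    AUC >= 0.5 and records the choice.
    """
    values = _as_clean_array(values, "values")
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must be paired")
    uniq = pd.unique(labels)
    if case_label is None:
        if "case" in uniq:
            case_label = "case"
        elif len(uniq) == 2:
            case_label = uniq[1]
        else:
            raise ValueError("need exactly two classes or an explicit case_label")
    is_case = labels == case_label
    if is_case.all() or not is_case.any():
        raise ValueError("both classes must be present")

    def analyse(v, dir_name):
        pts = roc_points(v, is_case)
        auc = _auc_trapezoid(pts)
        return pts, auc, dir_name

    if direction == "auto":
        pts, auc, dir_name = analyse(values, "case_high")
        if auc < 0.5:
            pts, auc, dir_name = analyse(-values, "case_low")
    elif direction == "case_high":
        pts, auc, dir_name = analyse(values, "case_high")
    elif direction == "case_low":
        pts, auc, dir_name = analyse(-values, "case_low")
    else:
        raise ValueError(f"unknown direction {direction!r}")

    oriented = values if dir_name == "case_high" else -values
    auc_dl, ci_low, ci_high = delong_ci(oriented, is_case)
    if not np.isclose(auc, auc_dl):  # trapezoid and pairwise forms must agree
        raise RuntimeError(f"ROC internal inconsistency: {auc} vs {auc_dl}")
    auc = auc_dl  # share floats with the CI so ci_low <= auc <= ci_high exactly

    youden = pts["sensitivity"] + pts["specificity"] - 1.0
    best = int(youden.to_numpy().argmax())
    sens = float(pts["sensitivity"].iloc[best])
    spec = float(pts["specificity"].iloc[best])
    cutoff = float(pts["threshold"].iloc[best])
    if dir_name == "case_low" and np.isfinite(cutoff):
        cutoff = -cutoff  # report on the original scale
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else np.inf
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else np.inf
    return RocResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high, cutoff=cutoff,
        sensitivity=sens, specificity=spec, lr_pos=float(lr_pos), lr_neg=float(lr_neg),
        direction=dir_name,
    )


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def region_comparison_table(
    records: pd.DataFrame,
    level: str = "subject",
    variant: str = "welch",
    adjust: str | None = None,
    case_group: str = "case",
) -> pd.DataFrame:
    """Per layer/scheme/region/class/metric: group means +/- SD, t, p and
    ROC AUC with DeLong CI; optional Benjamini-Hochberg column.

    ``level`` names the analysis unit carried in the records' ``eye`` column
    ('subject' expects OU both-eye averages, 'eye' the per-eye rows); it is
    recorded in the output so tables are explicit about their unit.
    Cells present in only one group are flagged, never silently dropped.
    """
    if level not in ("subject", "eye"):
        raise ValueError("level must be 'subject' or 'eye'")
    rows = []
    keys = ["layer", "scheme", "region", "vessel_class", "metric"]
    for key_vals, cell in records.groupby(keys, sort=False):
        groups = dict(list(cell.groupby("group")))
        ctrl_groups = [g for g in groups if g != case_group]
        row = dict(zip(keys, key_vals))
        row["level"] = level
        case = groups.get(case_group)
        ctrl = groups[ctrl_groups[0]] if ctrl_groups else None
        if case is None or ctrl is None or len(case) < 2 or len(ctrl) < 2:
            row.update({"flag": "missing_group", "n_case": 0 if case is None else len(case),
                        "n_control": 0 if ctrl is None else len(ctrl)})
            rows.append(row)
            continue
        cv, hv = case["value"].to_numpy(), ctrl["value"].to_numpy()
        tt = t_test(hv, cv, variant=variant)  # control minus case, as in HC-vs-patient tables
        values = np.concatenate([cv, hv])
        labels = np.array(["case"] * len(cv) + ["control"] * len(hv))
        try:
            rr = roc(values, labels)
            roc_cols = {"auc": rr.auc, "auc_ci_low": rr.ci_low, "auc_ci_high": rr.ci_high,
                        "roc_direction": rr.direction}
        except ValueError:
            roc_cols = {"auc": np.nan, "auc_ci_low": np.nan, "auc_ci_high": np.nan,
                        "roc_direction": "undefined"}
        row.update(
            {
                "n_case": len(cv), "n_control": len(hv),
                "mean_case": cv.mean(), "sd_case": cv.std(ddof=1),
                "mean_control": hv.mean(), "sd_control": hv.std(ddof=1),
                "t": tt.t, "df": tt.df, "p": tt.p, "flag": "",
                **roc_cols,
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    if adjust == "bh" and "p" in table:
        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
        table["p_bh"] = adj
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table
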