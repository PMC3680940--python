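"""Agreement, discrimination, risk-profile and model-comparison statistics.

Covers the comparison battery applied to a reference percent-density read
versus the automated mimic, and to the case-control risk models: Pearson r
with Fisher-z confidence interval; Bland–Altman limits of agreement; odds
ratios across PD categories by unconditional logistic regression; ROC AUC with
DeLong variance and the DeLong test for two correlated AUCs; a deviance /
likelihood-ratio / AIC table over a set of nested logistic models; and a
two-group cohort summary (t / Wilcoxon rank-sum / chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["pearson_ci", "bland_altman", "category_or", "roc_auc",
           "delong_compare", "deviance_table", "summarize_cohort",
           "PD_CATEGORY_BREAKS", "PD_DISPLAY_BREAKS"]

# analysis categories: a low (<5%) class, 5-10, 10-25, and the merged upper
# classes (25-50 / 50-75 / >75 combined)
PD_CATEGORY_BREAKS = (0.0, 5.0, 10.0, 25.0, 100.0)
# display-style six-category breaks
PD_DISPLAY_BREAKS = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0)


def pearson_ci(x, y, level: float = 0.95):
    """Pearson r with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return {"r": r, "ci_low": float(lo), "ci_high": float(hi), "n": int(x.size)}


def bland_altman(x, y):
    """Bland–Altman agreement of two paired measurements.

    Differences ``d = x - y`` against means ``m = (x + y)/2``; returns the mean
    difference, ±1.96·SD limits of agreement, and the least-squares slope,
    intercept and correlation of d on m (a nonzero slope indicates
    magnitude-dependent bias).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    d = x - y
    m = (x + y) / 2.0
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    out = {"mean_diff": mean_diff,
           "lower_limit": mean_diff - 1.96 * sd,
           "upper_limit": mean_diff + 1.96 * sd,
           "sd_diff": sd, "n": int(x.size)}
    if m.std() > 0 and sd > 0:
        slope, intercept = np.polyfit(m, d, 1)
        out["slope"] = float(slope)
        out["intercept"] = float(intercept)
        out["r"] = float(np.corrcoef(m, d)[0, 1])
    else:
        out["slope"], out["intercept"], out["r"] = 0.0, mean_diff, 0.0
    return out


def category_or(values, status, breaks=PD_CATEGORY_BREAKS, level: float = 0.95
                ) -> pd.DataFrame:
    """Odds ratios for density categories by unconditional logistic regression.

    The lowest category is the reference.  Returns one row per category with
    counts, OR and Wald confidence limits (reference row has OR 1).
    """
    values = np.asarray(values, dtype=np.float64)
    status = np.asarray(status, dtype=np.float64)
    edges = list(breaks)
    cats = pd.cut(values, bins=edges, right=False, include_lowest=True,
                  labels=False)
    cats = pd.Series(cats).fillna(len(edges) - 2).astype(int)  # top edge closed
    n_cat = len(edges) - 1
    ref = 0
    if not ((cats[status == 1] == ref).any() and (cats[status == 0] == ref).any()):
        raise ValueError("reference category empty in cases or controls")
    dummies = np.zeros((len(values), n_cat - 1))
    for c in range(1, n_cat):
        dummies[:, c - 1] = (cats == c).astype(float)
    X = sm.add_constant(dummies)
    res = sm.Logit(status, X).fit(disp=0)
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    rows = [{"category": f"[{edges[0]:g},{edges[1]:g})",
             "n_cases": int(((cats == 0) & (status == 1)).sum()),
             "n_controls": int(((cats == 0) & (status == 0)).sum()),
             "or": 1.0, "ci_low": np.nan, "ci_high": np.nan}]
    for c in range(1, n_cat):
        b = res.params[c]
        se = res.bse[c]
        hi_edge = f"{edges[c + 1]:g}" if c + 1 < len(edges) else "inf"
        rows.append({
            "category": f"[{edges[c]:g},{edges[c+1]:g})",
            "n_cases": int(((cats == c) & (status == 1)).sum()),
            "n_controls": int(((cats == c) & (status == 0)).sum()),
            "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - zcrit * se)),
            "ci_high": float(np.exp(b + zcrit * se)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _placements(scores, labels):
    """DeLong structural components: per-case and per-control placement
    values.  AUC is the mean of either set."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    cases = s[y == 1]
    ctrls = s[y == 0]
    if cases.size == 0 or ctrls.size == 0:
        raise ValueError("both classes must be present")
    # V10[i] = P(ctrl < case_i) + 0.5 P(ctrl == case_i)
    order = np.argsort(ctrls, kind="mergesort")
    cs = ctrls[order]
    lt = np.searchsorted(cs, cases, side="left")
    le = np.searchsorted(cs, cases, side="right")
    v10 = (lt + 0.5 * (le - lt)) / ctrls.size
    order = np.argsort(cases, kind="mergesort")
    xs = cases[order]
    lt = np.searchsorted(xs, ctrls, side="left")
    le = np.searchsorted(xs, ctrls, side="right")
    v01 = 1.0 - (lt + 0.5 * (le - lt)) / cases.size
    return v10, v01


def roc_auc(scores, labels, level: float = 0.95):
    """AUC (Mann–Whitney with the 1/2 tie convention) with DeLong SE/CI."""
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    return {"auc": auc, "se": se,
            "ci_low": max(0.0, auc - zcrit * se),
            "ci_high": min(1.0, auc + zcrit * se),
            "n_cases": m, "n_controls": n}


def delong_compare(scores_a, scores_b, labels):
    """DeLong test for two correlated AUCs on the same subjects; returns the
    AUC difference, its SE, z and the two-sided p-value."""
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]))
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]))
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return {"auc_a": auc_a, "auc_b": auc_b, "diff": 0.0,
                    "se": 0.0, "z": 0.0, "p": 1.0}
        raise FloatingPointError("degenerate DeLong variance with unequal AUCs")
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff,
            "se": float(np.sqrt(var)), "z": float(z), "p": float(p)}


# ---------------------------------------------------------------------------
# deviance / LRT / AIC table
# ---------------------------------------------------------------------------

def _logit_deviance(y, X=None):
    """Residual deviance and parameter count of a logistic fit (intercept-only
    when X is None)."""
    y = np.asarray(y, dtype=np.float64)
    if X is None:
        Xd = np.ones((y.size, 1))
    else:
        Xd = sm.add_constant(np.asarray(X, dtype=np.float64))
    res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
    return float(res.deviance), int(Xd.shape[1])


def deviance_table(models: dict, status, pd_reference_models: dict | None = None
                   ) -> pd.DataFrame:
    """Goodness-of-fit table for a set of logistic models of case status.

    ``models`` maps model name -> covariate matrix (None for the null model).
    ``pd_reference_models`` maps model name -> name of the PD-only model it
    nests (for the second LRT column): P1 tests each model against the null,
    P2 against its stated PD-only reference.  AIC = deviance + 2 * parameters.
    """
    status = np.asarray(status, dtype=np.float64)
    results = {}
    for name, X in models.items():
        dev, k = _logit_deviance(status, X)
        results[name] = {"deviance": dev, "k": k}
    null_name = next((n for n, X in models.items() if X is None), None)
    if null_name is None:
        dev0, k0 = _logit_deviance(status, None)
    else:
        dev0 = results[null_name]["deviance"]
        k0 = results[null_name]["k"]
    rows = []
    for name, X in models.items():
        dev, k = results[name]["deviance"], results[name]["k"]
        row = {"model": name, "deviance": dev, "aic": dev + 2 * k,
               "df": k}
        if X is None:
            row["p1"] = np.nan
            row["p2"] = np.nan
        else:
            row["p1"] = float(sps.chi2.sf(dev0 - dev, k - k0))
            row["p2"] = np.nan
            if pd_reference_models and name in pd_reference_models:
                ref = pd_reference_models[name]
                if ref not in results:
                    raise ValueError(f"reference model {ref!r} not in table")
                rdev, rk = results[ref]["deviance"], results[ref]["k"]
                if rk >= k:
                    raise ValueError(
                        f"{name!r} is not a strict supermodel of {ref!r}")
                row["p2"] = float(sps.chi2.sf(rdev - dev, k - rk))
        rows.append(row)
    return pd.DataFrame(rows, columns=["model", "deviance", "df", "p1", "p2",
                                       "aic"])


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(table: pd.DataFrame, group_col: str = "status",
                     continuous=(), skewed=(), categorical=()) -> pd.DataFrame:
    """Two-group descriptive summary.

    Continuous variables are compared with the two-sample t test and shown as
    mean (SD); skewed variables with the Wilcoxon rank-sum test and shown as
    medians; categorical variables with the chi-square test and shown as
    count (percent), percentages rounded to one decimal.  All tests two-sided.
    """
    g1 = table[table[group_col] == 1]
    g0 = table[table[group_col] == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in continuous:
        a, b = g1[col].dropna(), g0[col].dropna()
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append({"variable": col, "kind": "mean_sd",
                     "cases": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                     "controls": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                     "statistic": float(t), "p": float(p)})
    for col in skewed:
        a, b = g1[col].dropna(), g0[col].dropna()
        stat, p = sps.ranksums(a, b)
        rows.append({"variable": col, "kind": "median",
                     "cases": f"{a.median():.1f}",
                     "controls": f"{b.median():.1f}",
                     "statistic": float(stat), "p": float(p)})
    for col in categorical:
        tab = pd.crosstab(table[col], table[group_col])
        chi2, p, _, _ = sps.chi2_contingency(tab.to_numpy())
        n1 = int(g1[col].sum()) if table[col].dropna().isin([0, 1]).all() else None
        if n1 is not None:
            pct1 = 100.0 * n1 / len(g1)
            n0 = int(g0[col].sum())
            pct0 = 100.0 * n0 / len(g0)
            cases = f"{n1} ({pct1:.1f})"
            controls = f"{n0} ({pct0:.1f})"
        else:
            cases = controls = ""
        rows.append({"variable": col, "kind": "count_pct",
                     "cases": cases, "controls": controls,
                     "statistic": float(chi2), "p": float(p)})
    return pd.DataFrame(rows, columns=["variable", "kind", "cases",
                                       "controls", "statistic", "p"])
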