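"""Cohort-level statistics: group comparisons, severity correlations and
stepwise multivariate regression of severity on network and clinical
covariates.

The statistical stage mirrors routine clinical-EEG practice: one-way
ANOVA with Tukey post-hoc tests across lateralization groups, Spearman
rank correlation between each network metric and the severity score,
and SPSS-style stepwise linear regression (entry p < 0.05, removal
p > 0.10) of severity on the candidate covariates, reporting
standardized coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class SubjectRecord:
    """Clinical covariates for one subject; network features are joined later."""

    subject_id: str
    group: str  # "control" | "L-TLE" | "R-TLE" | "B-TLE"
    age: float
    sex: str = "U"
    age_of_onset: float = float("nan")
    duration: float = float("nan")
    seizure_freq_class: int | None = None  # 1 = <1/yr ... 4 = >=1/wk
    dre: bool = False
    va2: float = float("nan")
    asm_list: tuple[str, ...] = ()
    febrile_history: bool = False
    family_history: bool = False
    status_epilepticus: bool = False
    aura: bool = False
    generalized: bool = False
    postictal_confusion: bool = False
    seizure_duration_min: float = float("nan")

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "age_of_onset": self.age_of_onset,
            "duration": self.duration,
            "seizure_freq_class": self.seizure_freq_class,
            "dre": int(self.dre),
            "va2": self.va2,
            "n_asm": len(self.asm_list),
            "febrile_history": int(self.febrile_history),
            "family_history": int(self.family_history),
            "status_epilepticus": int(self.status_epilepticus),
            "aura": int(self.aura),
            "generalized": int(self.generalized),
            "postictal_confusion": int(self.postictal_confusion),
            "seizure_duration_min": self.seizure_duration_min,
        }
        return row


@dataclass
class GroupComparison:
    metric: str
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


@dataclass
class StepwiseResult:
    """Selected predictors with standardized coefficients and p-values."""

    selected: list[str]
    beta: dict[str, float]
    p_values: dict[str, float]
    n_obs: int
    steps: list[str] = field(default_factory=list)


def group_compare(table: pd.DataFrame, metric: str, grouping: str = "group") -> GroupComparison:
    """One-way ANOVA across groups with Tukey HSD pairwise comparisons."""
    clean = table[[metric, grouping]].dropna()
    groups = [g[metric].to_numpy() for _, g in clean.groupby(grouping, observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("group comparison needs >= 2 groups with >= 2 subjects each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero variance in every group: F undefined")
    f_stat, p = sps.f_oneway(*groups)
    tuk = pairwise_tukeyhsd(clean[metric].to_numpy(), clean[grouping].to_numpy())
    pairwise = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    return GroupComparison(metric=metric, f_stat=float(f_stat), p_value=float(p),
                           pairwise=pairwise)


def severity_correlation(table: pd.DataFrame, metric: str,
                         severity: str = "va2") -> tuple[float, float]:
    """Spearman rank correlation between *metric* and the severity score.

    Controls (missing severity) are excluded; requires >= 5 paired
    observations.
    """
    clean = table[[metric, severity]].dropna()
    if len(clean) < 5:
        raise ValueError("severity correlation needs >= 5 paired observations")
    r, p = sps.spearmanr(clean[metric], clean[severity])
    return float(r), float(p)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (x - x.mean()) / sd


def stepwise_regression(
    table: pd.DataFrame,
    response: str = "va2",
    candidates: list[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Stepwise (forward with backward removal) OLS of *response*.

    Complete cases only.  All variables are z-scored, so the reported
    coefficients are standardized betas.  At each step the candidate
    with the smallest partial-F p-value enters if p < *p_enter*; after
    every entry, included terms with p > *p_remove* are dropped.
    Constant and collinear candidates are excluded up front with a note
    in ``steps``.
    """
    if candidates is None:
        candidates = [c for c in table.columns if c != response]
    data = table[[response] + list(candidates)].dropna()
    n = len(data)
    if n < len(candidates) // 2 + 5:
        pass  # small-n stepwise is allowed; rank checks below guard the fits
    steps: list[str] = []
    usable: list[str] = []
    for c in candidates:
        x = data[c].to_numpy(dtype=float)
        if x.std(ddof=0) == 0:
            steps.append(f"excluded constant candidate {c!r}")
        else:
            usable.append(c)
    y = _zscore(data[response].to_numpy(dtype=float))
    z = {c: _zscore(data[c].to_numpy(dtype=float)) for c in usable}

    selected: list[str] = []
    while True:
        # entry step
        best_c, best_p = None, np.inf
        for c in usable:
            if c in selected:
                continue
            X = np.column_stack([np.ones(n)] + [z[s] for s in selected] + [z[c]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # collinear with current model
            fit = sm.OLS(y, X).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best_c, best_p = c, p
        if best_c is None or best_p >= p_enter:
            break
        selected.append(best_c)
        steps.append(f"entered {best_c!r} (p={best_p:.4g})")
        # removal step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            X = np.column_stack([np.ones(n)] + [z[s] for s in selected])
            fit = sm.OLS(y, X).fit()
            pvals = fit.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                gone = selected.pop(worst)
                steps.append(f"removed {gone!r} (p={pvals[worst]:.4g})")
                removed = True

    if selected:
        X = np.column_stack([np.ones(n)] + [z[s] for s in selected])
        fit = sm.OLS(y, X).fit()
        beta = {s: float(b) for s, b in zip(selected, fit.params[1:])}
        pvalues = {s: float(p) for s, p in zip(selected, fit.pvalues[1:])}
    else:
        beta, pvalues = {}, {}
    return StepwiseResult(selected=selected, beta=beta, p_values=pvalues,
                          n_obs=n, steps=steps)


def cohort_report(
    table: pd.DataFrame,
    metrics: list[str],
    severity: str = "va2",
    grouping: str = "group",
    regression_candidates: list[str] | None = None,
) -> dict:
    """Run the full statistical stage on a joined subject x feature table.

    Returns group tests per metric, Spearman severity correlations per
    metric, and the stepwise regression of severity.
    """
    group_rows, corr_rows = [], []
    for m in metrics:
        try:
            gc = group_compare(table, m, grouping)
            group_rows.append({"metric": m, "f": gc.f_stat, "p": gc.p_value})
        except ValueError:
            group_rows.append({"metric": m, "f": np.nan, "p": np.nan})
        try:
            r, p = severity_correlation(table, m, severity)
            corr_rows.append({"metric": m, "spearman_r": r, "p": p})
        except ValueError:
            corr_rows.append({"metric": m, "spearman_r": np.nan, "p": np.nan})
    patients = table[table[severity].notna()]
    reg = stepwise_regression(patients, response=severity,
                              candidates=regression_candidates)
    return {
        "group_tests": pd.DataFrame(group_rows),
        "correlations": pd.DataFrame(corr_rows),
        "regression": reg,
    }
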