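"""Group comparisons and outcome-association models.

Two-group comparisons of cohort characteristics by nutrition status use the
Mann-Whitney U test for continuous variables (normal approximation with tie
correction; an exact option exists for very small groups) and the Pearson
chi-square test without continuity correction for categorical variables.

Length of stay is dichotomized at the cohort median (value >= median flags the
long-stay class) and modelled with logistic regression: univariate fits of
each candidate covariate alone, then a multivariable fit of the covariates
whose univariate p falls below a selection threshold (default 0.05).
Categorical covariates expand against a stated reference level (tumor site:
stomach; risk stratification: high). Odds ratios are exp(coefficient) with
Wald 95% confidence intervals; perfect separation is flagged as
non-convergence and no estimates are reported for that fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_REFERENCE_LEVELS = {
    "tumor_site": "stomach",
    "risk_stratification": "high",
}

SELECTION_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "mann_whitney" | "chi_square"
    group_summaries: dict
    statistic: Optional[float]
    p_value: Optional[float]
    reason: Optional[str] = None


@dataclass(frozen=True)
class CovariateEffect:
    term: str
    odds_ratio: float
    ci: tuple[float, float]
    p_value: float


@dataclass
class LogisticFit:
    outcome: str
    covariates: list[str]
    mode: str  # "univariate" | "multivariate"
    effects: list[CovariateEffect] = field(default_factory=list)
    reference_levels: dict = field(default_factory=dict)
    converged: bool = False
    note: Optional[str] = None


class SeparationError(RuntimeError):
    """Perfect separation: the likelihood is unbounded, no estimates reported."""


def _summarize_continuous(series: pd.Series) -> str:
    vals = series.dropna()
    return f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"


def compare_groups(
    df: pd.DataFrame,
    grouping: str,
    variables: Sequence[str],
    exact_below_n: int = 0,
) -> list[GroupComparison]:
    """Compare each variable between the two levels of a boolean grouping column.

    Continuous (numeric, non-boolean) variables are tested with Mann-Whitney U
    (two-tailed normal approximation with tie correction; exact when both
    groups are smaller than ``exact_below_n``); categorical/boolean variables
    with Pearson chi-square without continuity correction. Summaries follow
    the conventional table layout: mean +- SD, or n (%) per level.
    """
    if df[grouping].isna().any():
        raise ValueError(f"grouping column {grouping!r} must be defined for all rows")
    g1 = df[df[grouping].astype(bool)]
    g0 = df[~df[grouping].astype(bool)]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")

    results: list[GroupComparison] = []
    for var in variables:
        col = df[var]
        is_continuous = pd.api.types.is_numeric_dtype(col) and not (
            pd.api.types.is_bool_dtype(col) or set(col.dropna().unique()) <= {0, 1}
        )
        if is_continuous:
            x = g1[var].dropna().to_numpy(dtype=float)
            y = g0[var].dropna().to_numpy(dtype=float)
            summaries = {
                "group_true": _summarize_continuous(g1[var]),
                "group_false": _summarize_continuous(g0[var]),
            }
            if len(x) < 2 or len(y) < 2:
                results.append(
                    GroupComparison(var, "mann_whitney", summaries, None, None,
                                    reason="fewer than 2 values in a group")
                )
                continue
            if np.ptp(np.concatenate([x, y])) == 0:
                results.append(
                    GroupComparison(var, "mann_whitney", summaries, None, None,
                                    reason="variable constant in both groups")
                )
                continue
            method = (
                "exact"
                if exact_below_n and max(len(x), len(y)) < exact_below_n
                else "asymptotic"
            )
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method=method, use_continuity=False
            )
            u = min(res.statistic, len(x) * len(y) - res.statistic)
            results.append(
                GroupComparison(var, "mann_whitney", summaries, float(u),
                                float(res.pvalue))
            )
        else:
            tab = pd.crosstab(col, df[grouping].astype(bool))
            summaries = {
                str(level): {
                    "n_true": int(tab.loc[level].get(True, 0)),
                    "n_false": int(tab.loc[level].get(False, 0)),
                }
                for level in tab.index
            }
            if tab.shape[0] < 2:
                results.append(
                    GroupComparison(var, "chi_square", summaries, None, None,
                                    reason="variable constant")
                )
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            results.append(
                GroupComparison(var, "chi_square", summaries, float(chi2), float(p))
            )
    return results


def dichotomize_outcome(
    values: Sequence[Optional[float]],
) -> tuple[list[Optional[bool]], float]:
    """Flag values at or above the cohort median; missing stays missing.

    Returns the per-patient flags and the cutoff (median of non-missing
    values; for even counts, the mean of the two middle order statistics).
    """
    arr = pd.Series(values, dtype=float)
    nonmissing = arr.dropna()
    if nonmissing.empty:
        raise ValueError("all values missing: no median to dichotomize at")
    cutoff = float(nonmissing.median())
    flags = [None if pd.isna(v) else bool(v >= cutoff) for v in arr]
    return flags, cutoff


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str], reference_levels: dict
) -> tuple[pd.DataFrame, dict]:
    """Expand covariates into a numeric design matrix with stated references."""
    cols = []
    refs_used = {}
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
            cols.append(col.astype(float).rename(cov))
        else:
            levels = sorted(col.dropna().unique())
            ref = reference_levels.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov!r}")
            refs_used[cov] = ref
            for level in levels:
                if level == ref:
                    continue
                cols.append(
                    (col == level).astype(float).rename(f"{cov}[{level} vs. {ref}]")
                )
    X = pd.concat(cols, axis=1)
    return X, refs_used


def _fit_one(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    mode: str,
    reference_levels: dict,
) -> LogisticFit:
    data = df[[outcome, *covariates]].dropna()
    y = data[outcome].astype(float)
    fit = LogisticFit(outcome=outcome, covariates=list(covariates), mode=mode)
    if y.nunique() < 2:
        fit.note = "outcome constant in the analysis sample"
        return fit
    X, refs = _design_matrix(data, covariates, reference_levels)
    fit.reference_levels = refs
    if len(data) <= X.shape[1] + 1:
        fit.note = "more parameters than observations"
        return fit
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Xc)
            res = model.fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and numeric failures
        fit.note = f"non-converged: {exc}"
        return fit
    converged = bool(res.mle_retvals.get("converged", False))
    # Boundary estimates (|beta| blowing up) signal quasi-separation even when
    # the optimizer reports nominal convergence.
    if not converged or np.any(np.abs(res.params.drop("const")) > 15):
        fit.note = "non-converged: perfect or quasi-perfect separation suspected"
        return fit
    ci = res.conf_int()
    fit.converged = True
    fit.effects = [
        CovariateEffect(
            term=term,
            odds_ratio=float(np.exp(res.params[term])),
            ci=(float(np.exp(ci.loc[term, 0])), float(np.exp(ci.loc[term, 1]))),
            p_value=float(res.pvalues[term]),
        )
        for term in X.columns
    ]
    return fit


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    mode: str = "multivariate",
    reference_levels: Optional[dict] = None,
) -> list[LogisticFit]:
    """Maximum-likelihood logistic fit(s) of a boolean outcome.

    ``univariate`` fits each covariate alone and returns one fit per
    covariate; ``multivariate`` returns a single joint fit. Non-converged
    fits (including perfect separation) are flagged and carry no estimates.
    """
    refs = {**DEFAULT_REFERENCE_LEVELS, **(reference_levels or {})}
    if mode == "univariate":
        return [_fit_one(df, outcome, [c], mode, refs) for c in covariates]
    if mode == "multivariate":
        return [_fit_one(df, outcome, covariates, mode, refs)]
    raise ValueError(f"unknown mode {mode!r}")


def select_covariates(
    univariate_fits: Sequence[LogisticFit], threshold: float = SELECTION_P_THRESHOLD
) -> list[str]:
    """Covariates whose univariate fit has any term with p below the threshold."""
    selected = []
    for fit in univariate_fits:
        if fit.converged and any(e.p_value < threshold for e in fit.effects):
            selected.extend(fit.covariates)
    return selected
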