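"""Burden stratification, Kaplan-Meier curves, log-rank and Cox models.

Progression-free survival (PFS) is the primary endpoint; overall survival
is supported but secondary.  "Two-year" rates are Kaplan-Meier estimates
at day 730 exactly.  Estimation is delegated to lifelines
(product-limit estimator, log-rank with hypergeometric variance, Cox
partial likelihood with Efron tie handling); this module fixes the
stratification rules, step-function conventions, and nested-model tests
used throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .exceptions import FitFailureError

logger = logging.getLogger(__name__)

#: Two years, in days, for "2-year survival rate" lookups.
TWO_YEARS_DAYS = 730.0

#: Clinical table columns understood by the subgroup analyses.
SUBGROUP_KEYS = (
    "iss_stage",
    "cyto_high_risk",
    "bortezomib",
    "imid",
    "ldh_elevated",
    "chr1_amp",
    "age_group",
)

TREATMENT_KEYS = ("bortezomib", "imid")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: step values at the observed times."""

    timeline: np.ndarray  # ascending, starts at 0
    survival: np.ndarray  # S(t), non-increasing, S(0) = 1
    at_risk: np.ndarray


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class CoxResult:
    effects: Mapping[str, CovariateEffect]
    log_likelihood: float
    n: int
    n_events: int


def stratify_by_mean(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Label burdens high/low against the cohort arithmetic mean.

    "High" is *strictly* greater than the mean, so an all-equal cohort is
    entirely low.  Returns (labels, threshold).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need >= 2 patients to stratify, got {v.size}")
    threshold = float(np.mean(v))
    labels = np.where(v > threshold, "high", "low")
    return labels, threshold


def stratify_by_quartiles(values: Sequence[float]) -> np.ndarray:
    """Label burdens Q1..Q4 by the 25/50/75 empirical percentiles.

    Values tied with a boundary fall into the lower quartile (labels are
    ``1 + #{boundaries strictly below the value}``), so an all-equal
    cohort is entirely Q1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 patients for quartiles, got {v.size}")
    bounds = np.quantile(v, [0.25, 0.5, 0.75])
    idx = 1 + (v[:, None] > bounds[None, :]).sum(axis=1)
    return np.array([f"Q{i}" for i in idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored observations (event 0) reduce the risk set without creating
    steps.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("times and events must be equal-length non-empty 1-D vectors")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return KMCurve(timeline=timeline, survival=survival, at_risk=at_risk)


def survival_rate_at(curve: KMCurve, t: float = TWO_YEARS_DAYS) -> float:
    """Step-function value of the KM curve at time ``t``.

    Uses the last estimate at or before ``t``; 1.0 before the first
    observed time.  Beyond the last observed time the last estimate
    carries forward with a warning.
    """
    if t > curve.timeline[-1]:
        warnings.warn(
            f"t={t} exceeds the last observed time {curve.timeline[-1]}; "
            "carrying the last KM estimate forward",
            stacklevel=2,
        )
    idx = int(np.searchsorted(curve.timeline, t, side="right")) - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> dict:
    """Log-rank test across >= 2 groups of (times, events).

    Standard statistic with hypergeometric variance, referred to a
    chi-square with (#groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} has no observations")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return {
        "chi_square": float(res.test_statistic),
        "p": float(res.p_value),
        "df": len(groups) - 1,
    }


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "pfs_days",
    event_col: str = "pfs_event",
) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling.

    Rows with a missing value in any used column are dropped listwise
    from this model only (count logged).  Wald confidence intervals and
    p-values per covariate; the partial log-likelihood supports nested
    model comparison via :func:`cox_nested_test`.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need >= 1 covariate")
    cols = [duration_col, event_col, *covariates]
    data = df[cols].apply(pd.to_numeric, errors="coerce")
    n_before = len(data)
    data = data.dropna()
    if len(data) < n_before:
        logger.info("cox_fit: dropped %d rows with missing values", n_before - len(data))
    if int(data[event_col].sum()) < 1:
        raise ValueError("no observed events")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant after listwise deletion")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise FitFailureError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    effects = {
        name: CovariateEffect(
            name=str(name),
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        )
        for name, row in summary.iterrows()
    }
    return CoxResult(
        effects=effects,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
    )


def cox_nested_test(full: CoxResult, reduced: CoxResult) -> dict:
    """Likelihood-ratio comparison of nested Cox models.

    Answers whether the extra covariates in ``full`` (e.g. a burden
    indicator on top of stage) add predictive benefit.  The statistic is
    clipped at 0 against round-off; for properly nested models fit on the
    same rows it is non-negative by construction.
    """
    df_extra = len(full.effects) - len(reduced.effects)
    if df_extra <= 0:
        raise ValueError("full model must have more covariates than reduced")
    lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    lr = max(lr, 0.0)
    return {"lr_statistic": float(lr), "df": df_extra, "p": float(stats.chi2.sf(lr, df_extra))}


def compare_burden_groups(
    values: Sequence[float], labels: Sequence, test: str | None = None
) -> dict:
    """Compare a continuous burden between prognostic groups.

    Welch two-sample t-test for two groups, one-way ANOVA for more; the
    choice can be forced with ``test='welch'|'anova'``.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [v[lab == g] for g in pd.unique(lab)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")
    if test is None:
        test = "welch" if len(groups) == 2 else "anova"
    if test == "welch":
        if len(groups) != 2:
            raise ValueError("welch test requires exactly 2 groups")
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    elif test == "anova":
        res = stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    statistic = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(statistic):  # identical groups with zero pooled variance
        statistic, p = 0.0, 1.0
    return {"statistic": statistic, "p": p, "test": test}


def _two_group_summary(sub: pd.DataFrame, duration_col: str, event_col: str) -> dict:
    """KM per burden label + log-rank between labels, within one cell."""
    out: dict = {"curves": {}, "two_year": {}, "n": {}}
    groups = []
    for label in ("high", "low"):
        cell = sub[sub["burden_label"] == label]
        out["n"][label] = int(len(cell))
        if cell.empty:
            logger.warning("empty cell for burden label %r; skipped", label)
            continue
        curve = km_estimate(cell[duration_col], cell[event_col])
        out["curves"][label] = curve
        out["two_year"][label] = survival_rate_at(curve, TWO_YEARS_DAYS)
        groups.append((cell[duration_col].to_numpy(), cell[event_col].to_numpy()))
    if len(groups) == 2:
        out["logrank"] = logrank_test(groups)
    return out


def subgroup_survival(
    clinical: pd.DataFrame,
    burden_labels: Sequence[str],
    subgroup: str,
    duration_col: str = "pfs_days",
    event_col: str = "pfs_event",
) -> dict:
    """Survival by burden label within levels of a prognostic subgroup.

    For stratification keys (stage, cytogenetic risk, LDH, chr1 amp, age
    group) each level is crossed with the high/low burden label: per-cell
    KM curves plus a within-level log-rank.  For treatment keys
    (bortezomib, imid) the cohort is *restricted* to treated patients
    (flag = 1) and the standard two-group comparison is run there.  Age
    groups are a median split.  Empty cells are skipped with a warning.
    """
    if subgroup not in SUBGROUP_KEYS:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUP_KEYS}")
    df = clinical.copy()
    df["burden_label"] = np.asarray(burden_labels)
    if subgroup == "age_group":
        median_age = df["age"].median()
        df["age_group"] = np.where(df["age"] > median_age, f">{median_age:g}", f"<={median_age:g}")
    if subgroup not in df.columns:
        raise ValueError(f"clinical table lacks column {subgroup!r}")
    results: dict = {}
    if subgroup in TREATMENT_KEYS:
        treated = df[pd.to_numeric(df[subgroup], errors="coerce") == 1]
        if treated.empty:
            raise ValueError(f"no patients with {subgroup} = 1")
        results["treated"] = _two_group_summary(treated, duration_col, event_col)
    else:
        for level, sub in df.groupby(subgroup, sort=True):
            results[str(level)] = _two_group_summary(sub, duration_col, event_col)
    return results
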