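"""Cohort-level association and survival analysis over pipeline outputs.

Associations use the non-parametric battery appropriate for TCR variables
that rarely meet normality: Kruskal-Wallis across groups (with Dunn's
post-hoc pairwise z-tests only after a significant omnibus), Wilcoxon
matched-pairs for paired samples, Mann-Whitney for two independent groups,
and two-sided Spearman rank correlation. Unadjusted p-values are the primary
output (this is an exploratory battery); Benjamini-Hochberg adjusted values
are emitted as a clearly separated extra column.

Survival analysis dichotomizes each variable at the cohort median (high =
strictly above the median; at-median observations fall in the low group,
config-flippable), reports the log-rank p and the univariate Cox hazard
ratio with CI, then refits the Cox model with the six clinical covariates
(age, sex, histology, stage, smoking, tumor size). Classical tests and the
proportional-hazards fit are delegated to scipy / lifelines; this module's
contribution is the orchestration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "histology", "stage", "smoking", "tumor_size")


@dataclass
class AssociationResult:
    name: str
    method: str
    statistic: float
    p_value: float
    n: int
    q_value: float | None = None
    detail: pd.DataFrame | None = None
    skipped: str | None = None


def spearman(x, y) -> tuple[float, float, int]:
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    rho, p = sps.spearmanr(df["x"], df["y"])
    return float(rho), float(p), len(df)


def dunn_test(values, groups) -> pd.DataFrame:
    """Dunn's pairwise rank-sum z-tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with tie
    term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    df["rank"] = sps.rankdata(df["value"])
    n_total = len(df)
    _, tie_counts = np.unique(df["value"], return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1))
    base = n_total * (n_total + 1) / 12 - tie_term
    means = df.groupby("group")["rank"].mean()
    sizes = df.groupby("group")["rank"].size()
    rows = []
    for g1, g2 in itertools.combinations(sorted(means.index, key=str), 2):
        se = np.sqrt(base * (1 / sizes[g1] + 1 / sizes[g2]))
        z = (means[g1] - means[g2]) / se
        rows.append(
            {"group_a": g1, "group_b": g2, "z": float(z),
             "p_value": float(2 * sps.norm.sf(abs(z)))}
        )
    return pd.DataFrame(rows)


def associate(df: pd.DataFrame, plan: list[dict], min_group_n: int = 3) -> list[AssociationResult]:
    """Run a declared list of comparisons against a metrics/covariate table.

    Each plan entry is a dict with ``name``, ``method`` (spearman |
    mann_whitney | wilcoxon_paired | kruskal_wallis) and the column roles the
    method needs (``x``/``y`` for correlations and paired tests,
    ``value``/``group`` for group comparisons). Groups with fewer than
    ``min_group_n`` complete cases cause the comparison to be skipped with a
    recorded reason. Dunn's test is attached to a Kruskal-Wallis result only
    when the omnibus is significant at 0.05.
    """
    results: list[AssociationResult] = []
    for item in plan:
        name, method = item["name"], item["method"]
        try:
            if method == "spearman":
                rho, p, n = spearman(df[item["x"]], df[item["y"]])
                results.append(AssociationResult(name, method, rho, p, n))
            elif method == "wilcoxon_paired":
                sub = df[[item["x"], item["y"]]].dropna()
                if len(sub) < min_group_n:
                    raise _Skip(f"only {len(sub)} complete pairs")
                stat, p = sps.wilcoxon(sub[item["x"]], sub[item["y"]])
                results.append(AssociationResult(name, method, float(stat), float(p), len(sub)))
            elif method in {"mann_whitney", "kruskal_wallis"}:
                sub = df[[item["value"], item["group"]]].dropna()
                arrays = [g[item["value"]].to_numpy() for _, g in sub.groupby(item["group"])]
                small = [len(a) for a in arrays if len(a) < min_group_n]
                if len(arrays) < 2 or small:
                    raise _Skip(f"group sizes {sorted(len(a) for a in arrays)} below {min_group_n}")
                if method == "mann_whitney":
                    if len(arrays) != 2:
                        raise _Skip("mann_whitney needs exactly 2 groups")
                    stat, p = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
                    detail = None
                else:
                    stat, p = sps.kruskal(*arrays)
                    detail = (
                        dunn_test(sub[item["value"]], sub[item["group"]]) if p < 0.05 else None
                    )
                results.append(
                    AssociationResult(name, method, float(stat), float(p), len(sub), detail=detail)
                )
            else:
                raise ValueError(f"unknown method {method!r} in plan entry {name!r}")
        except _Skip as sk:
            results.append(
                AssociationResult(name, method, float("nan"), float("nan"), 0, skipped=str(sk))
            )
    tested = [r for r in results if r.skipped is None]
    if tested:
        qs = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, qs):
            r.q_value = float(q)
    return results


class _Skip(Exception):
    pass


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value_bh": r.q_value,
                "n": r.n,
                "skipped": r.skipped,
            }
            for r in results
        ]
    )


# --------------------------------------------------------------------------- #
# Survival
# --------------------------------------------------------------------------- #


@dataclass
class SurvivalResult:
    variable: str
    n: int
    n_events: int
    n_high: int
    n_low: int
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    univariate_p: float
    multivariate_p: float | None = None
    multivariate_hr: float | None = None
    underpowered: bool = False


def median_split(values: pd.Series, at_median: str = "low") -> pd.Series:
    """High = strictly above the sample median; at-median rows go to the low
    group by default (flip with ``at_median='high'``)."""
    med = values.median()
    if at_median == "low":
        return (values > med).astype(int)
    return (values >= med).astype(int)


def survival_analysis(
    df: pd.DataFrame,
    variable: str,
    time_col: str = "os_time",
    event_col: str = "os_event",
    covariates=DEFAULT_COVARIATES,
    min_events: int = 10,
    at_median: str = "low",
) -> SurvivalResult:
    """Median-dichotomized log-rank + univariate Cox, then the multivariate
    Cox fit adjusted for the clinical covariates present in ``df``."""
    data = df[[variable, time_col, event_col]].dropna()
    if data[variable].nunique() < 2:
        raise ValueError(f"{variable} is constant; cannot dichotomize")
    high = median_split(data[variable], at_median)
    n_events = int(data[event_col].sum())
    if n_events < min_events or high.nunique() < 2:
        return SurvivalResult(
            variable, len(data), n_events, int(high.sum()), int((1 - high).sum()),
            float("nan"), float("nan"), (float("nan"), float("nan")), float("nan"),
            underpowered=True,
        )
    lr = logrank_test(
        data.loc[high == 1, time_col], data.loc[high == 0, time_col],
        event_observed_A=data.loc[high == 1, event_col],
        event_observed_B=data.loc[high == 0, event_col],
    )
    uni = pd.DataFrame({"time": data[time_col], "event": data[event_col], "high": high})
    cph = CoxPHFitter()
    cph.fit(uni, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    hr_ci = (
        float(np.exp(ci.loc["high"].iloc[0])),
        float(np.exp(ci.loc["high"].iloc[1])),
    )
    uni_p = float(cph.summary.loc["high", "p"])

    multi_p = multi_hr = None
    use_cov = [c for c in covariates if c in df.columns]
    if use_cov:
        multi = df[[variable, time_col, event_col, *use_cov]].dropna()
        if len(multi) >= min_events and multi[event_col].sum() >= min_events:
            enc = pd.get_dummies(multi[list(use_cov)], drop_first=True, dtype=float)
            enc = enc.loc[:, enc.nunique() > 1]
            design = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "time": multi[time_col],
                            "event": multi[event_col],
                            "high": median_split(multi[variable], at_median),
                        }
                    ),
                    enc,
                ],
                axis=1,
            )
            try:
                mfit = CoxPHFitter(penalizer=0.01)
                mfit.fit(design, duration_col="time", event_col="event")
                multi_p = float(mfit.summary.loc["high", "p"])
                multi_hr = float(np.exp(mfit.params_["high"]))
            except Exception:  # degenerate covariate patterns at small n
                multi_p = multi_hr = None
    return SurvivalResult(
        variable=variable,
        n=len(data),
        n_events=n_events,
        n_high=int(high.sum()),
        n_low=int((1 - high).sum()),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=hr_ci,
        univariate_p=uni_p,
        multivariate_p=multi_p,
        multivariate_hr=multi_hr,
    )


def survival_table(results: list[SurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "n": r.n,
                "n_events": r.n_events,
                "logrank_p": r.logrank_p,
                "hazard_ratio": r.hazard_ratio,
                "hr_ci_low": r.hr_ci[0],
                "hr_ci_high": r.hr_ci[1],
                "univariate_p": r.univariate_p,
                "multivariate_p": r.multivariate_p,
                "multivariate_hr": r.multivariate_hr,
                "underpowered": r.underpowered,
            }
            for r in results
        ]
    )
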