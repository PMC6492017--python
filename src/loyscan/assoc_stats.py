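"""Association and survival statistics used downstream of the LoY calls.

Thin, contract-checked wrappers over lifelines (Kaplan-Meier, log-rank,
Cox with Efron tie handling) and scipy (rank tests, Spearman, Fisher),
returning a uniform :class:`TestResult`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    df: int | None = None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


class FitError(RuntimeError):
    """Raised when a model fit fails to converge or is degenerate."""


def _clean_survival(time, event, group=None) -> pd.DataFrame:
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int)})
    if group is not None:
        df["group"] = np.asarray(group)
    if (df["time"] < 0).any():
        raise ValueError("negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return df


def km_estimate(time, event, group=None) -> pd.DataFrame:
    """Product-limit survival estimate per group, with right censoring.

    Returns a long frame (group, time, survival, at_risk); S(0) = 1 and the
    curve is non-increasing. Groups with fewer than 2 samples are dropped
    with a warning.
    """
    df = _clean_survival(time, event, group)
    if "group" not in df:
        df["group"] = "all"
    frames = []
    for name, sub in df.groupby("group", sort=True):
        if len(sub) < 2:
            logger.warning("km_estimate: dropping group %r with < 2 samples", name)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.survival_function_.reset_index()
        table.columns = ["time", "survival"]
        table.insert(0, "group", name)
        at_risk = kmf.event_table["at_risk"].reindex(table["time"]).values
        table["at_risk"] = at_risk
        frames.append(table)
    if not frames:
        raise ValueError("no group with >= 2 samples")
    return pd.concat(frames, ignore_index=True)


def logrank_test(time, event, group) -> TestResult:
    """k-group log-rank test (chi-square with k - 1 df)."""
    df = _clean_survival(time, event, group)
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if df["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        method="logrank",
        n=len(df),
        df=len(groups) - 1,
    )


def cox_fit(data: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str] | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) with per-covariate Wald p.

    Returns a frame indexed by covariate with columns ``coef``,
    ``hazard_ratio``, ``se``, ``p_value`` plus ``n`` and ``n_events``
    attached as frame attrs.
    """
    cols = covariates or [c for c in data.columns if c not in (duration_col, event_col)]
    sub = data[[duration_col, event_col] + cols].dropna()
    if sub[event_col].sum() < 1:
        raise ValueError("cox_fit needs at least one event")
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:  # complete separation, collinearity, ...
        raise FitError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    out = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "se": summary["se(coef)"],
            "p_value": summary["p"],
        }
    )
    out.attrs["n"] = len(sub)
    out.attrs["n_events"] = int(sub[event_col].sum())
    return out


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis rank test across >= 2 groups (average-rank ties)."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)}).dropna()
    samples = [sub["value"].values for _, sub in df.groupby("group", sort=True)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", len(pooled), df=len(samples) - 1)
    stat, p = stats.kruskal(*samples)
    return TestResult(float(stat), float(p), "kruskal_wallis", len(pooled),
                      df=len(samples) - 1)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null distribution when both groups have <= 25 observations and
    there are no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(stat), float(p), f"wilcoxon_rank_sum[{method}]",
                      a.size + b.size)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation; the statistic is rho."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return TestResult(float(rho), float(p), "spearman", int(ok.sum()))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table of non-negative counts.

    Two-sided by the minimum-likelihood convention: the p-value sums the
    probabilities of all tables (fixed margins) no more probable than the
    observed one.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {tab.shape}")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        if not np.allclose(tab, np.round(tab)) or np.any(tab < 0):
            raise ValueError("table entries must be non-negative integers")
        tab = tab.astype(int)
    _odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return TestResult(float(_odds), float(p), "fisher_exact", int(tab.sum()))


def median_split(values: pd.Series) -> pd.Series:
    """Two-level split at the median, ties assigned to the lower group."""
    values = pd.Series(values, dtype=float)
    med = values.median()
    out = pd.Series(np.where(values <= med, "low", "high"), index=values.index)
    out[values.isna()] = np.nan
    return out
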