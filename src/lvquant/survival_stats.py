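"""Group statistics for the study design: Kaplan-Meier survival with
log-rank comparison, one-way ANOVA with Dunnett's many-to-one correction,
and a one-within-factor repeated-measures ANOVA.

Survival tables carry one row per subject (group label, follow-up time in
days, event indicator); subjects completing follow-up are administratively
censored at the protocol end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

ALPHA = 0.05

REQUIRED_COLUMNS = ("group", "time", "event")


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survival table missing columns {missing}")
    if (table["time"] < 0).any():
        raise ValueError("follow-up times must be non-negative")
    if table.empty:
        raise ValueError("survival table is empty")
    return table


def make_survival_table(groups: dict[str, tuple[list[float], list[bool]]]) -> pd.DataFrame:
    """Assemble a survival table from {group: (times, events)}."""
    frames = [pd.DataFrame({"group": g, "time": t, "event": np.asarray(e, dtype=bool)})
              for g, (t, e) in groups.items()]
    return validate_survival_table(pd.concat(frames, ignore_index=True))


def endpoint_survival_table(n_total: int, n_survivors: int, end_day: float,
                            group: str, rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """Reconstruct a survival table from an endpoint count (k of n alive at
    ``end_day``).

    Death days are unknown, so deaths are spread over (0, end_day); the
    Kaplan-Meier estimate at ``end_day`` depends only on the counts when all
    deaths precede the administrative censoring, so any spread yields the
    same endpoint estimate.  Survivors are censored at ``end_day``.
    """
    if not 0 <= n_survivors <= n_total:
        raise ValueError("need 0 <= n_survivors <= n_total")
    n_deaths = n_total - n_survivors
    if rng is None:
        death_days = np.linspace(1.0, max(end_day - 1.0, 1.0), n_deaths) if n_deaths else []
    else:
        death_days = np.sort(rng.uniform(0.5, end_day - 0.5, size=n_deaths))
    times = np.concatenate([np.asarray(death_days, dtype=float),
                            np.full(n_survivors, float(end_day))])
    events = np.concatenate([np.ones(n_deaths, dtype=bool),
                             np.zeros(n_survivors, dtype=bool)])
    return make_survival_table({group: (times.tolist(), events.tolist())})


def kaplan_meier(table: pd.DataFrame, group: str) -> pd.Series:
    """Product-limit survival estimate for one group.

    Returns a step function as a Series indexed by time; with no censoring
    before an event time t, S(t) is simply (subjects alive after t)/n.
    """
    validate_survival_table(table)
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"unknown group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    sf = kmf.survival_function_["KM_estimate"]
    sf.index.name = "time"
    return sf


def survival_at(table: pd.DataFrame, group: str, t: float) -> float:
    """S(t) for a group (right-continuous step function)."""
    sf = kaplan_meier(table, group)
    idx = sf.index[sf.index <= t]
    return float(sf.loc[idx.max()]) if len(idx) else 1.0


def log_rank(table: pd.DataFrame, group_a: str, group_b: str) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Tied event times use the standard hypergeometric-variance correction.
    """
    validate_survival_table(table)
    a = table[table["group"] == group_a]
    b = table[table["group"] == group_b]
    for name, sub in ((group_a, a), (group_b, b)):
        if sub.empty:
            raise ValueError(f"group {name!r} has no subjects")
    if not (a["event"].any() or b["event"].any()):
        # degenerate: no events anywhere -> no information, statistic 0
        return 0.0, 1.0
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class DunnettResult:
    """One-way ANOVA F-test plus Dunnett many-to-one comparisons."""

    f_statistic: float
    f_pvalue: float
    control: str
    comparisons: pd.DataFrame  # index: group; columns: statistic, pvalue, pvalue_unadjusted


def anova_dunnett(groups: dict[str, np.ndarray], control_label: str) -> DunnettResult:
    """Compare every treatment group against the control.

    Adjusted p-values come from the multivariate-t distribution of the
    maximum Dunnett statistic; the unadjusted column is the two-sided p of
    the same t statistic with the pooled-variance degrees of freedom.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    control = arrays[control_label]
    treatments = {g: v for g, v in arrays.items() if g != control_label}

    pooled_var = np.concatenate([v - v.mean() for v in arrays.values()]).var(ddof=0)
    means = np.array([v.mean() for v in arrays.values()])
    if pooled_var == 0 and np.ptp(means) > 0:
        raise ValueError("degenerate data: zero pooled variance with unequal means")

    f_stat, f_p = sps.f_oneway(*arrays.values())
    res = sps.dunnett(*treatments.values(), control=control)
    n_total = sum(v.size for v in arrays.values())
    df = n_total - len(arrays)
    p_unadj = 2.0 * sps.t.sf(np.abs(res.statistic), df)
    comparisons = pd.DataFrame(
        {"statistic": res.statistic, "pvalue": res.pvalue, "pvalue_unadjusted": p_unadj},
        index=pd.Index(list(treatments), name="group"))
    return DunnettResult(f_statistic=float(f_stat), f_pvalue=float(f_p),
                         control=control_label, comparisons=comparisons)


def repeated_measures_anova(data: np.ndarray) -> tuple[float, float]:
    """One-within-factor repeated-measures ANOVA (sphericity assumed).

    ``data`` is a complete subjects x timepoints matrix.  For two
    timepoints the F statistic equals the squared paired t statistic.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a complete subjects x timepoints matrix (>= 2 each)")
    if np.isnan(data).any():
        raise ValueError("missing cells: repeated-measures design must be complete")
    n_sub, n_time = data.shape
    # no between-time variation: F is 0 by definition (and 0/0 numerically
    # when the within-subject error is also zero)
    if float(((data.mean(axis=0) - data.mean()) ** 2).sum()) == 0.0:
        return 0.0, 1.0
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_time),
        "time": np.tile(np.arange(n_time), n_sub),
        "value": data.ravel(),
    })
    fit = AnovaRM(long, depvar="value", subject="subject", within=["time"]).fit()
    row = fit.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])
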