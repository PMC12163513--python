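"""Kaplan-Meier estimation, log-rank testing and data-driven dichotomization.

Morphotype proportions are dichotomized at the cutoff that a single-split
survival tree would choose: an exhaustive search over the midpoints of
consecutive distinct proportion values, selecting the split that maximizes
the two-group log-rank statistic subject to both leaves holding at least a
minimum fraction of the cohort.  Because the cutoff is chosen to maximize
separation, the accompanying log-rank p-value is selection-biased and is
reported as exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .types import ValidationError

MIN_LEAF_FRAC = 0.1

ENDPOINTS = {"OS": ("os_time", "os_event"), "RFS": ("rfs_time", "rfs_event")}
SUBSETS = ("all", "stage I-III")


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty survival data")
    if t.shape != e.shape:
        raise ValidationError("times and events must be equal-length")
    if (t < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("events must be 0 or 1")
    return t, e


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) estimator with an at-risk table.

    Returns a step function as a DataFrame with columns ``time``,
    ``survival`` and ``at_risk`` — one row per distinct observed time,
    starting from S(0) = 1.
    """
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    out = pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """k-sample log-rank test; chi-square statistic with k-1 df and p-value."""
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValidationError("groups must align with times")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValidationError("need at least 2 groups")
    if (counts == 0).any():
        raise ValidationError("every group needs at least one subject")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def _two_group_logrank_stat(times, events, in_group1) -> float:
    """Vectorized observed-minus-expected log-rank chi-square (2 groups).

    Used by the exhaustive cutoff search where the test runs once per
    candidate split; agrees with :func:`logrank_test` exactly.
    """
    order = np.argsort(times, kind="stable")
    t, e, g1 = times[order], events[order], in_group1[order]
    ut, inv = np.unique(t, return_inverse=True)
    m = ut.size
    d = np.bincount(inv, weights=e, minlength=m)          # events at t_i
    d1 = np.bincount(inv, weights=e * g1, minlength=m)    # group-1 events
    removed = np.bincount(inv, minlength=m)               # leaving risk set
    removed1 = np.bincount(inv, weights=g1, minlength=m)
    n_total = t.size
    n1_total = g1.sum()
    n = n_total - np.concatenate(([0.0], np.cumsum(removed)[:-1]))   # at risk
    n1 = n1_total - np.concatenate(([0.0], np.cumsum(removed1)[:-1]))
    mask = (d > 0) & (n > 1)
    n, n1, d, d1 = n[mask], n1[mask], d[mask], d1[mask]
    if n.size == 0:
        return 0.0
    o_minus_e = (d1 - d * n1 / n).sum()
    var = (d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)).sum()
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)


@dataclass
class SurvivalStratification:
    """One dichotomized survival comparison (curves, cutoff, log-rank)."""

    variable: str  # e.g. "p_DE" or "tumor_nsi"
    endpoint: str  # OS | RFS
    subset: str  # all | stage I-III
    cutoff: float
    n_low: int
    n_high: int
    logrank_statistic: float
    logrank_p: float
    exploratory: bool = True  # cutoff chosen to maximize separation
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def optimal_cutoff(
    proportions,
    times,
    events,
    min_leaf_frac: float = MIN_LEAF_FRAC,
    variable: str = "proportion",
    endpoint: str = "OS",
    subset: str = "all",
) -> SurvivalStratification:
    """Exhaustive single-split search for the most informative cutoff.

    Candidate cutoffs are the midpoints of consecutive distinct proportion
    values; the split maximizing the two-group log-rank statistic is chosen
    among those leaving at least ``min_leaf_frac`` of subjects on each
    side.  Ties go to the smallest cutoff.  Deterministic given inputs.
    The reported p-value is flagged exploratory (selection-biased).
    """
    x = np.asarray(proportions, dtype=float)
    t, e = _check_surv(times, events)
    if x.shape != t.shape:
        raise ValidationError("proportions must align with survival data")
    if not 0 < min_leaf_frac <= 0.5:
        raise ValidationError("min_leaf_frac must be in (0, 0.5]")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValidationError("all proportion values identical; no split exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2
    n = x.size
    min_leaf = min_leaf_frac * n
    best_stat, best_cut = -1.0, None
    for cut in candidates:
        high = x > cut
        n_high = int(high.sum())
        if n_high < min_leaf or (n - n_high) < min_leaf:
            continue
        stat = _two_group_logrank_stat(t, e, high.astype(float))
        if stat > best_stat:
            best_stat, best_cut = stat, float(cut)
    if best_cut is None:
        raise ValidationError(
            f"no admissible split with min_leaf_frac={min_leaf_frac} (n={n})"
        )
    high = x > best_cut
    _, p = logrank_test(t, e, np.where(high, "high", "low"))
    return SurvivalStratification(
        variable=variable,
        endpoint=endpoint,
        subset=subset,
        cutoff=best_cut,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        logrank_statistic=best_stat,
        logrank_p=p,
        km_curves={
            "low": km_estimate(t[~high], e[~high]),
            "high": km_estimate(t[high], e[high]),
        },
    )


def stratified_survival_report(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("p_DE", "p_PP", "p_CT"),
    endpoints: tuple[str, ...] = ("OS", "RFS"),
    subsets: tuple[str, ...] = SUBSETS,
    min_leaf_frac: float = MIN_LEAF_FRAC,
) -> list[SurvivalStratification]:
    """Dichotomized KM comparisons for each (variable, endpoint, subset).

    ``cohort`` is one row per tumor holding the stratification variables,
    ``ajcc_stage`` and the endpoint columns (os_time/os_event,
    rfs_time/rfs_event).  The stage I-III subset drops stage IV rows
    before any analysis.
    """
    out = []
    for subset in subsets:
        if subset == "all":
            sub = cohort
        elif subset == "stage I-III":
            sub = cohort[cohort["ajcc_stage"] != "IV"]
        else:
            raise ValidationError(f"unknown subset {subset!r}; allowed {SUBSETS}")
        for endpoint in endpoints:
            try:
                time_col, event_col = ENDPOINTS[endpoint]
            except KeyError:
                raise ValidationError(f"unknown endpoint {endpoint!r}") from None
            if time_col not in cohort.columns or event_col not in cohort.columns:
                raise ValidationError(f"cohort lacks columns for endpoint {endpoint}")
            for var in variables:
                if var not in cohort.columns:
                    raise ValidationError(f"cohort lacks stratification column {var!r}")
                d = sub[[var, time_col, event_col]].dropna()
                out.append(
                    optimal_cutoff(
                        d[var].to_numpy(), d[time_col].to_numpy(),
                        d[event_col].to_numpy(),
                        min_leaf_frac=min_leaf_frac,
                        variable=var, endpoint=endpoint, subset=subset,
                    )
                )
    return out


def strata_frame(strata: list[SurvivalStratification]) -> pd.DataFrame:
    """Tabular summary of stratifications (one row each)."""
    return pd.DataFrame(
        [
            {
                "variable": s.variable, "endpoint": s.endpoint, "subset": s.subset,
                "cutoff": s.cutoff, "n_low": s.n_low, "n_high": s.n_high,
                "logrank_statistic": s.logrank_statistic, "logrank_p": s.logrank_p,
                "exploratory": s.exploratory,
            }
            for s in strata
        ],
        columns=["variable", "endpoint", "subset", "cutoff", "n_low", "n_high",
                 "logrank_statistic", "logrank_p", "exploratory"],
    )
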