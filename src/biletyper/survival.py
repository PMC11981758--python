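"""Kaplan-Meier estimation and log-rank comparison for cohort strata.

Thin, typed surface over lifelines: the product-limit estimator with the
standard simultaneous-risk-set handling of tied event times, and the plain
(unweighted) log-rank test with a 1-df chi-square reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data import CohortMetadata

__all__ = ["SurvivalCurve", "km_estimate", "logrank_test", "survival_by_group"]


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate for one group.

    ``event_times`` are the distinct times with at least one death; S(t) is
    the running product of (1 - d/n) over event times <= t.  Censored times
    shrink the risk set without a drop.
    """

    group: str
    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "group": self.group,
            }
        )

    def at(self, t: float) -> float:
        """S(t): survival probability just after time t."""
        mask = self.event_times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0


def km_estimate(times, events, group: str = "all") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (death)")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    with_events = tbl[tbl["observed"] > 0]
    event_times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([surv.loc[t] for t in event_times])
    return SurvivalCurve(
        group=group,
        event_times=event_times,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
        events=with_events["observed"].to_numpy(dtype=int),
        survival=survival,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def survival_by_group(
    records: list[CohortMetadata],
    grouping: dict[str, str],
) -> dict:
    """KM curves and a log-rank test for samples stratified by ``grouping``.

    ``grouping`` maps sample id to a stratum label (e.g. a biletype or a
    high/low abundance flag); samples without survival data are skipped.
    Exactly two strata are required for the test.
    """
    by_group: dict[str, list[tuple[float, int]]] = {}
    for r in records:
        if r.sample_id not in grouping or r.survival_time is None:
            continue
        by_group.setdefault(grouping[r.sample_id], []).append(
            (r.survival_time, r.event)
        )
    labels = sorted(by_group)
    if len(labels) != 2:
        raise ValueError(f"need exactly two strata with survival data, got {labels}")
    curves = {}
    for g in labels:
        t, e = zip(*by_group[g])
        curves[g] = km_estimate(t, e, group=g)
    (ta, ea) = zip(*by_group[labels[0]])
    (tb, eb) = zip(*by_group[labels[1]])
    chi2, p = logrank_test(ta, ea, tb, eb)
    return {"curves": curves, "chi_square": chi2, "p_value": p, "groups": labels}
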