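"""Time-to-event evaluation: Kaplan-Meier, log-rank, Cox HR, Harrell's C,
IPCW time-dependent AUC and maximally selected risk cutoffs.

Conventions: time is in months and must be positive; event = 1 marks an
observed event (relapse/death per the DFS/OS definition in use), 0 censoring;
higher risk scores mean worse expected outcome. Cox fits use the Efron tie
correction; tied risk pairs count 0.5 in the concordance index; the
time-dependent AUC is the cumulative/dynamic definition with inverse
probability of censoring weights from the Kaplan-Meier censoring estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _ll_cindex

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank",
    "cox_hr",
    "concordance_index",
    "time_dependent_auc",
    "optimal_cutoff",
    "CutoffResult",
]


@dataclass
class SurvivalData:
    """Validated per-patient (time, event, risk) triples."""

    time: np.ndarray
    event: np.ndarray
    risk: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if np.isnan(self.time).any() or (self.time <= 0).any():
            raise ValueError("survival times must be positive and non-missing")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")
        self.event = self.event.astype(np.int64)
        if self.risk is not None:
            self.risk = np.asarray(self.risk, dtype=np.float64)
            if self.risk.shape != self.time.shape or np.isnan(self.risk).any():
                raise ValueError("risk scores must align with times and be non-missing")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, mask) -> "SurvivalData":
        return SurvivalData(self.time[mask], self.event[mask],
                            None if self.risk is None else self.risk[mask])


@dataclass
class KMCurve:
    """Right-continuous product-limit survival step function."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def S(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    hr: float
    ci95: tuple
    p: float
    log_hr: float = 0.0
    se_log_hr: float = float("nan")
    separated: bool = False


def km_estimate(d: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimate; all-censored data gives S = 1."""
    kmf = KaplanMeierFitter()
    kmf.fit(d.time, event_observed=d.event)
    times = kmf.survival_function_.index.to_numpy(dtype=np.float64)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=np.float64)
    # lifelines includes t=0 with S=1; keep event-time grid only
    keep = times > 0
    at_risk = np.array([(d.time >= t).sum() for t in times[keep]], dtype=np.int64)
    return KMCurve(times=times[keep], survival=surv[keep], at_risk=at_risk)


def logrank(a: SurvivalData, b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a.event.sum() == 0 and b.event.sum() == 0:
        warnings.warn("no events in either group; log-rank statistic is 0",
                      stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(a.time, b.time, event_observed_A=a.event,
                       event_observed_B=b.event)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(d: SurvivalData, group: np.ndarray) -> CoxResult:
    """Univariable proportional-hazards fit of a binary group indicator.

    Newton iteration on the Efron partial likelihood (via lifelines); returns
    the hazard ratio for group 1 vs 0 with a Wald 95% CI, and the log-rank p.
    Complete separation (monotone likelihood) is flagged and the CI reported
    as unbounded.
    """
    group = np.asarray(group).astype(np.int64)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be present")
    if d.event.sum() == 0:
        raise ValueError("need at least one event")
    _, p = logrank(d.subset(group == 0), d.subset(group == 1))
    df = pd.DataFrame({"time": d.time, "event": d.event, "group": group})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["group"])
        se = float(cph.standard_errors_["group"])
        if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
            raise ConvergenceError("monotone likelihood")
        lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
        return CoxResult(hr=float(np.exp(beta)), ci95=(float(lo), float(hi)),
                         p=p, log_hr=beta, se_log_hr=se)
    except ConvergenceError:
        sign = 1.0 if _events_favor_group1(d, group) else -1.0
        return CoxResult(hr=float("inf") if sign > 0 else 0.0,
                         ci95=(0.0, float("inf")), p=p,
                         log_hr=float("inf") * sign, separated=True)


def _events_favor_group1(d: SurvivalData, group: np.ndarray) -> bool:
    return d.event[group == 1].mean() >= d.event[group == 0].mean()


def concordance_index(d: SurvivalData) -> float:
    """Harrell's C for risk scores: higher risk should mean earlier events.

    Pairs are comparable iff the earlier time is an event; tied risks in a
    comparable pair count one half.
    """
    if d.risk is None:
        raise ValueError("risk scores required")
    if d.event.sum() == 0 or len(d) < 2:
        raise ValueError("concordance undefined: no comparable pairs")
    # lifelines' convention scores higher = longer survival, so negate risk
    return float(_ll_cindex(d.time, -d.risk, d.event))


def time_dependent_auc(d: SurvivalData, horizons) -> dict:
    """Cumulative/dynamic AUC(t) with IPCW at each horizon (months).

    Cases are patients with an event by t, controls those event-free beyond t;
    censoring weights come from the Kaplan-Meier estimate of the censoring
    distribution on the same data.
    """
    from sksurv.metrics import cumulative_dynamic_auc

    if d.risk is None:
        raise ValueError("risk scores required")
    horizons = np.atleast_1d(np.asarray(horizons, dtype=np.float64))
    y = np.array(list(zip(d.event.astype(bool), d.time)),
                 dtype=[("event", "?"), ("time", "<f8")])
    out = {}
    for t in horizons:
        if not ((d.time <= t) & (d.event == 1)).any():
            raise ValueError(f"no cases (events) by horizon {t}")
        if not (d.time > t).any():
            raise ValueError(f"no controls (survivors) beyond horizon {t}")
        auc, _ = cumulative_dynamic_auc(y, y, d.risk, [t])
        out[float(t)] = float(auc[0])
    return out


@dataclass
class CutoffResult:
    threshold: float
    statistic: float
    high_mask: np.ndarray  # True where risk > threshold


def optimal_cutoff(d: SurvivalData, minprop: float = 0.1) -> CutoffResult:
    """Maximally selected log-rank cutoff on the risk score.

    Scans every split ``risk > c`` with both groups holding at least
    ``minprop`` of the patients and the candidate inside the
    [minprop, 1-minprop] risk quantile band, returning the split with the
    largest log-rank statistic. Rank-based: a strictly increasing transform
    of the risks selects the same patient split.
    """
    if d.risk is None:
        raise ValueError("risk scores required")
    n = len(d)
    if n < 10:
        raise ValueError("need at least 10 patients for cutoff selection")
    lo, hi = np.quantile(d.risk, [minprop, 1 - minprop])
    candidates = [c for c in np.unique(d.risk) if lo <= c < hi]
    best = None
    for c in candidates:
        high = d.risk > c
        if high.sum() < minprop * n or (~high).sum() < minprop * n:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, _ = logrank(d.subset(~high), d.subset(high))
        if best is None or stat > best[1]:
            best = (c, stat, high)
    if best is None:
        raise ValueError("no threshold leaves both groups above the minimum size")
    return CutoffResult(threshold=float(best[0]), statistic=float(best[1]),
                        high_mask=best[2])
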