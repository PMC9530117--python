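"""Survival comparison between expression cohorts.

Implements the product-limit (Kaplan-Meier) estimator, the two-group
log-rank test and a hazard-ratio estimate, all from the same event table.

The default hazard-ratio estimator maximises the one-covariate
proportional-hazards partial likelihood (Breslow tie handling) by Newton
iteration on the per-event-time risk-set tables; for a single binary
grouping this is exact and needs no regression machinery.  The classical
observed/expected summary (O_A/E_A)/(O_B/E_B) is available as
``method="oe"``; it is a quick approximation whose magnitude is
noticeably shrunk toward 1 when the true ratio is far from 1 and
follow-up is long, which is why it is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats


def _check_group(times, events) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("empty survival group")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 (censored) or 1 (death)")
    return t, e


def km_estimator(times, events) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns a DataFrame with columns ``time``, ``n_at_risk``, ``n_events``
    and ``survival`` at each distinct event time (ties grouped); the curve
    starts implicitly at S(0) = 1 and is non-increasing.
    """
    t, e = _check_group(times, events)
    event_times = np.unique(t[e == 1])
    rows = []
    surv = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(et), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _logrank_table(tA, eA, tB, eB) -> Tuple[float, float, float, float, float]:
    """Observed events, expected events and hypergeometric variance.

    Returns (O_A, E_A, O_B, E_B, V) summed over distinct event times.
    """
    all_t = np.concatenate([tA, tB])
    all_e = np.concatenate([eA, eB])
    group = np.concatenate([np.zeros(tA.size, bool), np.ones(tB.size, bool)])
    event_times = np.unique(all_t[all_e == 1])
    oa = ea = ob = eb = var = 0.0
    for et in event_times:
        at_risk = all_t >= et
        n = at_risk.sum()
        n_a = (at_risk & ~group).sum()
        n_b = n - n_a
        died = (all_t == et) & (all_e == 1)
        d = died.sum()
        d_a = (died & ~group).sum()
        oa += d_a
        ob += d - d_a
        ea += d * n_a / n
        eb += d * n_b / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return oa, ea, ob, eb, var


def logrank_test(times_a, events_a, times_b, events_b) -> Tuple[float, float]:
    """Two-group log-rank test: observed-minus-expected chi-square, 1 df."""
    tA, eA = _check_group(times_a, events_a)
    tB, eB = _check_group(times_b, events_b)
    if eA.sum() + eB.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    oa, ea, ob, eb, var = _logrank_table(tA, eA, tB, eB)
    if var == 0:
        return 0.0, 1.0
    chi2 = (oa - ea) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class HazardRatio:
    hr: float
    ci_low: float
    ci_high: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float


def _risk_set_table(tA, eA, tB, eB):
    """Per-event-time risk-set sizes and event counts (A first)."""
    t = np.concatenate([tA, tB])
    e = np.concatenate([eA, eB])
    in_a = np.concatenate([np.ones(tA.size, bool), np.zeros(tB.size, bool)])
    event_times = np.unique(t[e == 1])
    n_a = np.array([(in_a & (t >= et)).sum() for et in event_times], dtype=float)
    n_b = np.array([(~in_a & (t >= et)).sum() for et in event_times], dtype=float)
    d_a = np.array([(in_a & (t == et) & (e == 1)).sum() for et in event_times], dtype=float)
    d = np.array([((t == et) & (e == 1)).sum() for et in event_times], dtype=float)
    return n_a, n_b, d_a, d


def _partial_likelihood_hr(tA, eA, tB, eB, max_iter: int = 100, tol: float = 1e-12):
    """Newton maximisation of the binary-covariate Breslow partial
    likelihood; returns (hr, observed information on the log scale)."""
    n_a, n_b, d_a, d = _risk_set_table(tA, eA, tB, eB)
    beta = 0.0
    info = np.nan
    for _ in range(max_iter):
        theta = np.exp(beta)
        w = n_a * theta / (n_a * theta + n_b)
        score = float((d_a - d * w).sum())
        info = float((d * w * (1.0 - w)).sum())
        if info <= 0:
            raise ValueError("zero information: a group has no events at risk")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    return float(np.exp(beta)), info


def hazard_ratio(
    times_a, events_a, times_b, events_b,
    alpha: float = 0.05, method: str = "partial_likelihood",
) -> HazardRatio:
    """Hazard ratio of group A relative to group B.

    method="partial_likelihood" (default): exact one-covariate
    proportional-hazards estimate with the Wald interval
    exp(log HR +/- z / sqrt(information)).
    method="oe": the (O_A/E_A)/(O_B/E_B) log-rank-table approximation with
    the log-normal interval exp(log HR +/- z * sqrt(1/E_A + 1/E_B)).
    """
    tA, eA = _check_group(times_a, events_a)
    tB, eB = _check_group(times_b, events_b)
    if eA.sum() == 0 or eB.sum() == 0:
        raise ValueError("hazard ratio needs at least one event in each group")
    oa, ea, ob, eb, _ = _logrank_table(tA, eA, tB, eB)
    if ea == 0 or eb == 0:
        raise ValueError("zero expected events in one group")
    z = stats.norm.isf(alpha / 2)
    if method == "partial_likelihood":
        hr, info = _partial_likelihood_hr(tA, eA, tB, eB)
        se = 1.0 / np.sqrt(info)
    elif method == "oe":
        hr = (oa / ea) / (ob / eb)
        se = np.sqrt(1.0 / ea + 1.0 / eb)
    else:
        raise ValueError(f"unknown hazard-ratio method {method!r}")
    return HazardRatio(
        hr=float(hr),
        ci_low=float(hr * np.exp(-z * se)),
        ci_high=float(hr * np.exp(z * se)),
        observed_a=float(oa),
        expected_a=float(ea),
        observed_b=float(ob),
        expected_b=float(eb),
    )
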