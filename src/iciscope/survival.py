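"""Kaplan-Meier curves, log-rank tests, maximally selected cutoffs, Cox HRs.

The score cutoff follows the maximally-selected-rank-statistic idea: the
standardized two-group log-rank statistic is evaluated at every admissible
midpoint between consecutive distinct scores, and the cutoff with the largest
|z| wins. The resulting grouping feeds plain log-rank tests and univariate
Cox fits (Newton-Raphson on the Breslow partial likelihood), including
per-stratum hazard ratios for forest plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate on the observed event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")
        if (self.survival < -1e-12).any() or (self.survival > 1 + 1e-12).any():
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass
class CutoffResult:
    cutoff: float
    z_statistic: float
    candidates: np.ndarray
    z_values: np.ndarray
    min_group_fraction: float


@dataclass
class StratumHR:
    stratum: str
    n: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    monotone_likelihood: bool = False


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    return t, e


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit estimator; deaths processed before censorings at ties."""
    t, e = _as_arrays(times, events)
    fitter = KaplanMeierFitter()
    fitter.fit(t, e)
    grid = fitter.event_table.index.to_numpy(dtype=float)
    surv = fitter.survival_function_.iloc[:, 0].to_numpy()
    at_risk = fitter.event_table["at_risk"].to_numpy()
    # lifelines inserts a time-0 anchor row; keep it only if 0 was observed
    keep = np.ones(len(grid), bool) if (t == 0).any() else grid > 0
    return KMCurve(
        times=grid[keep],
        survival=surv[keep],
        at_risk=at_risk[keep],
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """k-group log-rank chi-square (hypergeometric variance) and p-value."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def _logrank_z(times: np.ndarray, events: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for group 1."""
    order = np.argsort(times, kind="stable")
    t, e, grp = times[order], events[order], in_group[order]
    n = len(t)
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    # risk-set counts by scanning distinct event times
    for et in event_times:
        at_risk = t >= et
        n_risk = at_risk.sum()
        n1_risk = (at_risk & grp).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & grp).sum()
        if n_risk <= 1:
            continue
        expect = d * n1_risk / n_risk
        v = (
            d
            * (n1_risk / n_risk)
            * (1 - n1_risk / n_risk)
            * (n_risk - d)
            / (n_risk - 1)
        )
        o_minus_e += d1 - expect
        var += v
    if var <= 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


def best_cutoff(
    score, times, events, min_group_fraction: float = 0.1
) -> CutoffResult:
    """Maximally selected log-rank cutoff for a continuous score.

    Candidates are midpoints between consecutive distinct sorted scores;
    splits leaving either group under ``min_group_fraction`` of the cohort
    are inadmissible. Ties in |z| resolve to the lower cutoff.
    """
    s = np.asarray(score, dtype=float)
    t, e = _as_arrays(times, events)
    if len(s) < 10:
        raise ValueError("need at least 10 subjects to select a cutoff")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(s)
    min_n = min_group_fraction * n
    candidates, zs = [], []
    for c in mids:
        high = s > c
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        candidates.append(c)
        zs.append(_logrank_z(t, e, high))
    if not candidates:
        raise ValueError("no admissible cutoff satisfies the group-size constraint")
    candidates = np.asarray(candidates)
    zs = np.asarray(zs)
    best_idx = int(np.argmax(np.abs(zs)))  # argmax takes the first (lowest) tie
    return CutoffResult(
        cutoff=float(candidates[best_idx]),
        z_statistic=float(zs[best_idx]),
        candidates=candidates,
        z_values=zs,
        min_group_fraction=min_group_fraction,
    )


def _breslow_loglik(beta: float, t, e, x) -> float:
    """Breslow partial log-likelihood for a single binary covariate."""
    ll = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        d_mask = (t == et) & (e == 1)
        d = d_mask.sum()
        ll += beta * x[d_mask].sum()
        ll -= d * np.log(np.sum(np.exp(beta * x[at_risk])))
    return float(ll)


def cox_hr(times, events, binary_group, stratum: str = "all") -> StratumHR:
    """Univariate Cox PH fit for a binary group (high=1 vs low=0).

    Newton-Raphson on the Breslow partial likelihood; Wald CI and p. If one
    group has no events the likelihood is monotone in beta: the fit is
    flagged and the CI reported unbounded.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(binary_group, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cox_hr needs both groups present")
    events_by_group = {v: int(e[x == v].sum()) for v in (0.0, 1.0)}
    if min(events_by_group.values()) == 0 and e.sum() > 0:
        sign = 1.0 if events_by_group[1.0] > 0 else -1.0
        logger.warning("monotone partial likelihood: one group has no events")
        return StratumHR(
            stratum=stratum,
            n=len(t),
            hazard_ratio=float(np.inf if sign > 0 else 0.0),
            ci_low=0.0,
            ci_high=np.inf,
            p=np.nan,
            monotone_likelihood=True,
        )
    event_times = np.unique(t[e == 1])
    if len(event_times) == 0:
        raise ValueError("no events observed")
    beta = 0.0
    for _ in range(50):
        grad, hess = 0.0, 0.0
        for et in event_times:
            at_risk = t >= et
            d_mask = (t == et) & (e == 1)
            d = d_mask.sum()
            w = np.exp(beta * x[at_risk])
            sw = w.sum()
            swx = (w * x[at_risk]).sum()
            swx2 = (w * x[at_risk] ** 2).sum()
            grad += x[d_mask].sum() - d * swx / sw
            hess -= d * (swx2 / sw - (swx / sw) ** 2)
        if hess == 0:
            break
        step = grad / hess
        beta -= step
        if abs(step) < 1e-12:
            break
    se = float(np.sqrt(-1.0 / hess))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return StratumHR(
        stratum=stratum,
        n=len(t),
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(p),
    )


def stratified_forest(
    clinical: ClinicalTable,
    ici_groups: pd.Series,
    strata_definitions: dict[str, pd.Series],
    min_stratum_size: int = 10,
) -> list[StratumHR]:
    """Per-stratum Cox HR (high vs low ICI score) for a forest plot.

    ``strata_definitions`` maps a stratum name to a boolean sample mask over
    the clinical table. Strata below ``min_stratum_size`` (or with a single
    ICI group) are skipped with a log entry.
    """
    df = clinical.data
    groups = ici_groups.loc[df.index]
    out: list[StratumHR] = []
    for name, mask in strata_definitions.items():
        mask = mask.reindex(df.index).fillna(False).astype(bool)
        sub = df[mask]
        if len(sub) < min_stratum_size:
            logger.info("stratum %s skipped: %d samples", name, len(sub))
            continue
        g = (groups[mask] == "high").astype(float)
        if g.nunique() < 2 or sub["os_event"].sum() == 0:
            logger.info("stratum %s skipped: degenerate grouping", name)
            continue
        out.append(
            cox_hr(sub["os_time"], sub["os_event"], g.to_numpy(), stratum=name)
        )
    return out


def km_by_group(
    clinical: ClinicalTable, groups: pd.Series
) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group label (convenience for plots/exports)."""
    df = clinical.data
    g = groups.loc[df.index]
    return {
        str(label): kaplan_meier(sub["os_time"], sub["os_event"])
        for label, sub in df.groupby(g)
    }
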