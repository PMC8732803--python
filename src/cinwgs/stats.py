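"""Cohort-level statistics: Fisher exact, chi-square, proportion trend,
Kaplan-Meier, log-rank and Cox proportional hazards.

Fisher's two-sided p uses the probability-mass rule (sum of hypergeometric
point probabilities no larger than the observed table's). The Kaplan-Meier
estimator is implemented directly (with Greenwood variance); the Cox model
delegates to statsmodels' partial-likelihood machinery with Breslow ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

_REL_TOL = 1e-7  # relative slack on the "<= observed pmf" comparison


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: bool  # recurrence/death (True) vs censored (False)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: non-positive time {self.time}")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, probability-mass rule."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts")
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    if r1 in (0, n) or c1 in (0, n):
        warnings.warn("degenerate margin: p = 1")
        return 1.0
    a_obs = int(t[0, 0])
    dist = sps.hypergeom(n, r1, c1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a_obs)
    included = pmf <= p_obs * (1 + _REL_TOL)
    if included.all():
        return 1.0
    return min(float(pmf[included].sum()), 1.0)


def chisq_test(table) -> tuple[float, float, int]:
    """Pearson chi-square without continuity correction: (stat, p, df)."""
    t = np.asarray(table, dtype=float)
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(df)


def prop_trend_test(successes, totals, scores=None) -> tuple[float, float]:
    """Cochran-Armitage trend test: signed Z statistic and two-sided p."""
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1:
        raise ValueError("successes and totals must be equal-length vectors")
    if (x > n).any() or (x < 0).any() or (n <= 0).any():
        raise ValueError("invalid counts")
    s = np.arange(len(x), dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != x.shape:
        raise ValueError("scores length mismatch")
    N = n.sum()
    pbar = x.sum() / N
    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class KaplanMeier:
    """Product-limit estimate with Greenwood variance."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    variance: np.ndarray  # Greenwood variance of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation (right-continuous), S(0-) = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)


def km_estimate(records: list[SurvivalRecord]) -> KaplanMeier:
    if not records:
        raise ValueError("no records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times = np.unique(times[events])
    surv, var_terms, at_risk, n_ev = [], [], [], []
    s = 1.0
    gw = 0.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & events))
        s *= 1 - d_i / n_i
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            var = s**2 * gw
        else:
            var = 0.0  # S = 0, variance degenerate
        surv.append(s)
        var_terms.append(var)
        at_risk.append(n_i)
        n_ev.append(d_i)
    return KaplanMeier(
        times=event_times,
        survival=np.asarray(surv),
        variance=np.asarray(var_terms),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


def logrank_test(groups: dict[str, list[SurvivalRecord]]) -> tuple[float, float, int]:
    """Standard log-rank chi-square across >= 2 groups: (stat, p, df)."""
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    times = np.concatenate([[r.time for r in groups[g]] for g in labels])
    events = np.concatenate([[r.event for r in groups[g]] for g in labels]).astype(bool)
    memb = np.concatenate(
        [np.full(len(groups[g]), gi) for gi, g in enumerate(labels)]
    )

    event_times = np.unique(times[events])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & events).sum()
        n_g = np.array([(at_risk & (memb == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array(
            [((times == t) & events & (memb == g)).sum() for g in range(k)],
            dtype=float,
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    V[a, b] += c * (n_g[a] / n) * ((a == b) - n_g[b] / n)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, p, df


@dataclass
class CoxResult:
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    log_hr: dict[str, float]
    se: dict[str, float]
    converged: bool
    unreliable: bool  # monotone likelihood / separation suspected


def cox_fit(
    records: list[SurvivalRecord], covariates: list[str], ties: str = "breslow"
) -> CoxResult:
    """Cox proportional hazards via partial likelihood (Breslow ties).

    Wald confidence intervals and p-values. Complete separation is flagged
    via absurd coefficient magnitude or standard error.
    """
    import statsmodels.api as sm

    if not any(r.event for r in records):
        raise ValueError("no events in data")
    X = pd.DataFrame([{c: r.covariates[c] for c in covariates} for r in records])
    for c in covariates:
        if X[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} has zero variance")
    time = np.array([r.time for r in records], dtype=float)
    status = np.array([r.event for r in records], dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.PHReg(time, X.to_numpy(dtype=float), status=status, ties=ties)
        fit = model.fit(disp=False)
    beta = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    zcrit = sps.norm.ppf(0.975)
    unreliable = bool(np.any(np.abs(beta) > 15) or np.any(se > 100))
    pvals = 2 * sps.norm.sf(np.abs(beta) / se)
    return CoxResult(
        hazard_ratios={c: float(np.exp(b)) for c, b in zip(covariates, beta)},
        ci_lower={c: float(np.exp(b - zcrit * s)) for c, b, s in zip(covariates, beta, se)},
        ci_upper={c: float(np.exp(b + zcrit * s)) for c, b, s in zip(covariates, beta, se)},
        p_values={c: float(p) for c, p in zip(covariates, pvals)},
        log_hr={c: float(b) for c, b in zip(covariates, beta)},
        se={c: float(s) for c, s in zip(covariates, se)},
        converged=True,
        unreliable=unreliable,
    )
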