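"""Survival comparison between stratification profiles.

Implements the three pieces of machinery the profile comparison needs:
the Kaplan-Meier product-limit estimator per group, the two-group log-rank
test, and a two-group Cox proportional-hazards fit (single binary
covariate, Breslow tie handling) maximized by safeguarded Newton iteration
with a Wald confidence interval and p-value.

All functions take a tidy frame with columns ``time`` (follow-up, >= 0),
``event`` (1 = recurrence observed, 0 = censored) and ``group``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm


def _check(data: pd.DataFrame) -> pd.DataFrame:
    t = np.asarray(data["time"], dtype=float)
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("times must be finite and nonnegative")
    ev = set(np.asarray(data["event"]).tolist())
    if not ev <= {0, 1}:
        raise ValueError("event must be 0/1")
    return data


@dataclass
class KmCurve:
    """One group's product-limit estimate: S(t) right-continuous step
    function with steps at event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_fit(data: pd.DataFrame) -> dict[str, KmCurve]:
    """Kaplan-Meier estimate per group.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored
    subjects leave the risk set without a step.
    """
    _check(data)
    curves = {}
    for label, grp in data.groupby("group"):
        t = grp["time"].to_numpy(dtype=float)
        e = grp["event"].to_numpy(dtype=int)
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        ev_times = np.unique(t[e == 1])
        surv, at_risk, n_ev = [], [], []
        s = 1.0
        for ti in ev_times:
            n_i = int((t >= ti).sum())
            d_i = int(((t == ti) & (e == 1)).sum())
            s *= 1.0 - d_i / n_i
            surv.append(s)
            at_risk.append(n_i)
            n_ev.append(d_i)
        curves[label] = KmCurve(times=ev_times, survival=np.asarray(surv),
                                n_at_risk=np.asarray(at_risk),
                                n_events=np.asarray(n_ev))
    return curves


def logrank_test(data: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation given the pooled risk set;
    chi2 = (sum O - E)^2 / sum V on 1 df.
    """
    _check(data)
    labels = sorted(data["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {len(labels)}")
    t = data["time"].to_numpy(dtype=float)
    e = data["event"].to_numpy(dtype=int)
    g = (data["group"] == labels[1]).to_numpy()
    if e.sum() == 0:
        raise ValueError("no events")
    o_minus_e, var = 0.0, 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class CoxFit:
    """Two-group Cox fit: log hazard ratio of group 1 vs group 0 (reference,
    first label in sorted order), Wald SE/CI/p."""

    log_hr: float
    se: float
    p: float
    hr: float = field(init=False)
    ci95: tuple = field(init=False)
    reference: str = ""
    comparison: str = ""
    converged: bool = True
    diverged_sign: int = 0   # +-1 when the partial likelihood is monotone

    def __post_init__(self):
        self.hr = math.exp(self.log_hr) if math.isfinite(self.log_hr) else math.nan
        if math.isfinite(self.log_hr) and math.isfinite(self.se):
            self.ci95 = (math.exp(self.log_hr - 1.96 * self.se),
                         math.exp(self.log_hr + 1.96 * self.se))
        else:
            self.ci95 = (math.nan, math.nan)


def _breslow_terms(data: pd.DataFrame):
    """Per distinct event time: (events in group1, total events,
    group1 at risk, group0 at risk)."""
    labels = sorted(data["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"Cox fit needs exactly 2 groups, found {len(labels)}")
    t = data["time"].to_numpy(dtype=float)
    e = data["event"].to_numpy(dtype=int)
    x = (data["group"] == labels[1]).to_numpy()
    terms = []
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        terms.append((
            int(((t == ti) & (e == 1) & x).sum()),
            int(((t == ti) & (e == 1)).sum()),
            int((at_risk & x).sum()),
            int((at_risk & ~x).sum()),
        ))
    return labels, terms


def cox_partial_loglik(beta: float, terms) -> float:
    """Breslow partial log-likelihood for a single binary covariate."""
    ll = 0.0
    for m, d, n1, n0 in terms:
        ll += beta * m - d * math.log(n0 + n1 * math.exp(beta))
    return ll


def cox_two_group(data: pd.DataFrame, tol: float = 1e-8,
                  max_iter: int = 100) -> CoxFit:
    """Two-group Cox proportional-hazards estimate.

    Maximizes the Breslow partial likelihood by Newton iteration with step
    halving, converged when |score| < ``tol``. When all events fall in one
    group the likelihood is monotone; the fit is flagged diverged with the
    sign of the runaway estimate instead of reporting a number.
    """
    _check(data)
    labels, terms = _breslow_terms(data)
    if not terms:
        raise ValueError("no events")
    m_tot = sum(m for m, _, _, _ in terms)
    d_tot = sum(d for _, d, _, _ in terms)
    # monotone likelihood: every event in one group while both are at risk
    if all(m == d for m, d, _, _ in terms) or m_tot == 0:
        sign = 1 if m_tot > 0 else -1
        return CoxFit(log_hr=math.nan, se=math.nan, p=math.nan,
                      reference=str(labels[0]), comparison=str(labels[1]),
                      converged=False, diverged_sign=sign)

    beta = 0.0
    ll = cox_partial_loglik(beta, terms)
    converged = False
    for _ in range(max_iter):
        score, info = 0.0, 0.0
        for m, d, n1, n0 in terms:
            w = n1 * math.exp(beta)
            p1 = w / (n0 + w)
            score += m - d * p1
            info += d * p1 * (1 - p1)
        if abs(score) < tol:
            converged = True
            break
        if info <= 0:
            break
        step = score / info
        step = max(min(step, 5.0), -5.0)
        # step halving safeguard
        for _ in range(30):
            new_beta = beta + step
            new_ll = cox_partial_loglik(new_beta, terms)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll = new_beta, new_ll
        if abs(beta) > 20:
            return CoxFit(log_hr=math.nan, se=math.nan, p=math.nan,
                          reference=str(labels[0]), comparison=str(labels[1]),
                          converged=False, diverged_sign=int(math.copysign(1, beta)))
    info = sum(d * (n1 * math.exp(beta) / (n0 + n1 * math.exp(beta)))
               * (1 - n1 * math.exp(beta) / (n0 + n1 * math.exp(beta)))
               for m, d, n1, n0 in terms)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = float(2 * norm.sf(abs(z)))
    return CoxFit(log_hr=float(beta), se=float(se), p=max(p, 5e-324),
                  reference=str(labels[0]), comparison=str(labels[1]),
                  converged=converged)


def km_plot(curves: dict[str, KmCurve], path=None, title: str = ""):
    """Optional Kaplan-Meier step plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], np.repeat(c.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(c.survival, 2)[:-1]])
        ax.plot(t, s, label=str(label))
    ax.set_xlabel("time")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
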