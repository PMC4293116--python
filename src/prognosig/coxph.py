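"""Cox proportional-hazards fitting on the Breslow partial likelihood.

The screening stage fits thousands of univariate models with a single
binary covariate (low/high expression group), so that case is vectorised
across genes: the risk-set sufficient statistics reduce to counts of
high-group samples at risk at each distinct event time, and the Newton
iteration runs on whole arrays. The multivariate fitter (risk group
adjusted for stage/grade) uses a dense Newton-Raphson with step-halving.

Ties are handled with the Breslow approximation. Monotone likelihoods
(complete separation of the event order) are reported with a
``separated`` flag rather than a silently divergent estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxResult",
    "cox_two_group",
    "cox_two_group_batch",
    "cox_multivariate",
    "breslow_loglik",
]

#: |beta| beyond which the likelihood is treated as monotone (separation)
SEPARATION_BOUND = 15.0
MAX_ITER = 50
TOL = 1e-8


@dataclass
class CoxResult:
    """One fitted Cox coefficient with Wald inference."""

    name: str
    beta: float
    se: float
    p_wald: float
    n: int
    n_events: int
    separated: bool = False
    p_logrank: Optional[float] = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return (float(lo), float(hi))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci95
        flag = " SEPARATED" if self.separated else ""
        return (
            f"<CoxResult {self.name}: HR={self.hr:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f}), p={self.p_wald:.3g}{flag}>"
        )


def _validate_survival(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    return times, events


def _risk_set_layout(times, events):
    """Sort by time and precompute distinct-event-time bookkeeping.

    Returns the sort order plus, per distinct event time, the index of the
    first at-risk sample in sorted order and the death count.
    """
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    event_times = np.unique(ts[es == 1])
    first_idx = np.searchsorted(ts, event_times, side="left")
    death_count = np.array([int(((ts == t) & (es == 1)).sum()) for t in event_times])
    return order, ts, es, event_times, first_idx, death_count


def breslow_loglik(beta, times, events, x):
    """Breslow log partial likelihood for a single covariate vector."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    order, ts, es, etimes, first, d = _risk_set_layout(times, events)
    xs = x[order]
    eta = beta * xs
    ll = float(eta[es == 1].sum())
    exps = np.exp(eta)
    # suffix sums give risk-set totals
    suffix = np.concatenate([np.cumsum(exps[::-1])[::-1], [0.0]])
    for j, i0 in enumerate(first):
        ll -= d[j] * np.log(suffix[i0])
    return ll


def cox_two_group_batch(times, events, groups: np.ndarray):
    """Fit univariate binary-covariate Cox models for many genes at once.

    Parameters
    ----------
    times, events : arrays of length n
    groups : bool/int array (n_genes, n), 1 = high group

    Returns
    -------
    DataFrame with columns beta, se, p_wald, separated, degenerate,
    n, n_events (one row per gene, in input order).
    """
    times, events = _validate_survival(times, events)
    G = np.atleast_2d(np.asarray(groups, dtype=float))
    if G.shape[1] != len(times):
        raise ValueError("groups must have one column per sample")
    n, n_events = len(times), int(events.sum())

    order, ts, es, etimes, first, d = _risk_set_layout(times, events)
    Gs = G[:, order]
    # per distinct event time: high-group at-risk count r1, total at risk r
    suffix1 = np.concatenate(
        [np.cumsum(Gs[:, ::-1], axis=1)[:, ::-1], np.zeros((G.shape[0], 1))], axis=1
    )
    r1 = suffix1[:, first]  # (genes, J)
    r_tot = (len(ts) - first).astype(float)  # (J,)
    r0 = r_tot[None, :] - r1
    sumx = Gs[:, es == 1].sum(axis=1)  # Σ x over deaths
    dvec = d.astype(float)

    degenerate = (G.std(axis=1) == 0) | (G.min(axis=1) < 0) | (G.max(axis=1) > 1)

    def loglik(beta):
        eb = np.exp(beta)[:, None]
        return beta * sumx - (dvec[None, :] * np.log(r0 + eb * r1)).sum(axis=1)

    beta = np.zeros(G.shape[0])
    sep = np.zeros(G.shape[0], dtype=bool)
    done = degenerate.copy()
    ll = loglik(beta)
    for _ in range(MAX_ITER):
        eb = np.exp(beta)[:, None]
        denom = r0 + eb * r1
        frac = eb * r1 / denom
        U = sumx - (dvec[None, :] * frac).sum(axis=1)
        info = (dvec[None, :] * frac * (1.0 - frac)).sum(axis=1)
        step = np.where(info > 1e-300, U / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        step[done] = 0.0
        new_beta = beta + step
        new_ll = loglik(new_beta)
        # step-halving where the likelihood worsened
        for _h in range(30):
            worse = (~done) & (new_ll < ll - 1e-12)
            if not worse.any():
                break
            new_beta = np.where(worse, 0.5 * (beta + new_beta), new_beta)
            new_ll = loglik(new_beta)
        moved = np.abs(new_beta - beta)
        beta, ll = new_beta, new_ll
        sep |= (~done) & (np.abs(beta) > SEPARATION_BOUND)
        done |= sep | (moved < TOL)
        if done.all():
            break

    eb = np.exp(beta)[:, None]
    frac = eb * r1 / (r0 + eb * r1)
    info = (dvec[None, :] * frac * (1.0 - frac)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(info), np.inf)
        z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(degenerate | sep, np.nan, p)
    beta_out = np.where(degenerate, np.nan, beta)
    beta_out = np.where(sep, np.sign(beta) * np.inf, beta_out)
    return pd.DataFrame(
        {
            "beta": beta_out,
            "se": se,
            "p_wald": p,
            "separated": sep,
            "degenerate": degenerate,
            "n": n,
            "n_events": n_events,
        }
    )


def cox_two_group(times, events, groups, name: str = "group") -> CoxResult:
    """Univariate Cox model for a single binary low/high grouping.

    ``groups`` may be boolean, 0/1, or the string labels ``low``/``high``;
    1/``high`` is the indicator level whose hazard ratio is reported.
    """
    g = np.asarray(groups)
    if g.dtype.kind in "UO":
        g = (g == "high").astype(int)
    g = g.astype(float)
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be non-empty")
    res = cox_two_group_batch(times, events, g[None, :]).iloc[0]
    return CoxResult(
        name=name,
        beta=float(res["beta"]),
        se=float(res["se"]),
        p_wald=float(res["p_wald"]) if np.isfinite(res["se"]) else np.nan,
        n=int(res["n"]),
        n_events=int(res["n_events"]),
        separated=bool(res["separated"]),
    )


def cox_multivariate(times, events, covariates: pd.DataFrame) -> "list[CoxResult]":
    """Multivariable Cox model; one :class:`CoxResult` per covariate.

    Constant columns are dropped with a warning; rank deficiency after the
    drop is an error. Separation is flagged per covariate.
    """
    times, events = _validate_survival(times, events)
    X = covariates.astype(float)
    if X.isna().to_numpy().any():
        raise ValueError("covariates contain missing values; drop those samples first")
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}", UserWarning)
    if not keep:
        raise ValueError("no non-constant covariates remain")
    Xm = X[keep].to_numpy()
    if np.linalg.matrix_rank(Xm - Xm.mean(axis=0)) < Xm.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    order, ts, es, etimes, first, d = _risk_set_layout(times, events)
    Xs = Xm[order]
    n, p = Xs.shape
    dvec = d.astype(float)
    sum_x_events = Xs[es == 1].sum(axis=0)

    def score_info(beta):
        eta = Xs @ beta
        shift = eta.max()  # overflow guard; cancels exactly since Σd_j = n_events
        w = np.exp(eta - shift)
        # suffix sums over the sorted samples
        S0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        wx = w[:, None] * Xs
        S1 = np.vstack([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros(p)])
        ll = float((eta[es == 1] - shift).sum())
        U = sum_x_events.copy()
        H = np.zeros((p, p))
        for j, i0 in enumerate(first):
            s0 = S0[i0]
            xbar = S1[i0] / s0
            ll -= dvec[j] * np.log(s0)
            U -= dvec[j] * xbar
            block = Xs[i0:]
            wB = w[i0:]
            S2 = (wB[:, None] * block).T @ block
            H += dvec[j] * (S2 / s0 - np.outer(xbar, xbar))
        return ll, U, H

    beta = np.zeros(p)
    ll, U, H = score_info(beta)
    for _ in range(MAX_ITER):
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, U, rcond=None)[0]
        norm = np.linalg.norm(step)
        if norm > 2.0:
            step *= 2.0 / norm
        new_beta = beta + step
        new_ll, new_U, new_H = score_info(new_beta)
        halved = 0
        while new_ll < ll - 1e-12 and halved < 30:
            new_beta = 0.5 * (beta + new_beta)
            new_ll, new_U, new_H = score_info(new_beta)
            halved += 1
        moved = np.max(np.abs(new_beta - beta))
        beta, ll, U, H = new_beta, new_ll, new_U, new_H
        if moved < TOL or np.any(np.abs(beta) > SEPARATION_BOUND):
            break

    sep_mask = np.abs(beta) > SEPARATION_BOUND
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    results = []
    for k, name in enumerate(keep):
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[k] / se[k] if se[k] > 0 else 0.0
        results.append(
            CoxResult(
                name=name,
                beta=float(beta[k]),
                se=float(se[k]),
                p_wald=float(2.0 * stats.norm.sf(abs(z))) if not sep_mask[k] else np.nan,
                n=n,
                n_events=int(events.sum()),
                separated=bool(sep_mask[k]),
            )
        )
    return results
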