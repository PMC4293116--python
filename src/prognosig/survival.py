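"""Survival-based validation of predicted risk groups.

Kaplan-Meier curves and the log-rank test are delegated to lifelines;
Cox models (uni- and multivariable, Breslow ties) come from
:mod:`prognosig.coxph`. The 20-month confusion-table accuracy follows
the source protocol literally: a patient's *actual* class is high-risk
when the recorded time is at or below the threshold, regardless of
censoring, with an opt-in flag to exclude patients censored before the
threshold (whose true class is unknown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import ClinicalTable
from .coxph import CoxResult, cox_multivariate as _cox_multivariate, cox_two_group

__all__ = [
    "KMCurve",
    "ConfusionSummary",
    "km_curve",
    "logrank_test",
    "survival_fraction_at",
    "cox_multivariate",
    "confusion_accuracy",
    "risk_labels_from_survival",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray  # distinct event times, sorted
    at_risk: np.ndarray  # n at risk just before each event time
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray

    def __post_init__(self):
        if ((self.survival < -1e-12) | (self.survival > 1 + 1e-12)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_j/n_j)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        survival=surv.loc[ev.index].to_numpy(dtype=float),
        censor_times=np.sort(times[events == 0]),
    )


def survival_fraction_at(curve: KMCurve, t: float) -> float:
    """S(t) under the right-continuous step convention ('beyond t')."""
    if t < 0:
        raise ValueError("t must be >= 0")
    past = curve.times <= t
    if not past.any():
        return 1.0
    return float(curve.survival[past][-1])


def logrank_test(times, events, groups) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) on 1 degree of freedom."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    if len(labs) != 2:
        raise ValueError("exactly two non-empty groups required")
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    mask = groups == labs[0]
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_multivariate(
    times,
    events,
    covariates: pd.DataFrame,
) -> List[CoxResult]:
    """Multivariable Breslow Cox model (thin re-export; see coxph)."""
    return _cox_multivariate(times, events, covariates)


def risk_group_covariates(
    risk: pd.Series,
    clinical: ClinicalTable,
    adjust: Sequence[str] = (),
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Assemble (times, events, design) for risk-group Cox models.

    ``adjust`` may contain ``stage`` and/or ``grade``; stage is encoded
    IA/IB/IIA = 0 vs IIB/III/IV = 1 and grade 1/2 = 0 vs 3/4 = 1. Samples
    missing a requested covariate are dropped.
    """
    df = pd.DataFrame(index=clinical.sample_ids)
    df["risk_high"] = (risk.reindex(clinical.sample_ids).astype(str) == "high").astype(
        float
    )
    if "stage" in adjust:
        df["stage_late"] = clinical.stage_binary()
    if "grade" in adjust:
        df["grade_high"] = clinical.grade_binary()
    keep = df.notna().all(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} sample(s) missing stage/grade", UserWarning
        )
    df = df[keep]
    clin = clinical.loc(list(df.index))
    return clin.time.to_numpy(), clin.event.to_numpy(), df


@dataclass
class ConfusionSummary:
    """2x2 classification table; positive = predicted high risk."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else np.nan

    def as_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion_accuracy(
    predicted: pd.Series,
    clinical: ClinicalTable,
    threshold: float = 20.0,
    exclude_censored_before_threshold: bool = False,
) -> ConfusionSummary:
    """Compare predicted risk groups to the survival-time dichotomy.

    Actual class is high-risk when time <= ``threshold`` months (low when
    the patient survived beyond it), taken from the recorded time
    regardless of censoring; ``exclude_censored_before_threshold`` drops
    patients censored before the threshold, whose actual class is
    unknowable.
    """
    if len(clinical) == 0:
        raise ValueError("empty clinical table")
    pred = predicted.reindex(clinical.sample_ids).astype(str)
    if pred.isna().any() or (~pred.isin(["low", "high"])).any():
        bad = pred.index[~pred.isin(["low", "high"])].tolist()
        raise ValueError(f"predictions must cover all samples with low/high: {bad[:5]}")
    time = clinical.time
    event = clinical.event
    keep = pd.Series(True, index=clinical.sample_ids)
    if exclude_censored_before_threshold:
        keep = ~((event == 0) & (time <= threshold))
    actual_high = (time <= threshold)[keep]
    pred_high = (pred == "high")[keep]
    tp = int((pred_high & actual_high).sum())
    fp = int((pred_high & ~actual_high).sum())
    fn = int((~pred_high & actual_high).sum())
    tn = int((~pred_high & ~actual_high).sum())
    if tp + fp + tn + fn == 0:
        raise ValueError("no samples left to tabulate")
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def risk_labels_from_survival(clinical: ClinicalTable, threshold: float = 20.0) -> pd.Series:
    """Observed risk class: 'high' when time <= threshold months."""
    return pd.Series(
        np.where(clinical.time <= threshold, "high", "low"),
        index=clinical.sample_ids,
        name="risk",
    )
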