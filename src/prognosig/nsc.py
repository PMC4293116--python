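"""Nearest-shrunken-centroid (NSC / PAM-style) risk classification.

Per gene i and class k the standardised centroid deviation is

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k + 1/n)

with s_i the pooled within-class standard deviation (divisor n - K) and
s0 the median of the s_i (the fudge that keeps low-variance genes from
dominating). Soft-thresholding |d_ik| by Delta shrinks centroids toward
the overall centroid; genes whose deviations all reach zero drop out of
the classifier, so the surviving set at the selected threshold IS the
gene signature. The threshold is chosen by leave-one-out
cross-validation, taking the largest Delta attaining the minimum error
(the most parsimonious signature among the best).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "ShrunkenCentroidModel",
    "CVProfile",
    "train_nsc",
    "predict_nsc",
    "loocv_select_threshold",
    "signature_genes",
]


@dataclass
class ShrunkenCentroidModel:
    """Fitted NSC classifier; all arrays indexed by ``genes`` x ``classes``."""

    classes: List[str]
    genes: List[str]
    overall_centroid: np.ndarray  # (G,)
    centroids: np.ndarray  # (G, K) raw class means
    shrunken_centroids: np.ndarray  # (G, K)
    s: np.ndarray  # (G,) pooled within-class sd
    s0: float
    m_k: np.ndarray  # (K,)
    priors: np.ndarray  # (K,)
    delta: float
    dik: np.ndarray  # (G, K) unshrunk standardised deviations
    m_rule: str = "plus"

    def __post_init__(self):
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if (self.s < 0).any():
            raise ValueError("pooled deviations must be non-negative")

    @property
    def shrunken_dik(self) -> np.ndarray:
        return _soft_threshold(self.dik, self.delta)

    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes,
            "genes": self.genes,
            "overall_centroid": self.overall_centroid.tolist(),
            "centroids": self.centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "s": self.s.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "priors": self.priors.tolist(),
            "delta": self.delta,
            "dik": self.dik.tolist(),
            "m_rule": self.m_rule,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ShrunkenCentroidModel":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("overall_centroid", "centroids", "shrunken_centroids", "s", "m_k", "priors", "dik"):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


@dataclass
class CVProfile:
    """LOOCV error counts over the shrinkage grid."""

    deltas: np.ndarray
    errors: np.ndarray  # misclassification counts per delta
    selected_delta: float
    n_folds: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta": self.deltas, "errors": self.errors})


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _class_stats(X: np.ndarray, y: np.ndarray, classes: List[str], m_rule: str):
    """Centroids, pooled sd, fudge and class factors for data X (G x n)."""
    n = X.shape[1]
    K = len(classes)
    nk = np.array([(y == c).sum() for c in classes], dtype=float)
    overall = X.mean(axis=1)
    centroids = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    ss = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        resid = X[:, y == c] - centroids[:, [j]]
        ss += (resid**2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if m_rule == "plus":
        m_k = np.sqrt(1.0 / nk + 1.0 / n)
    elif m_rule == "minus":
        m_k = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 0.0))
    else:
        raise ValueError("m_rule must be 'plus' or 'minus'")
    return overall, centroids, s, s0, m_k, nk


def train_nsc(
    expr: ExpressionMatrix,
    labels: pd.Series,
    delta: float,
    m_rule: str = "plus",
    uniform_priors: bool = False,
    classes: Optional[Sequence[str]] = None,
) -> ShrunkenCentroidModel:
    """Fit the shrunken-centroid model at shrinkage threshold ``delta``."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    y = labels.reindex(expr.sample_ids)
    if y.isna().any():
        missing = y.index[y.isna()].tolist()
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    y = y.astype(str).to_numpy()
    if classes is None:
        classes = sorted(set(y))
    else:
        classes = [str(c) for c in classes]
        if set(y) - set(classes):
            raise ValueError("labels contain classes outside the supplied order")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")

    X = expr.values.to_numpy()
    overall, centroids, s, s0, m_k, nk = _class_stats(X, y, classes, m_rule)
    denom = (m_k[None, :] * (s + s0)[:, None])
    dik = (centroids - overall[:, None]) / denom
    dshr = _soft_threshold(dik, delta)
    shrunken = overall[:, None] + denom * dshr
    priors = np.full(len(classes), 1.0 / len(classes)) if uniform_priors else nk / nk.sum()
    return ShrunkenCentroidModel(
        classes=list(classes),
        genes=list(expr.gene_ids),
        overall_centroid=overall,
        centroids=centroids,
        shrunken_centroids=shrunken,
        s=s,
        s0=s0,
        m_k=m_k,
        priors=priors,
        delta=float(delta),
        dik=dik,
        m_rule=m_rule,
    )


def predict_nsc(
    model: ShrunkenCentroidModel, expr: ExpressionMatrix
) -> Tuple[pd.Series, pd.DataFrame]:
    """Classify samples by the shrunken-centroid discriminant.

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k,
    summed over the model's genes; ties go to the first class in model
    order. Genes of the model absent from ``expr`` are dropped with a
    warning (an error if none overlap). Returns predicted labels and the
    per-class discriminant scores.
    """
    present = [g for g in model.genes if g in set(expr.gene_ids)]
    if not present:
        raise KeyError("no overlap between model genes and expression matrix")
    if len(present) < len(model.genes):
        warnings.warn(
            f"{len(model.genes) - len(present)} model gene(s) missing from the "
            "matrix; predicting on the intersection",
            UserWarning,
        )
    idx = [model.genes.index(g) for g in present]
    X = expr.values.loc[present].to_numpy()  # (G', n)
    cent = model.shrunken_centroids[idx]  # (G', K)
    scale = (model.s + model.s0)[idx]
    diff = X[:, :, None] - cent[:, None, :]  # (G', n, K)
    scores = (diff**2 / scale[:, None, None] ** 2).sum(axis=0) - 2.0 * np.log(
        model.priors
    )[None, :]
    best = np.argmin(scores, axis=1)  # argmin takes the first (= model order) on ties
    labels = pd.Series(
        [model.classes[k] for k in best], index=expr.sample_ids, name="predicted"
    )
    score_df = pd.DataFrame(scores, index=expr.sample_ids, columns=model.classes)
    return labels, score_df


def signature_genes(model: ShrunkenCentroidModel) -> List[str]:
    """Genes with any nonzero shrunken deviation at the model's delta."""
    surviving = np.abs(model.shrunken_dik).sum(axis=1) > 0
    return [g for g, keep in zip(model.genes, surviving) if keep]


def loocv_select_threshold(
    expr: ExpressionMatrix,
    labels: pd.Series,
    grid_size: int = 30,
    m_rule: str = "plus",
    uniform_priors: bool = False,
    classes: Optional[Sequence[str]] = None,
) -> Tuple[CVProfile, ShrunkenCentroidModel]:
    """Choose the shrinkage threshold by leave-one-out cross-validation.

    The grid is ``grid_size`` equally spaced values on [0, max |d_ik|] of
    the full-data fit. Each sample is left out in turn, the model refitted
    and the sample predicted at every grid value; the selected Delta* is
    the LARGEST grid value attaining the minimum error count, and the
    returned model is refitted on all data at Delta*. Folds that would
    leave a class with fewer than 2 samples are skipped with a warning.
    """
    if expr.n_samples < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    full = train_nsc(expr, labels, 0.0, m_rule, uniform_priors, classes)
    dmax = float(np.abs(full.dik).max())
    deltas = np.linspace(0.0, dmax, grid_size)

    y = labels.reindex(expr.sample_ids).astype(str).to_numpy()
    X = expr.values.to_numpy()
    cls = full.classes
    K = len(cls)
    errors = np.zeros(grid_size)
    n_folds = 0
    skipped = 0
    for i in range(expr.n_samples):
        mask = np.ones(expr.n_samples, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if min((y_tr == c).sum() for c in cls) < 2:
            skipped += 1
            continue
        n_folds += 1
        overall, centroids, s, s0, m_k, nk = _class_stats(X[:, mask], y_tr, cls, m_rule)
        denom = m_k[None, :] * (s + s0)[:, None]
        dik = (centroids - overall[:, None]) / denom
        priors = (
            np.full(K, 1.0 / K) if uniform_priors else nk / nk.sum()
        )
        x = X[:, i]
        # all deltas at once: (D, G, K) shrunken deviations
        dshr = _soft_threshold(dik[None, :, :], deltas[:, None, None])
        cent = overall[None, :, None] + denom[None, :, :] * dshr
        diff = x[None, :, None] - cent
        scores = (diff**2 / ((s + s0) ** 2)[None, :, None]).sum(axis=1)
        scores = scores - 2.0 * np.log(priors)[None, :]
        pred = np.argmin(scores, axis=1)
        truth = cls.index(y[i])
        errors += pred != truth
    if n_folds == 0:
        raise ValueError("all LOOCV folds were skipped (classes too small)")
    if skipped:
        warnings.warn(f"skipped {skipped} LOOCV fold(s) leaving a class < 2", UserWarning)

    best = errors.min()
    delta_star = float(deltas[np.nonzero(errors == best)[0].max()])
    profile = CVProfile(
        deltas=deltas, errors=errors, selected_delta=delta_star, n_folds=n_folds
    )
    final = train_nsc(expr, labels, delta_star, m_rule, uniform_priors, cls)
    return profile, final
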