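"""End-to-end signature discovery as a fit/results pair.

:class:`PrognosticSignatureModel` bundles the protocol that turns a
training cohort (expression + survival) and a candidate gene pool into a
risk classifier: univariate median-split Cox screening, then a
nearest-shrunken-centroid fit whose shrinkage threshold is chosen by
leave-one-out cross-validation against the observed 20-month risk
classes. ``fit()`` returns a :class:`PrognosticSignatureResults` holding
the signature (the classifier's surviving genes), the CV profile and
training accuracies, with methods to predict risk groups on new cohorts
and to validate them (Kaplan-Meier, log-rank, Cox with optional
stage/grade adjustment, 20-month confusion accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .coxph import CoxResult, cox_multivariate, cox_two_group
from .dwd import dwd_adjust
from .nsc import (
    CVProfile,
    ShrunkenCentroidModel,
    loocv_select_threshold,
    predict_nsc,
    signature_genes,
)
from .selection import select_prognostic_genes
from .survival import (
    confusion_accuracy,
    km_curve,
    logrank_test,
    risk_group_covariates,
    risk_labels_from_survival,
)

__all__ = ["PrognosticSignatureModel", "PrognosticSignatureResults", "DegenerateRunError"]


class DegenerateRunError(RuntimeError):
    """The protocol could not produce a classifier (no genes / one class)."""


class PrognosticSignatureModel:
    """Prognostic-signature discovery protocol bound to a training cohort.

    Parameters
    ----------
    expr : ExpressionMatrix
        Training expression (typically a DWD-merged multi-cohort matrix).
    clinical : ClinicalTable
        Matching survival data; must cover every training sample.
    candidates : sequence of genes, optional
        The candidate pool entering prognostic selection (e.g. the
        differentially expressed genes); defaults to all genes.
    alpha : float
        Wald-P threshold of the univariate screen (default 0.05).
    risk_threshold_months : float or "median"
        Survival dichotomy defining the training risk classes
        (default 20 months; "median" uses the median observed time,
        guaranteeing balanced training classes).
    grid_size : int
        Number of shrinkage-threshold grid points for LOOCV.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        clinical: ClinicalTable,
        candidates: Optional[Sequence[str]] = None,
        alpha: float = 0.05,
        risk_threshold_months: float = 20.0,
        grid_size: int = 30,
        m_rule: str = "plus",
        uniform_priors: bool = False,
    ):
        missing = [s for s in expr.sample_ids if s not in clinical.sample_ids]
        if missing:
            raise ValueError(f"clinical table lacks training samples: {missing[:5]}")
        self.expr = expr
        self.clinical = clinical.loc(list(expr.sample_ids))
        self.candidates = list(candidates) if candidates is not None else list(expr.gene_ids)
        self.alpha = alpha
        if risk_threshold_months == "median":
            risk_threshold_months = float(np.median(self.clinical.time))
        self.risk_threshold_months = float(risk_threshold_months)
        self.grid_size = grid_size
        self.m_rule = m_rule
        self.uniform_priors = uniform_priors

    @classmethod
    def from_cohorts(
        cls,
        expr_a: ExpressionMatrix,
        expr_b: ExpressionMatrix,
        clin_a: ClinicalTable,
        clin_b: ClinicalTable,
        **kwargs,
    ) -> "PrognosticSignatureModel":
        """Build the model from two cohorts, DWD-merging their expression."""
        merged = dwd_adjust(expr_a, expr_b)
        clinical = clin_a.concat(clin_b)
        return cls(merged, clinical, **kwargs)

    def fit(self) -> "PrognosticSignatureResults":
        """Run selection + LOOCV shrinkage search; returns the results."""
        kept, cox_table = select_prognostic_genes(
            self.expr, self.clinical, self.candidates, alpha=self.alpha
        )
        if not kept:
            raise DegenerateRunError("no candidate gene passed prognostic selection")
        labels = risk_labels_from_survival(self.clinical, self.risk_threshold_months)
        if labels.nunique() < 2 or labels.value_counts().min() < 2:
            raise DegenerateRunError("training risk classes are degenerate")
        sub = self.expr.subset_genes(kept)
        profile, model = loocv_select_threshold(
            sub,
            labels,
            grid_size=self.grid_size,
            m_rule=self.m_rule,
            uniform_priors=self.uniform_priors,
            classes=["high", "low"],
        )
        resub_pred, _ = predict_nsc(model, sub)
        resub_acc = float((resub_pred == labels).mean())
        loocv_acc = 1.0 - profile.errors.min() / profile.n_folds
        return PrognosticSignatureResults(
            model=self,
            prognostic_genes=kept,
            selection_table=cox_table,
            cv_profile=profile,
            classifier=model,
            training_labels=labels,
            resubstitution_accuracy=resub_acc,
            loocv_accuracy=float(loocv_acc),
        )


@dataclass
class PrognosticSignatureResults:
    """Fitted signature: surviving genes, CV profile, validation methods."""

    model: PrognosticSignatureModel
    prognostic_genes: List[str]
    selection_table: pd.DataFrame
    cv_profile: CVProfile
    classifier: ShrunkenCentroidModel
    training_labels: pd.Series
    resubstitution_accuracy: float
    loocv_accuracy: float

    @property
    def signature_genes(self) -> List[str]:
        return signature_genes(self.classifier)

    def align_to_training(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        """Gene-wise centre a cohort onto the classifier's frame.

        Each gene's cohort mean is translated to the training overall
        centroid, removing platform/batch location offsets (the same
        move cross-platform subtype classifiers make before prediction).
        Within-cohort contrasts are untouched; a cohort whose outcome mix
        is extremely skewed loses part of its class signal to the
        centring — the price of not knowing the batch offset.
        """
        genes = [g for g in self.classifier.genes if g in set(expr.gene_ids)]
        if not genes:
            raise KeyError("no overlap between classifier genes and expression matrix")
        sub = expr.subset_genes(genes)
        idx = [self.classifier.genes.index(g) for g in genes]
        target = self.classifier.overall_centroid[idx]
        shifted = sub.values.sub(sub.values.mean(axis=1), axis=0).add(target, axis=0)
        return ExpressionMatrix(shifted, sub.cohort)

    def predict(self, expr: ExpressionMatrix, align: bool = True) -> pd.Series:
        """Predicted risk group ('low'/'high') per sample.

        ``align=True`` (default) first centres the cohort's gene means
        onto the training frame; pass ``align=False`` when the cohort is
        already on the training scale.
        """
        if align:
            expr = self.align_to_training(expr)
        labels, _ = predict_nsc(self.classifier, expr)
        return labels

    def validate(
        self,
        expr: ExpressionMatrix,
        clinical: ClinicalTable,
        adjust: Sequence[str] = (),
        threshold_months: Optional[float] = None,
    ) -> Dict[str, object]:
        """Predict risk groups on a validation cohort and score them.

        Returns a dict with the predicted labels, log-rank (chi2, p),
        univariate (and optionally stage/grade-adjusted) Cox results for
        the high-vs-low comparison, Kaplan-Meier curves per group, and
        the threshold confusion summary.
        """
        threshold = (
            self.model.risk_threshold_months if threshold_months is None else threshold_months
        )
        clin = clinical.loc(list(expr.sample_ids))
        pred = self.predict(expr)
        out: Dict[str, object] = {"predicted": pred, "n": len(clin)}
        times = clin.time.to_numpy()
        events = clin.event.to_numpy()
        groups = pred.to_numpy()
        if len(set(groups)) < 2:
            out["degenerate"] = True
            return out
        out["degenerate"] = False
        chi2, p = logrank_test(times, events, groups)
        out["logrank_chi2"], out["logrank_p"] = chi2, p
        cox = cox_two_group(times, events, groups, name="risk_high")
        cox.p_logrank = p
        out["cox"] = cox
        out["km"] = {
            g: km_curve(times[groups == g], events[groups == g]) for g in ("low", "high")
        }
        out["confusion"] = confusion_accuracy(pred, clin, threshold=threshold)
        if adjust:
            t_adj, e_adj, design = risk_group_covariates(pred, clin, adjust=adjust)
            if design["risk_high"].nunique() > 1:
                out["cox_adjusted"] = cox_multivariate(t_adj, e_adj, design)
        return out

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        lines = [
            "Prognostic signature discovery".center(62),
            "=" * 62,
            f"Training samples:            {self.model.expr.n_samples}",
            f"Candidate genes:             {len(self.model.candidates)}",
            f"Prognostic genes (Wald P < {self.model.alpha:g}): {len(self.prognostic_genes)}",
            f"Signature size:              {len(self.signature_genes)}",
            f"Shrinkage threshold Delta*:  {self.classifier.delta:.4f}",
            f"LOOCV accuracy:              {self.loocv_accuracy:.3f}",
            f"Resubstitution accuracy:     {self.resubstitution_accuracy:.3f}",
            f"Risk classes:                time <= {self.model.risk_threshold_months:g} months = high",
            "-" * 62,
            "Top prognostic genes (by Wald P):",
        ]
        top = (
            self.selection_table.query("status == 'kept'")
            .sort_values("p_wald")
            .head(10)
        )
        lines.append(f"{'gene':<12}{'HR':>8}{'beta':>9}{'p_wald':>12}")
        for gene, row in top.iterrows():
            lines.append(
                f"{gene:<12}{row['hr']:>8.3f}{row['beta']:>9.3f}{row['p_wald']:>12.3g}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_km(self, validation: Dict[str, object], ax=None):
        """Kaplan-Meier curves of a ``validate()`` result's risk groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if validation.get("degenerate"):
            raise ValueError("validation run is degenerate (single predicted class)")
        for grp, curve in validation["km"].items():
            t = np.concatenate([[0.0], curve.times])
            s = np.concatenate([[1.0], curve.survival])
            ax.step(t, s, where="post", label=f"{grp} risk")
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
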