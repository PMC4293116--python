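"""Univariate prognostic screening by median dichotomisation.

Each candidate gene's expression is split at the cohort median into low
(<= median) and high (> median) groups, and a two-group Cox model is
fitted; genes whose Wald P falls below ``alpha`` survive. No multiplicity
correction is applied at this stage — the screen deliberately trades
specificity for recall, and the downstream shrunken-centroid fit prunes
the survivors.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .coxph import cox_two_group_batch

__all__ = ["median_dichotomize", "select_prognostic_genes"]

log = logging.getLogger(__name__)


def median_dichotomize(values, tie_side: str = "low") -> np.ndarray:
    """Split samples at the median; returns a boolean array (True = high).

    Samples exactly at the median go to the low group by default (``<=``
    rule); pass ``tie_side='high'`` for the ``>=`` convention. Raises on a
    constant vector, where one group would be empty.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    med = np.median(values)
    high = values > med if tie_side == "low" else values >= med
    if high.all() or not high.any():
        raise ValueError("degenerate dichotomisation: one group is empty")
    return high


def select_prognostic_genes(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    candidates: Sequence[str],
    alpha: float = 0.05,
    tie_side: str = "low",
) -> Tuple[List[str], pd.DataFrame]:
    """Keep candidate genes whose median-split Cox Wald P < ``alpha``.

    Returns the kept gene list (input order) and the per-gene Cox table
    (beta, hr, se, p_wald, kept/excluded status for every candidate).
    Genes with a degenerate median split or a separated likelihood are
    excluded and logged, never silently reported.
    """
    candidates = list(candidates)
    if not candidates:
        log.warning("empty candidate list passed to prognostic selection")
        return [], pd.DataFrame(
            columns=["beta", "hr", "se", "p_wald", "status"], index=pd.Index([], name="gene")
        )
    missing = [g for g in candidates if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"candidate genes not in expression matrix: {missing[:5]}")
    samples = list(expr.sample_ids)
    clin = clinical.loc(samples)
    times = clin.time.to_numpy()
    events = clin.event.to_numpy()

    X = expr.values.loc[candidates].to_numpy()
    med = np.median(X, axis=1, keepdims=True)
    groups = (X > med) if tie_side == "low" else (X >= med)
    degenerate = (~groups.any(axis=1)) | groups.all(axis=1)
    groups = groups.astype(float)

    res = cox_two_group_batch(times, events, groups)
    res.index = pd.Index(candidates, name="gene")
    res["degenerate"] = res["degenerate"] | degenerate
    status = np.where(
        res["degenerate"], "degenerate", np.where(res["separated"], "separated", "tested")
    )
    keep_mask = (status == "tested") & (res["p_wald"].to_numpy() < alpha)
    out = pd.DataFrame(
        {
            "beta": res["beta"],
            "hr": np.exp(res["beta"]),
            "se": res["se"],
            "p_wald": res["p_wald"],
            "status": status,
        },
        index=res.index,
    )
    out.loc[keep_mask, "status"] = "kept"
    n_bad = int((status != "tested").sum())
    if n_bad:
        log.info("excluded %d candidate(s) with degenerate split or separation", n_bad)
    kept = [g for g, k in zip(candidates, keep_mask) if k]
    return kept, out
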