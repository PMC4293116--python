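"""Random-signature permutation null for the discovery protocol.

Gene pools of a fixed size are drawn uniformly from a universe and each
is pushed through the full protocol (prognostic screening, LOOCV-tuned
shrunken-centroid fit, risk prediction on held-out cohorts). Each run is
scored per validation cohort by the log-rank chi-square (1 df) of its
predicted risk groups — the chi-square statistic the validation
machinery produces. Benjamini-Hochberg adjustment is applied per cohort
across runs; a run is "reproducible" when its adjusted p clears alpha in
every cohort, and genes are ranked by how often they appear in
reproducible pools (inclusion frequency).

Per-run seeds derive deterministically from (master seed, run index), so
a study can be sharded across workers and recomposed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable, ExpressionMatrix
from .diffexp import bh_adjust
from .signature import DegenerateRunError, PrognosticSignatureModel

__all__ = [
    "SignatureRun",
    "StudySummary",
    "sample_random_pool",
    "run_signature_protocol",
    "random_signature_study",
    "inclusion_frequency",
]


@dataclass
class SignatureRun:
    """One protocol execution on one gene pool."""

    pool: List[str]
    selected: List[str] = field(default_factory=list)
    signature: List[str] = field(default_factory=list)
    chi2: Dict[str, float] = field(default_factory=dict)  # per validation cohort
    p: Dict[str, float] = field(default_factory=dict)
    padj: Dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    reason: str = ""
    reproducible_in_all: bool = False

    def complete(self, cohorts: Sequence[str]) -> bool:
        """True when every cohort carries a finite statistic."""
        return (not self.degenerate) and all(
            np.isfinite(self.p.get(c, np.nan)) for c in cohorts
        )


def sample_random_pool(universe: Sequence[str], size: int, rng) -> List[str]:
    """Uniform sample of ``size`` genes without replacement."""
    universe = list(universe)
    if size > len(universe):
        raise ValueError(f"pool size {size} exceeds universe size {len(universe)}")
    idx = rng.choice(len(universe), size=size, replace=False)
    return [universe[i] for i in idx]


def run_signature_protocol(
    pool: Sequence[str],
    training: Tuple[ExpressionMatrix, ClinicalTable],
    validations: Sequence[Tuple[str, ExpressionMatrix, ClinicalTable]],
    alpha: float = 0.05,
    risk_threshold_months: float = 20.0,
    grid_size: int = 30,
) -> SignatureRun:
    """Run selection -> LOOCV NSC -> per-cohort log-rank on one pool.

    ``validations`` is a sequence of (name, expression, clinical). Runs
    where selection or training degenerates are returned flagged, with no
    statistics; a validation cohort where prediction collapses to one
    class gets a NaN statistic.
    """
    expr, clinical = training
    pool = list(pool)
    missing = [g for g in pool if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"pool genes not in training matrix: {missing[:5]}")
    for name, vexpr, vclin in validations:
        absent = [s for s in vexpr.sample_ids if s not in vclin.sample_ids]
        if absent:
            raise ValueError(f"cohort {name!r}: clinical lacks samples {absent[:5]}")

    run = SignatureRun(pool=pool)
    model = PrognosticSignatureModel(
        expr,
        clinical,
        candidates=pool,
        alpha=alpha,
        risk_threshold_months=risk_threshold_months,
        grid_size=grid_size,
    )
    try:
        results = model.fit()
    except DegenerateRunError as err:
        run.degenerate = True
        run.reason = str(err)
        return run
    run.selected = results.prognostic_genes
    run.signature = results.signature_genes
    if not run.signature:
        run.degenerate = True
        run.reason = "fully shrunk model (empty signature)"
        return run
    for name, vexpr, vclin in validations:
        rep = results.validate(vexpr, vclin)
        if rep.get("degenerate"):
            run.chi2[name] = np.nan
            run.p[name] = np.nan
        else:
            run.chi2[name] = float(rep["logrank_chi2"])
            run.p[name] = float(rep["logrank_p"])
    return run


@dataclass
class StudySummary:
    """Aggregate view of a random-signature study."""

    n_runs: int
    cohorts: List[str]
    n_degenerate: int
    n_complete: int
    raw_significant: Dict[str, int]
    raw_fraction: Dict[str, float]
    adj_significant: Dict[str, int]
    n_reproducible: int
    inclusion: Optional[pd.DataFrame]  # per-gene frequency + rank, or None
    outperform_fraction: Optional[float]
    chi2_quantiles: Dict[str, Dict[str, float]]
    runs: List[SignatureRun] = field(repr=False, default_factory=list)


def random_signature_study(
    universe: Sequence[str],
    training: Tuple[ExpressionMatrix, ClinicalTable],
    validations: Sequence[Tuple[str, ExpressionMatrix, ClinicalTable]],
    n_runs: int,
    pool_size: int = 225,
    alpha: float = 0.05,
    reference: Optional[SignatureRun] = None,
    seed: int = 0,
    risk_threshold_months: float = 20.0,
    grid_size: int = 30,
) -> StudySummary:
    """Sample ``n_runs`` random pools, run the protocol, and aggregate.

    BH adjustment is per cohort across runs with a defined statistic;
    degenerate runs never enter the BH denominator. The outperformance
    fraction counts runs whose chi2 strictly exceeds the reference's in
    every cohort.
    """
    cohort_names = [name for name, _, _ in validations]
    runs: List[SignatureRun] = []
    for i in range(n_runs):
        rng = np.random.default_rng([int(seed), i])
        pool = sample_random_pool(universe, pool_size, rng)
        runs.append(
            run_signature_protocol(
                pool,
                training,
                validations,
                alpha=alpha,
                risk_threshold_months=risk_threshold_months,
                grid_size=grid_size,
            )
        )
    return summarize_study(
        runs, cohort_names, universe, alpha=alpha, reference=reference, n_runs=n_runs
    )


def summarize_study(
    runs: List[SignatureRun],
    cohort_names: Sequence[str],
    universe: Sequence[str],
    alpha: float = 0.05,
    reference: Optional[SignatureRun] = None,
    n_runs: Optional[int] = None,
) -> StudySummary:
    """Aggregate a list of runs (separated out so shards can be merged)."""
    cohort_names = list(cohort_names)
    n_runs = len(runs) if n_runs is None else n_runs
    complete = [r for r in runs if r.complete(cohort_names)]
    raw_sig, raw_frac, adj_sig = {}, {}, {}
    chi2_q: Dict[str, Dict[str, float]] = {}
    for c in cohort_names:
        ps = np.array([r.p[c] for r in complete])
        raw_sig[c] = int((ps < alpha).sum()) if len(ps) else 0
        raw_frac[c] = float((ps < alpha).mean()) if len(ps) else np.nan
        if len(ps):
            padj = bh_adjust(ps)
            for r, a in zip(complete, padj):
                r.padj[c] = float(a)
            adj_sig[c] = int((padj < alpha).sum())
            chi2 = np.array([r.chi2[c] for r in complete])
            chi2_q[c] = {
                f"q{int(q * 100):02d}": float(np.quantile(chi2, q))
                for q in (0.05, 0.25, 0.5, 0.75, 0.95)
            }
        else:
            adj_sig[c] = 0
            chi2_q[c] = {}
    for r in runs:
        r.reproducible_in_all = r.complete(cohort_names) and all(
            r.padj.get(c, np.inf) < alpha for c in cohort_names
        )
    reproducible = [r for r in runs if r.reproducible_in_all]

    inclusion = None
    if reproducible:
        mask = [r.reproducible_in_all for r in runs]
        inclusion = inclusion_frequency(runs, mask, universe=universe)

    outperform = None
    if reference is not None and reference.complete(cohort_names):
        wins = [
            all(r.chi2[c] > reference.chi2[c] for c in cohort_names) for r in complete
        ]
        outperform = float(np.mean(wins)) if wins else np.nan

    return StudySummary(
        n_runs=n_runs,
        cohorts=cohort_names,
        n_degenerate=sum(r.degenerate for r in runs),
        n_complete=len(complete),
        raw_significant=raw_sig,
        raw_fraction=raw_frac,
        adj_significant=adj_sig,
        n_reproducible=len(reproducible),
        inclusion=inclusion,
        outperform_fraction=outperform,
        chi2_quantiles=chi2_q,
        runs=runs,
    )


def inclusion_frequency(
    runs: Sequence[SignatureRun],
    significant_mask: Sequence[bool],
    universe: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene pool-membership frequency among the masked runs.

    Returns a DataFrame indexed by gene with columns ``frequency`` and
    ``rank`` (dense, 1 = most frequently included, ties share a rank).
    """
    if len(significant_mask) != len(runs):
        raise ValueError("mask length must equal the number of runs")
    chosen = [r for r, m in zip(runs, significant_mask) if m]
    if not chosen:
        raise ValueError("mask selects zero runs")
    if universe is None:
        universe = sorted({g for r in chosen for g in r.pool})
    universe = list(universe)
    counts = pd.Series(0, index=universe, dtype=float)
    for r in chosen:
        in_pool = [g for g in r.pool if g in counts.index]
        counts[in_pool] += 1
    freq = counts / len(chosen)
    rank = pd.Series(
        stats.rankdata(-freq.to_numpy(), method="dense"), index=freq.index, dtype=int
    )
    return pd.DataFrame({"frequency": freq, "rank": rank})
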