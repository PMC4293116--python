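"""In-memory containers shared by every pipeline stage.

An :class:`ExpressionMatrix` is a genes x samples table of log2 mRNA
abundance with a per-sample cohort label; a :class:`ClinicalTable` carries
right-censored survival outcomes (months) plus optional TNM stage and
histological grade; a :class:`PairedDesign` records matched tumour/normal
sample pairs for the differential-expression stage.

All containers validate their invariants on construction and raise
``ValueError`` naming the offending field, so downstream code can assume
clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGE_LEVELS = ("IA", "IB", "IIA", "IIB", "III", "IV")
#: stages compared as early (0) vs late (1): IA/IB/IIA vs IIB/III/IV
STAGE_HIGH = frozenset({"IIB", "III", "IV"})
GRADE_LEVELS = (1, 2, 3, 4)
GRADE_HIGH = frozenset({3, 4})


class ExpressionMatrix:
    """Log2 expression values, genes as rows and samples as columns.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes x samples, float; index = HGNC gene symbols, columns = sample
        IDs. Both must be unique and every value finite.
    cohort : pandas.Series or str, optional
        Per-sample cohort label (indexed by sample ID) or a single label
        applied to all samples.
    """

    def __init__(self, values: pd.DataFrame, cohort=None):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        values = values.astype(float, copy=False)
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
            )
        self.values = values
        if cohort is None:
            cohort = pd.Series("cohort0", index=values.columns, dtype=object)
        elif isinstance(cohort, str):
            cohort = pd.Series(cohort, index=values.columns, dtype=object)
        else:
            cohort = pd.Series(cohort).reindex(values.columns)
            if cohort.isna().any():
                missing = cohort.index[cohort.isna()].tolist()
                raise ValueError(f"cohort label missing for samples: {missing[:5]}")
        self.cohort = cohort.astype(object)

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.cohort)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[list(samples)], self.cohort.loc[list(samples)]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ncoh = self.cohort.nunique()
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} "
            f"samples, {ncoh} cohort(s)>"
        )


class ClinicalTable:
    """Per-sample survival outcome with optional stage/grade covariates.

    Stored as a DataFrame indexed by sample ID with columns
    ``time_months`` (float > 0), ``event`` (1 = death, 0 = censored),
    ``stage`` (one of IA, IB, IIA, IIB, III, IV or missing), ``grade``
    (1-4 or missing) and ``cohort``.
    """

    COLUMNS = ("time_months", "event", "stage", "grade", "cohort")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.duplicated().any():
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        for col in ("stage", "grade", "cohort"):
            if col not in table.columns:
                table[col] = np.nan
        times = pd.to_numeric(table["time_months"], errors="raise").astype(float)
        if not np.isfinite(times).all() or (times <= 0).any():
            bad = table.index[~np.isfinite(times) | (times <= 0)].tolist()
            raise ValueError(f"time_months must be finite and > 0; bad samples: {bad[:5]}")
        events = pd.to_numeric(table["event"], errors="raise").astype(int)
        if not events.isin([0, 1]).all():
            bad = table.index[~events.isin([0, 1])].tolist()
            raise ValueError(f"event must be 0 or 1; bad samples: {bad[:5]}")
        stage = table["stage"]
        known = stage.dropna()
        if len(known) and not known.astype(str).isin(STAGE_LEVELS).all():
            bad = known[~known.astype(str).isin(STAGE_LEVELS)].unique().tolist()
            raise ValueError(f"unknown stage values: {bad[:5]}")
        grade = pd.to_numeric(table["grade"], errors="coerce")
        known = grade.dropna()
        if len(known) and not known.isin(GRADE_LEVELS).all():
            bad = known[~known.isin(GRADE_LEVELS)].unique().tolist()
            raise ValueError(f"unknown grade values: {bad[:5]}")
        out = pd.DataFrame(index=table.index)
        out["time_months"] = times
        out["event"] = events
        out["stage"] = stage
        out["grade"] = grade
        out["cohort"] = table["cohort"]
        self.table = out

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def time(self) -> pd.Series:
        return self.table["time_months"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]

    def loc(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise KeyError(f"samples not in clinical table: {missing[:5]}")
        return ClinicalTable(self.table.loc[list(samples)])

    def stage_binary(self) -> pd.Series:
        """Early (0: IA/IB/IIA) vs late (1: IIB/III/IV); NaN where missing."""
        s = self.table["stage"]
        out = pd.Series(np.nan, index=s.index)
        out[s.notna()] = s.dropna().astype(str).isin(STAGE_HIGH).astype(float)
        return out

    def grade_binary(self) -> pd.Series:
        """Low (0: grade 1/2) vs high (1: grade 3/4); NaN where missing."""
        g = self.table["grade"]
        out = pd.Series(np.nan, index=g.index)
        out[g.notna()] = g.dropna().isin(GRADE_HIGH).astype(float)
        return out

    def concat(self, other: "ClinicalTable") -> "ClinicalTable":
        return ClinicalTable(pd.concat([self.table, other.table]))

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ClinicalTable {len(self.table)} samples, "
            f"{int(self.table['event'].sum())} events>"
        )


@dataclass(frozen=True)
class PairedDesign:
    """Matched tumour/normal sample pairs for paired differential expression."""

    pairs: tuple  # of (tumour_id, normal_id)

    def __init__(self, pairs: Iterable[tuple]):
        pairs = tuple((str(t), str(n)) for t, n in pairs)
        seen: set = set()
        for t, n in pairs:
            for s in (t, n):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears twice in the design")
                seen.add(s)
        object.__setattr__(self, "pairs", pairs)

    @property
    def tumours(self) -> list:
        return [t for t, _ in self.pairs]

    @property
    def normals(self) -> list:
        return [n for _, n in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        for t, n in self.pairs:
            for s in (t, n):
                if s not in expr.sample_ids:
                    raise ValueError(f"design sample {s!r} not in expression matrix")
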