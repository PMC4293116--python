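"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as gene x sample TSV (first column ``gene``,
header row of sample IDs); the GCT v1.2 dialect is accepted on read.
Clinical tables are TSV with columns ``sample_id  time_months  event
stage  grade  cohort``. Gene sets use the standard GMT layout. Readers
reject malformed input with precise coordinates rather than coercing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "collapse_probesets",
]


def _parse_matrix_block(lines: List[str], path, gene_col: int, skip_cols: int):
    """Parse tab-separated numeric rows; first line is the header."""
    header = lines[0].rstrip("\n").split("\t")
    samples = header[skip_cols + 1 :]
    genes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        gene = parts[gene_col]
        cells = parts[skip_cols + 1 :]
        if len(cells) != len(samples):
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} values, expected {len(samples)}"
            )
        row = np.empty(len(cells))
        for j, cell in enumerate(cells):
            try:
                row[j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {lineno}, "
                    f"column {samples[j]!r}"
                ) from None
        genes.append(gene)
        rows.append(row)
    df = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated gene symbol(s): {dup[:5]}")
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: missing values are not supported")
    return df


def read_expression(path, cohort=None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT v1.2.

    GCT is recognised by its ``#1.2`` version line; its ``Name`` column is
    used as the gene symbol and ``Description`` is dropped.
    """
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    if not lines:
        raise ValueError(f"{path}: empty file")
    if lines[0].startswith("#1.2"):
        # GCT: version line, dims line, then header with Name/Description
        if len(lines) < 3:
            raise ValueError(f"{path}: truncated GCT file")
        df = _parse_matrix_block(lines[2:], path, gene_col=0, skip_cols=1)
    else:
        df = _parse_matrix_block(lines, path, gene_col=0, skip_cols=0)
    return ExpressionMatrix(df, cohort=cohort)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a gene x sample TSV, floats at 6 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        vals = matrix.values.to_numpy()
        for gene, row in zip(matrix.gene_ids, vals):
            fh.write(str(gene) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"stage": "string"})
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicated sample_id(s): {dups[:5]}")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    out = clinical.table.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path) -> Dict[str, List[str]]:
    """Read named gene sets; order preserved, within-set duplicates removed."""
    sets: Dict[str, List[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        name = parts[0]
        genes = list(dict.fromkeys(g for g in parts[2:] if g))
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def collapse_probesets(
    probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe x sample matrix to one row per gene symbol.

    For each gene mapped by more than one probe set, the probe row with the
    largest sample variance (n-1 denominator) is kept; ties are broken
    toward the lexicographically smallest probe ID. Probes absent from the
    mapping are dropped.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    if probe_values.shape[1] < 1:
        raise ValueError("probe matrix has no samples")
    mapped = [p for p in probe_values.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the mapping")
    sub = probe_values.loc[mapped]
    variances = sub.var(axis=1, ddof=1).fillna(0.0)
    best: Dict[str, str] = {}
    for probe in sorted(mapped, key=str):  # lexicographic order fixes ties
        gene = probe_to_gene[probe]
        if gene not in best or variances[probe] > variances[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    collapsed = sub.loc[[best[g] for g in genes]]
    collapsed.index = genes
    return ExpressionMatrix(collapsed)


def write_ground_truth(truth, path) -> None:
    """Serialise a simulation GroundTruth to JSON."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))
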