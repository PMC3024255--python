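"""TSV readers and writers for expression matrices, adjacencies, labels and
results.

Expression TSV: header row of node ids, first column sample ids.
Adjacency TSV: square, node ids as both header and first column; symmetry is
validated to 1e-8 and the matrix then symmetrized by averaging.
Label TSV: two columns (node, module); '0' and 'grey' both mean unassigned,
'gold' is reserved.  Undefined values serialize as 'NA'.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .netcore import AdjacencyMatrix, ExpressionMatrix, ModuleAssignment

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"
SYMMETRY_TOL = 1e-8


def _read_numeric_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        for col in bad:
            rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                            & df[col].notna()]
            raise ValueError(
                f"non-numeric cell(s) in column {col!r}, row(s) {list(rows)[:5]}")
    return df


def read_expression(path) -> ExpressionMatrix:
    df = _read_numeric_tsv(path)
    return ExpressionMatrix(df.to_numpy(float),
                            sample_ids=[str(i) for i in df.index],
                            node_ids=[str(c) for c in df.columns])


def write_expression(X: ExpressionMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA",
                        index_label="sample")


def read_adjacency(path) -> AdjacencyMatrix:
    df = _read_numeric_tsv(path)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("adjacency TSV must have identical row and column ids")
    A = df.to_numpy(float)
    asym = np.nanmax(np.abs(A - A.T)) if A.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(f"adjacency not symmetric (max deviation {asym:.3g})")
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(A, node_ids=[str(c) for c in df.columns])


def write_adjacency(A: AdjacencyMatrix, path) -> None:
    pd.DataFrame(A.values, index=A.node_ids, columns=A.node_ids).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def read_labels(path, node_universe=None) -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label TSV needs node and module columns")
    nodes = df.iloc[:, 0].tolist()
    labels = df.iloc[:, 1].fillna("grey").tolist()
    assignment = ModuleAssignment(nodes, labels)
    if node_universe is not None:
        unknown = sorted(set(nodes) - set(node_universe))
        if unknown:
            raise ValueError(f"labels reference unknown node id(s): {unknown[:5]}")
        assignment = assignment.reorder(list(node_universe))
    return assignment


def write_labels(labels: ModuleAssignment, path) -> None:
    pd.DataFrame({"node": labels.node_ids, "module": labels.labels}).to_csv(
        path, sep="\t", index=False)


def write_results(result, out_prefix) -> list[Path]:
    """Write long-format statistics, composite summary and run metadata."""
    import json

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    p = prefix.with_name(prefix.name + "_statistics.tsv")
    result.results.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT,
                          na_rep="NA")
    paths.append(p)
    p = prefix.with_name(prefix.name + "_composites.tsv")
    result.composites.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT,
                             na_rep="NA")
    paths.append(p)
    p = prefix.with_name(prefix.name + "_run.json")
    with open(p, "w") as fh:
        json.dump(result.metadata, fh, indent=2, default=str)
    paths.append(p)
    return paths
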