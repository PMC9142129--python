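"""File formats: expression matrices, DREAM-style gold standards, networks.

Expression files are delimited text with genes in rows: first column the
gene identifier, remaining columns numeric samples.  Gold standards use the
DREAM three-column convention ``gene1 <tab> gene2 <tab> {0,1}``; absent
pairs count as 0 and the edge set is symmetrized (the inference output is
an undirected skeleton).  Missing expression values are a hard error — this
package expects a complete matrix, with imputation delegated to external
tooling (e.g., regularized iterative PCA) beforehand.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .information import DataMatrix
from .netgen import GoldStandard

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_gold",
    "write_gold",
    "write_network",
]


class FormatError(ValueError):
    """A malformed input file, reported with the offending line."""


_MISSING_TOKENS = {"", "na", "nan", "null", "none", "missing"}


def _detect_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_expression(path: str | Path, *, transpose: bool = False) -> DataMatrix:
    """Read a genes x samples activity matrix from TSV/CSV.

    ``transpose=True`` accepts samples-in-rows input (header row of gene
    names, first column a sample id).
    """
    path = Path(path)
    text = path.read_text().splitlines()
    lines = [(no, ln) for no, ln in enumerate(text, 1) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: file is empty")
    delim = _detect_delimiter(lines[0][1])
    rows: list[tuple[str, list[float]]] = []
    header_skipped = False
    width: int | None = None
    for no, ln in lines:
        cells = ln.split(delim)
        if len(cells) < 2:
            raise FormatError(f"{path}:{no}: expected id + samples, got {ln!r}")
        ident, values = cells[0].strip(), cells[1:]
        if not rows and not header_skipped:
            # a header row has non-numeric sample cells
            if any(not _is_number(v) for v in values):
                header_skipped = True
                continue
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise FormatError(
                f"{path}:{no}: ragged row ({len(values)} values, expected {width})"
            )
        parsed = []
        for col, v in enumerate(values, 2):
            v = v.strip()
            if v.lower() in _MISSING_TOKENS:
                raise FormatError(
                    f"{path}:{no}: missing value in column {col}; this tool "
                    "requires a complete matrix — impute missing entries "
                    "externally (e.g., regularized iterative PCA) first"
                )
            if not _is_number(v):
                raise FormatError(f"{path}:{no}: non-numeric value {v!r}")
            parsed.append(float(v))
        rows.append((ident, parsed))
    ids = [r[0] for r in rows]
    dupes = sorted({g for g in ids if ids.count(g) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate gene id(s): {dupes}")
    mat = np.array([r[1] for r in rows])
    if transpose:
        mat = mat.T
        ids = [f"G{i + 1}" for i in range(mat.shape[0])]
    if mat.shape[1] < 3:
        raise FormatError(f"{path}: need at least 3 samples, found {mat.shape[1]}")
    return DataMatrix(mat, tuple(ids))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_expression(D: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for ident, row in zip(D.variable_ids, D.values):
            w.writerow([ident, *(repr(float(v)) for v in row)])


def read_gold(path: str | Path, ids: Sequence[str]) -> GoldStandard:
    """Read a DREAM three-column gold standard aligned to ``ids``.

    Lines are ``gene1 gene2 label``; label 1 marks an edge, 0 a non-edge;
    unlisted pairs are non-edges.  Contradictory duplicate lines and gene
    ids not present in ``ids`` are errors.
    """
    path = Path(path)
    index = {g: k for k, g in enumerate(ids)}
    seen: dict[tuple[int, int], int] = {}
    with path.open() as fh:
        for no, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith("#"):
                continue
            cells = ln.split()
            if len(cells) != 3:
                raise FormatError(f"{path}:{no}: expected 'gene1 gene2 label'")
            g1, g2, lab = cells
            for g in (g1, g2):
                if g not in index:
                    raise FormatError(
                        f"{path}:{no}: gene id {g!r} not in the expression matrix"
                    )
            if lab not in ("0", "1"):
                raise FormatError(f"{path}:{no}: label must be 0 or 1, got {lab!r}")
            i, j = index[g1], index[g2]
            if i == j:
                raise FormatError(f"{path}:{no}: self-pair {g1!r}")
            key = (min(i, j), max(i, j))
            val = int(lab)
            if key in seen and seen[key] != val:
                raise FormatError(
                    f"{path}:{no}: contradictory labels for pair {g1!r}-{g2!r}"
                )
            seen[key] = val
    edges = frozenset(k for k, v in seen.items() if v == 1)
    return GoldStandard(len(ids), edges, tuple(ids))


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for i, j in sorted(gold.edges):
            w.writerow([gold.ids[i], gold.ids[j], 1])


def write_network(
    edges: Iterable[tuple[int, int, float]],
    ids: Sequence[str],
    path: str | Path,
    *,
    fmt: str = "tsv",
    criterion: str = "MPMI",
    case_labels: np.ndarray | None = None,
    header_meta: dict | None = None,
) -> None:
    """Write a ranked edge list as TSV, SIF or GraphML.

    The TSV carries a comment header recording the run configuration and
    seed so every output file is self-describing.
    """
    path = Path(path)
    edges = list(edges)
    if fmt == "tsv":
        with path.open("w", newline="") as fh:
            for key, val in (header_meta or {}).items():
                fh.write(f"# {key}: {val}\n")
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["gene1", "gene2", "criterion", "score", "case"])
            for i, j, s in edges:
                case = (
                    int(case_labels[i, j]) if case_labels is not None else ""
                )
                w.writerow([ids[i], ids[j], criterion, repr(float(s)), case])
    elif fmt == "sif":
        with path.open("w") as fh:
            for i, j, _ in edges:
                fh.write(f"{ids[i]}\tpmi\t{ids[j]}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for key, val in (header_meta or {}).items():
            g.graph[key] = str(val)
        g.add_nodes_from(ids)
        for i, j, s in edges:
            g.add_edge(ids[i], ids[j], score=float(s), criterion=criterion)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
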