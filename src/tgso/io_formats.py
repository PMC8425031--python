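"""Readers and writers for the five input tables and the ranking output.

All tables are plain delimited text (tab or comma, auto-detected per file,
overridable).  Protein identifiers are matched by exact string equality after
whitespace trimming; no alias resolution is attempted -- reconciling IDs
across source databases is a data-preparation step, not part of the method.

Internal node order is first appearance in the PPI edge list; every matrix
and vector downstream uses this order, which makes runs exactly replayable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "ExpressionTable",
    "LocalizationTable",
    "OrthologyTable",
    "read_ppi_edgelist",
    "read_expression_table",
    "read_localization_table",
    "read_orthology_table",
    "read_essential_list",
    "write_ranking",
    "read_ranking",
]


def _split_line(line: str, sep: str | None) -> list[str]:
    if sep is not None:
        return [f.strip() for f in line.split(sep)]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


@dataclass
class PPINetwork:
    """Undirected, unweighted PPI graph over a fixed node order.

    ``adjacency`` is a symmetric CSR matrix of 0/1 entries with an empty
    diagonal; ``node_ids[i]`` names internal index ``i``.
    """

    node_ids: list[str]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {pid: i for i, pid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate protein IDs in node list")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def index_of(self, protein_id: str) -> int:
        return self._index[protein_id]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the neighbours NG(i), in ascending index order."""
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    def degree(self, i: int) -> int:
        return int(self.adjacency.indptr[i + 1] - self.adjacency.indptr[i])

    def degrees(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i, j])

    def edges(self) -> Iterator[tuple[int, int]]:
        """Each undirected edge once, as (i, j) with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return zip(coo.row.tolist(), coo.col.tolist())

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return coo.row, coo.col

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "PPINetwork":
        """Build a network from ID pairs: self-pairs dropped, duplicate edges
        (either orientation) collapsed, node order = first appearance."""
        node_ids: list[str] = []
        index: dict[str, int] = {}
        seen: set[tuple[int, int]] = set()
        rows: list[int] = []
        cols: list[int] = []
        for a, b in pairs:
            if a == b:
                continue
            for pid in (a, b):
                if pid not in index:
                    index[pid] = len(node_ids)
                    node_ids.append(pid)
            i, j = index[a], index[b]
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            rows += [key[0], key[1]]
            cols += [key[1], key[0]]
        n = len(node_ids)
        adjacency = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
        )
        return cls(node_ids=node_ids, adjacency=adjacency)


def read_ppi_edgelist(path: str | Path, sep: str | None = None) -> PPINetwork:
    """Read a two-column edge list into a :class:`PPINetwork`.

    Repeated interactions and self-interactions are filtered out.  Raises
    ``ValueError`` naming the offending line for malformed rows and for an
    empty file.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = _split_line(line, sep)
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: empty edge list")
    net = PPINetwork.from_edges(pairs)
    logger.info("read PPI %s: N=%d, |E|=%d", path, net.n_nodes, net.n_edges)
    return net


@dataclass
class ExpressionTable:
    """Per-protein expression profiles over T time points.

    ``data`` is indexed by protein ID with T numeric columns.  Proteins
    absent from the table are simply uncovered; downstream correlation
    treats them as contributing zero.
    """

    data: pd.DataFrame

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def has(self, protein_id: str) -> bool:
        return protein_id in self.data.index

    def vector(self, protein_id: str) -> np.ndarray:
        return self.data.loc[protein_id].to_numpy(dtype=float)

    def coverage(self, node_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask, aligned with ``node_ids``: True where covered."""
        return np.fromiter(
            (pid in self.data.index for pid in node_ids), dtype=bool, count=len(node_ids)
        )


def read_expression_table(
    path: str | Path,
    network: PPINetwork | None = None,
    sep: str | None = None,
) -> ExpressionTable:
    """Read an (ID, value_1 .. value_T) table.

    A first line whose numeric columns do not parse as floats is treated as a
    header and skipped.  Requires T >= 2 and a consistent column count; a
    non-numeric data cell is a ``ValueError`` naming line and column.
    """
    ids: list[str] = []
    seen_ids: set[str] = set()
    rows: list[list[float]] = []
    width: int | None = None
    first_data_line = True
    for lineno, line in _data_lines(path):
        fields = _split_line(line, sep)
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: need an ID plus at least 2 numeric columns"
            )
        values: list[float] = []
        bad_col = None
        for col, cell in enumerate(fields[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                bad_col = col
                break
            if not math.isfinite(v):
                bad_col = col
                break
            values.append(v)
        if bad_col is not None:
            if first_data_line:
                first_data_line = False
                continue  # header line
            raise ValueError(
                f"{path}: line {lineno}, column {bad_col}: non-numeric cell"
            )
        first_data_line = False
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise ValueError(
                f"{path}: line {lineno}: {len(values)} value columns, expected {width}"
            )
        if fields[0] in seen_ids:
            logger.warning("%s: line %d: duplicate row for %s kept first", path, lineno, fields[0])
            continue
        seen_ids.add(fields[0])
        ids.append(fields[0])
        rows.append(values)
    if width is None:
        raise ValueError(f"{path}: empty expression table")
    data = pd.DataFrame(rows, index=ids)
    table = ExpressionTable(data=data)
    if network is not None:
        covered = int(table.coverage(network.node_ids).sum())
        extra = len(ids) - len(set(ids) & set(network.node_ids))
        logger.info(
            "expression %s: T=%d, covers %d/%d network proteins (%d extra rows ignored downstream)",
            path, width, covered, network.n_nodes, extra,
        )
    return table


@dataclass
class LocalizationTable:
    """Per-protein subcellular compartment sets L(u) over a finite vocabulary."""

    sets: dict[str, frozenset[str]]
    vocabulary: list[str]

    def compartments(self, protein_id: str) -> frozenset[str]:
        return self.sets.get(protein_id, frozenset())

    @property
    def n_annotated(self) -> int:
        return sum(1 for s in self.sets.values() if s)


def read_localization_table(
    path: str | Path,
    vocabulary: Sequence[str] | None = None,
    sep: str | None = None,
) -> LocalizationTable:
    """Read (protein, compartment) pairs, one per line, into per-protein sets.

    The vocabulary defaults to the sorted set of observed compartments; an
    explicit vocabulary rejects annotations outside it.
    """
    sets: dict[str, set[str]] = {}
    observed: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = _split_line(line, sep)
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ValueError(
                f"{path}: line {lineno}: expected (protein, compartment)"
            )
        pid, comp = fields
        if vocabulary is not None and comp not in vocabulary:
            raise ValueError(
                f"{path}: line {lineno}: compartment {comp!r} not in vocabulary"
            )
        sets.setdefault(pid, set()).add(comp)
        observed.add(comp)
    vocab = list(vocabulary) if vocabulary is not None else sorted(observed)
    return LocalizationTable(
        sets={pid: frozenset(s) for pid, s in sets.items()}, vocabulary=vocab
    )


@dataclass
class OrthologyTable:
    """Per-protein ortholog counts I(i) against |S| reference organisms."""

    counts: dict[str, int]
    n_organisms: int

    def count(self, protein_id: str) -> int:
        """I(i); proteins without a row default to 0."""
        return self.counts.get(protein_id, 0)


def read_orthology_table(
    path: str | Path, n_organisms: int, sep: str | None = None
) -> OrthologyTable:
    """Read ortholog information in either of two dialects.

    Two columns: (protein, count).  1 + ``n_organisms`` columns: per-organism
    0/1 presence flags, summed to the count.  Counts outside [0, |S|] are
    validation errors.
    """
    if n_organisms < 1:
        raise ValueError("n_organisms must be >= 1")
    counts: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = _split_line(line, sep)
        if len(fields) == 2:
            try:
                c = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer count {fields[1]!r}"
                ) from exc
        elif len(fields) == 1 + n_organisms:
            flags = fields[1:]
            if any(f not in ("0", "1") for f in flags):
                raise ValueError(
                    f"{path}: line {lineno}: presence flags must be 0 or 1"
                )
            c = sum(int(f) for f in flags)
        else:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 or {1 + n_organisms} columns, "
                f"got {len(fields)}"
            )
        if c < 0:
            raise ValueError(f"{path}: line {lineno}: negative ortholog count")
        if c > n_organisms:
            raise ValueError(
                f"{path}: line {lineno}: count {c} exceeds |S|={n_organisms}"
            )
        counts[fields[0]] = c
    return OrthologyTable(counts=counts, n_organisms=n_organisms)


def read_essential_list(path: str | Path) -> set[str]:
    """Read the known-essential protein list: one ID per line."""
    return {line for _, line in _data_lines(path)}


def write_ranking(
    ranked: Sequence[tuple[str, float, int]], path: str | Path
) -> None:
    """Write a ranked list as TSV: rank, protein, score (full precision)."""
    if not ranked:
        raise ValueError("refusing to write an empty ranking")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("rank\tprotein\tscore\n")
        for pid, score, rank in ranked:
            fh.write(f"{rank}\t{pid}\t{score:.17g}\n")


def read_ranking(path: str | Path) -> list[tuple[str, float, int]]:
    """Read back a ranking written by :func:`write_ranking`."""
    out: list[tuple[str, float, int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rank"):
            raise ValueError(f"{path}: missing ranking header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            out.append((fields[1], float(fields[2]), int(fields[0])))
    return out
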