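"""The three weighted layers built on the PPI edge set.

ADN (Aggregation-Degree Network) re-weights each edge by a neighbourhood
density measure

    DBN(u, v) = (|NG(u) ∩ NG(v)| + 1) / min(|NG(u)|, |NG(v)|),

CEN (Co-Expression Network) by Pearson correlation of expression profiles
propagated through shared neighbours,

    Connection(u, v) = PCC(u, v) + Σ_{ε ∈ NG(u)∩NG(v)} PCC(u, ε)·PCC(v, ε),

and CLN (Co-Localization Network) by the Jaccard similarity of subcellular
compartment sets scaled by the mean compartment-frequency score of the pair,

    colo_sub(u, v) = |L(u)∩L(v)| / |L(u)∪L(v)| · (S_score(u) + S_score(v)) / 2.

All three layers are symmetric, nonnegative, and supported only on edges of
the original graph.  Conventions for missing data: a protein without an
expression profile (or with a constant profile) contributes PCC = 0; a pair
with no compartment annotation on either side scores 0.  Connection values
are floored at 0 so that downstream fusion and the damped iteration operate
on nonnegative weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import ExpressionTable, LocalizationTable, PPINetwork

__all__ = [
    "WeightedLayer",
    "LocationFrequency",
    "dbn_weight",
    "build_adn",
    "pearson_cc",
    "connection_weight",
    "build_cen",
    "location_frequency",
    "self_localization_score",
    "colocalization_weight",
    "build_cln",
]


@dataclass
class WeightedLayer:
    """Symmetric nonnegative edge weights sharing a network's node order."""

    node_ids: list[str]
    matrix: sp.csr_matrix
    tag: str

    def weight(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])


def _require_edge(network: PPINetwork, u: int, v: int) -> None:
    if u == v or not network.has_edge(u, v):
        raise ValueError(f"({u}, {v}) is not an edge of the network")


def _common_neighbors(network: PPINetwork, u: int, v: int) -> np.ndarray:
    return np.intersect1d(network.neighbors(u), network.neighbors(v), assume_unique=True)


def dbn_weight(network: PPINetwork, u: int, v: int) -> float:
    """Density between nodes for an existing edge (u, v).

    Both endpoint degrees are >= 1 because the edge exists, so the
    denominator is never zero.
    """
    _require_edge(network, u, v)
    shared = len(_common_neighbors(network, u, v))
    return (shared + 1) / min(network.degree(u), network.degree(v))


def _edge_layer(network: PPINetwork, values: np.ndarray, tag: str) -> WeightedLayer:
    rows, cols = network.edge_arrays()
    n = network.n_nodes
    matrix = sp.csr_matrix(
        (
            np.concatenate([values, values]),
            (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
        ),
        shape=(n, n),
    )
    matrix.eliminate_zeros()
    return WeightedLayer(node_ids=network.node_ids, matrix=matrix, tag=tag)


def build_adn(network: PPINetwork) -> WeightedLayer:
    """Aggregation-degree layer: DBN on every edge, zero elsewhere."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    rows, cols = network.edge_arrays()
    degrees = network.degrees()
    # shared-neighbour counts for all edges at once: (A @ A)[i, j] counts
    # walks of length 2, i.e. |NG(i) ∩ NG(j)|
    a = network.adjacency.astype(np.float64)
    common = np.asarray((a @ a)[rows, cols]).ravel()
    values = (common + 1.0) / np.minimum(degrees[rows], degrees[cols])
    return _edge_layer(network, values, "ADN")


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation (n−1 denominator); 0 for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 time points")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    return float(zx @ zy / (n - 1))


def _zscore_matrix(network: PPINetwork, expr: ExpressionTable) -> np.ndarray:
    """N×T matrix of standardized profiles; all-zero rows for uncovered or
    constant profiles, so PCC(i, j) = Z[i] @ Z[j] / (T−1) with the missing-data
    convention built in."""
    n = network.n_nodes
    t = expr.n_timepoints
    if t < 2:
        raise ValueError("expression table must have at least 2 time points")
    z = np.zeros((n, t))
    for i, pid in enumerate(network.node_ids):
        if not expr.has(pid):
            continue
        x = expr.vector(pid)
        s = x.std(ddof=1)
        if s == 0.0:
            continue
        z[i] = (x - x.mean()) / s
    return z


def connection_weight(
    network: PPINetwork, expr: ExpressionTable, u: int, v: int
) -> float:
    """Co-expression weight of an existing edge, floored at 0."""
    _require_edge(network, u, v)
    z = _zscore_matrix(network, expr)
    return _connection_from_z(network, z, u, v)


def _connection_from_z(
    network: PPINetwork, z: np.ndarray, u: int, v: int
) -> float:
    t = z.shape[1]
    pcc = lambda a, b: float(z[a] @ z[b] / (t - 1))
    value = pcc(u, v)
    for eps in _common_neighbors(network, u, v):
        value += pcc(u, int(eps)) * pcc(v, int(eps))
    return max(value, 0.0)


def build_cen(network: PPINetwork, expr: ExpressionTable) -> WeightedLayer:
    """Co-expression layer: Connection weight on every edge."""
    z = _zscore_matrix(network, expr)
    rows, cols = network.edge_arrays()
    values = np.array(
        [_connection_from_z(network, z, int(i), int(j)) for i, j in zip(rows, cols)]
    )
    if values.size == 0:
        values = np.zeros(0)
    return _edge_layer(network, values, "CEN")


@dataclass
class LocationFrequency:
    """Relative frequency of each compartment across annotated proteins.

    ``score[c]`` = sub(c) / Σ_k sub(k), summing to 1 over the vocabulary.
    """

    counts: dict[str, int]
    scores: dict[str, float]


def location_frequency(loc: LocalizationTable) -> LocationFrequency:
    """Compartment frequencies sub(i) and normalized sub_score(i).

    The normalizing sum runs over compartments, making sub_score a
    distribution over the location vocabulary.
    """
    counts = {c: 0 for c in loc.vocabulary}
    for compartments in loc.sets.values():
        for c in compartments:
            counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            "no subcellular annotations: the co-localization layer needs "
            "localization data (or disable the CLN layer)"
        )
    scores = {c: counts[c] / total for c in counts}
    return LocationFrequency(counts=counts, scores=scores)


def self_localization_score(
    freq: LocationFrequency, loc: LocalizationTable, protein_id: str
) -> float:
    """S_score(u) = Σ_{i ∈ L(u)} sub_score(i); 0 for unannotated proteins."""
    return sum(freq.scores.get(c, 0.0) for c in loc.compartments(protein_id))


def colocalization_weight(
    freq: LocationFrequency, loc: LocalizationTable, u: str, v: str
) -> float:
    """Jaccard of L(u), L(v) times the mean of the two self-localization
    scores; 0 when neither protein is annotated."""
    lu = loc.compartments(u)
    lv = loc.compartments(v)
    union = lu | lv
    if not union:
        return 0.0
    jaccard = len(lu & lv) / len(union)
    mean_score = (
        self_localization_score(freq, loc, u) + self_localization_score(freq, loc, v)
    ) / 2.0
    return jaccard * mean_score


def build_cln(network: PPINetwork, loc: LocalizationTable) -> WeightedLayer:
    """Co-localization layer: colo_sub on every edge.

    A network with no annotated protein at all yields the all-zero layer
    (the frequency normalization is skipped as there is nothing to score).
    """
    rows, cols = network.edge_arrays()
    if loc.n_annotated == 0:
        return _edge_layer(network, np.zeros(len(rows)), "CLN")
    freq = location_frequency(loc)
    ids = network.node_ids
    s_scores = [self_localization_score(freq, loc, pid) for pid in ids]
    values = np.empty(len(rows))
    for k, (i, j) in enumerate(zip(rows, cols)):
        lu = loc.compartments(ids[i])
        lv = loc.compartments(ids[j])
        union = lu | lv
        if not union:
            values[k] = 0.0
        else:
            values[k] = (len(lu & lv) / len(union)) * (s_scores[i] + s_scores[j]) / 2.0
    return _edge_layer(network, values, "CLN")
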