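"""Fusion of the three layers into LSG scores and the PCIN transition matrix.

Each protein gets a fused neighbourhood score

    LSG(u) = Σ_{v ∈ NG(u)} DBN(u, v) · (colo_sub(u, v) + Connection(u, v)),

and the comprehensive interaction matrix is

    PCIN(i, i) = LSG(i) / Σ_k LSG(k)
    PCIN(i, j) = min(LSG(i), LSG(j)) / Σ_k LSG(k)   for edges (i, j) of E.

Off-diagonal entries are restricted to the PPI edge set so that the matrix
remains a re-weighting of the observed interaction topology (and stays
sparse); ``dense=True`` realizes the alternative all-pairs reading for
comparison.  Either way PCIN is symmetric, nonnegative, and column
sub-stochastic: each column sum is bounded by
(LSG(i) + Σ_{j≠i} LSG(j)) / Σ_k LSG(k) = 1, because min(LSG(i), LSG(j)) ≤
LSG(j).  Sub-stochasticity is what guarantees convergence of the damped
iteration for any teleport weight α > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import PPINetwork
from .layers import WeightedLayer

__all__ = ["LSGVector", "TransitionMatrix", "lsg_scores", "build_pcin"]


@dataclass
class LSGVector:
    """Per-protein fused layer scores, aligned with the network node order."""

    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class TransitionMatrix:
    """The comprehensive interaction matrix PCIN (sparse unless dense=True)."""

    node_ids: list[str]
    matrix: sp.csr_matrix | np.ndarray
    dense: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ x).ravel()

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


def _check_alignment(network: PPINetwork, *ls: WeightedLayer) -> None:
    for layer in ls:
        if layer.node_ids != network.node_ids:
            raise ValueError(
                f"layer {layer.tag} node order does not match the network"
            )


def lsg_scores(
    adn: WeightedLayer,
    cen: WeightedLayer,
    cln: WeightedLayer,
    network: PPINetwork,
) -> LSGVector:
    """Fuse the three layers into per-protein LSG scores.

    Isolated nodes have an empty neighbour sum and score 0.
    """
    _check_alignment(network, adn, cen, cln)
    combined = adn.matrix.multiply(cen.matrix + cln.matrix)
    values = np.asarray(combined.sum(axis=1)).ravel()
    return LSGVector(values=values)


def build_pcin(
    network: PPINetwork, lsg: LSGVector, dense: bool = False
) -> TransitionMatrix:
    """Construct PCIN from the fused scores.

    Raises ``ValueError`` when all fused weights are zero, which signals
    missing or constant biological data rather than a numerical problem.
    """
    values = np.asarray(lsg.values, dtype=float)
    if values.shape != (network.n_nodes,):
        raise ValueError("LSG vector length does not match the network")
    total = values.sum()
    if total <= 0.0:
        raise ValueError("degenerate network: all fused weights zero")
    diag = values / total
    if dense:
        pairwise = np.minimum.outer(values, values) / total
        np.fill_diagonal(pairwise, diag)
        return TransitionMatrix(node_ids=network.node_ids, matrix=pairwise, dense=True)
    rows, cols = network.edge_arrays()
    off = np.minimum(values[rows], values[cols]) / total
    n = network.n_nodes
    matrix = sp.csr_matrix(
        (
            np.concatenate([off, off, diag]),
            (
                np.concatenate([rows, cols, np.arange(n)]),
                np.concatenate([cols, rows, np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )
    return TransitionMatrix(node_ids=network.node_ids, matrix=matrix, dense=False)
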