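"""End-to-end orchestration: layers → fusion → iteration → ranking.

Also hosts the layer-subset rule shared by the CLI ``--layers`` flag and the
ablation study: with M = ADN where selected (else unit weights on edges) and
S = the sum of the selected co-expression/co-localization layers (else unit
weights on edges), the fused score is LSG(u) = Σ_v M(u,v)·S(u,v).  The full
selection reproduces the standard fusion, a single layer reduces to that
layer's row sums, and the empty selection reduces to plain degree (the
unweighted-PPI control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .integration import LSGVector, TransitionMatrix, build_pcin, lsg_scores
from .io_formats import (
    ExpressionTable,
    LocalizationTable,
    OrthologyTable,
    PPINetwork,
)
from .layers import WeightedLayer, build_adn, build_cen, build_cln
from .ranking import (
    IterationConfig,
    ScoreVector,
    conservatism_seed,
    iterate_scores,
    rank_proteins,
    uniform_seed,
)

__all__ = ["PipelineResult", "run_pipeline", "variant_lsg", "unit_edge_layer"]

ALL_LAYERS = ("adn", "cen", "cln")


def unit_edge_layer(network: PPINetwork, tag: str = "UNIT") -> WeightedLayer:
    """Weight 1 on every edge of E — the unweighted-PPI control layer."""
    rows, cols = network.edge_arrays()
    n = network.n_nodes
    matrix = sp.csr_matrix(
        (
            np.ones(2 * len(rows)),
            (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
        ),
        shape=(n, n),
    )
    return WeightedLayer(node_ids=network.node_ids, matrix=matrix, tag=tag)


def variant_lsg(
    network: PPINetwork,
    adn: WeightedLayer,
    cen: WeightedLayer,
    cln: WeightedLayer,
    layers: Iterable[str],
) -> LSGVector:
    """Fused scores for an arbitrary subset of the three layers."""
    selected = set(layers)
    unknown = selected - set(ALL_LAYERS)
    if unknown:
        raise ValueError(f"unknown layers: {sorted(unknown)}")
    if selected == set(ALL_LAYERS):
        return lsg_scores(adn, cen, cln, network)
    unit = unit_edge_layer(network)
    mult = adn.matrix if "adn" in selected else unit.matrix
    additive = [l.matrix for t, l in (("cen", cen), ("cln", cln)) if t in selected]
    add = sum(additive) if additive else unit.matrix
    values = np.asarray(mult.multiply(add).sum(axis=1)).ravel()
    return LSGVector(values=values)


@dataclass
class PipelineResult:
    """Everything a run produces, for reporting and evaluation."""

    network: PPINetwork
    lsg: LSGVector
    pcin: TransitionMatrix
    seed: ScoreVector
    scores: ScoreVector
    ranked: list[tuple[str, float, int]]
    diagnostics: dict = field(default_factory=dict)


def run_pipeline(
    network: PPINetwork,
    expr: ExpressionTable,
    loc: LocalizationTable,
    orth: OrthologyTable,
    cfg: IterationConfig | None = None,
    layers: Iterable[str] = ALL_LAYERS,
    dense_pcin: bool = False,
    seedless_uniform: bool = False,
) -> PipelineResult:
    """Build the layers, fuse, iterate, and rank.

    ``layers`` selects which of adn/cen/cln participate in the fusion;
    ``seedless_uniform`` replaces the conservatism seed with 1/N.
    """
    cfg = cfg or IterationConfig()
    adn = build_adn(network)
    cen = build_cen(network, expr)
    cln = build_cln(network, loc)
    lsg = variant_lsg(network, adn, cen, cln, layers)
    pcin = build_pcin(network, lsg, dense=dense_pcin)
    seed = uniform_seed(network) if seedless_uniform else conservatism_seed(orth, network)
    scores = iterate_scores(pcin, seed, cfg, network.n_edges)
    ranked = rank_proteins(scores, network.node_ids)
    diagnostics = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "expression_coverage": int(expr.coverage(network.node_ids).sum()),
        "localization_annotated": sum(
            1 for pid in network.node_ids if loc.compartments(pid)
        ),
        "orthology_nonzero": sum(
            1 for pid in network.node_ids if orth.count(pid) > 0
        ),
        "iterations": scores.iterations,
        "residual": scores.residual,
        "converged": scores.converged,
        "layers": sorted(set(layers)),
    }
    return PipelineResult(
        network=network,
        lsg=lsg,
        pcin=pcin,
        seed=seed,
        scores=scores,
        ranked=ranked,
        diagnostics=diagnostics,
    )
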