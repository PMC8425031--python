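"""Evaluation of a ranking against a known-essential reference set.

Four instruments: precision at the top K% of the ranking, the jackknife
curve (cumulative essential count by rank), ROC / precision–recall curves
with their areas, and F1 (both the maximum over the threshold sweep and at
the cutoff equal to the number of essentials).  Essential IDs absent from
the ranked network are excluded from every denominator, with a logged
count — rankings can only be judged on proteins they actually scored.

Curve computation is delegated to scikit-learn (``roc_curve``,
``precision_recall_curve``); the PR area uses average precision, i.e. the
step-interpolated sum, the conservative convention for the heavily skewed
essential/non-essential class balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .io_formats import (
    ExpressionTable,
    LocalizationTable,
    OrthologyTable,
    PPINetwork,
)
from .pipeline import run_pipeline
from .ranking import IterationConfig, rank_proteins, top_k_percent

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "precision_at_top",
    "jackknife_curve",
    "roc_pr_curves",
    "f1_scores",
    "evaluate_ranking",
    "degree_baseline_ranking",
    "run_ablation",
    "ABLATION_VARIANTS",
]

DEFAULT_TOP_PERCENTS = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0)

# variant name -> layer subset fed to the fusion rule
ABLATION_VARIANTS: dict[str, tuple[str, ...]] = {
    "InitPPI": (),
    "ADN": ("adn",),
    "CEN": ("cen",),
    "CLN": ("cln",),
    "PCIN": ("adn", "cen", "cln"),
}


def _restrict_essential(
    ranked_ids: list[str], essential: set[str]
) -> set[str]:
    present = essential & set(ranked_ids)
    missing = len(essential) - len(present)
    if missing:
        logger.info(
            "%d essential proteins absent from the ranked network; excluded",
            missing,
        )
    return present


def precision_at_top(
    ranked: list[tuple[str, float, int]], essential: set[str], k_percent: float
) -> tuple[int, float]:
    """(true-essential count, precision) among the top K% of the ranking."""
    if not ranked:
        raise ValueError("empty ranking")
    top = top_k_percent(ranked, k_percent)
    ess = _restrict_essential([pid for pid, _, _ in ranked], essential)
    count = sum(1 for pid in top if pid in ess)
    return count, count / len(top) if top else 0.0


def jackknife_curve(
    ranked: list[tuple[str, float, int]], essential: set[str], depth: int
) -> np.ndarray:
    """Cumulative essential count at each rank r = 1..depth."""
    if depth > len(ranked):
        raise ValueError("depth exceeds the number of ranked proteins")
    ess = _restrict_essential([pid for pid, _, _ in ranked], essential)
    hits = np.fromiter(
        (pid in ess for pid, _, _ in ranked[:depth]), dtype=int, count=depth
    )
    return np.cumsum(hits)


def _labels_scores(
    node_ids: list[str], scores: np.ndarray, essential: set[str]
) -> tuple[np.ndarray, np.ndarray]:
    ess = _restrict_essential(list(node_ids), essential)
    y = np.fromiter((pid in ess for pid in node_ids), dtype=int, count=len(node_ids))
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both essential and non-essential proteins to score")
    return y, np.asarray(scores, dtype=float)


def roc_pr_curves(
    node_ids: list[str], scores: np.ndarray, essential: set[str]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC points, PR points, AUROC (trapezoidal) and AUPR (step/AP)."""
    y, s = _labels_scores(node_ids, scores, essential)
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    auroc = float(auc(fpr, tpr))
    aupr = float(average_precision_score(y, s))
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([recall, precision])
    return roc_points, pr_points, auroc, aupr


def f1_scores(
    node_ids: list[str], scores: np.ndarray, essential: set[str]
) -> tuple[float, float]:
    """(max F1 over the threshold sweep, F1 at cutoff = |essential|).

    The second value treats exactly the top-|essential| proteins as
    predicted positives, the natural operating point when the prevalence is
    known.
    """
    y, s = _labels_scores(node_ids, scores, essential)
    precision, recall, _ = precision_recall_curve(y, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    max_f1 = float(np.nanmax(f1))
    n_pos = int(y.sum())
    top_idx = np.argsort(-s, kind="stable")[:n_pos]
    tp = int(y[top_idx].sum())
    prec = tp / n_pos
    rec = tp / n_pos
    f1_at = 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)
    return max_f1, f1_at


@dataclass
class EvaluationReport:
    """All four instruments for one ranking, plus bookkeeping counts."""

    n_ranked: int
    n_essential: int
    top_counts: dict[float, int]
    top_precisions: dict[float, float]
    jackknife: np.ndarray
    auroc: float
    aupr: float
    max_f1: float
    f1_at_essential_count: float
    roc_points: np.ndarray = field(repr=False, default=None)
    pr_points: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_ranked": self.n_ranked,
            "n_essential": self.n_essential,
            "top_counts": {str(k): v for k, v in self.top_counts.items()},
            "top_precisions": {str(k): v for k, v in self.top_precisions.items()},
            "auroc": self.auroc,
            "aupr": self.aupr,
            "max_f1": self.max_f1,
            "f1_at_essential_count": self.f1_at_essential_count,
            "jackknife": self.jackknife.tolist(),
        }


def evaluate_ranking(
    ranked: list[tuple[str, float, int]],
    essential: set[str],
    top_percents: tuple[float, ...] = DEFAULT_TOP_PERCENTS,
    jackknife_depth: int = 1000,
) -> EvaluationReport:
    """Full evaluation of one ranked list against the essential set."""
    node_ids = [pid for pid, _, _ in ranked]
    scores = np.array([s for _, s, _ in ranked])
    ess = _restrict_essential(node_ids, essential)
    depth = min(jackknife_depth, len(ranked))
    top_counts: dict[float, int] = {}
    top_precisions: dict[float, float] = {}
    for k in top_percents:
        c, p = precision_at_top(ranked, ess, k)
        top_counts[k] = c
        top_precisions[k] = p
    roc_points, pr_points, auroc, aupr = roc_pr_curves(node_ids, scores, ess)
    max_f1, f1_at = f1_scores(node_ids, scores, ess)
    return EvaluationReport(
        n_ranked=len(ranked),
        n_essential=len(ess),
        top_counts=top_counts,
        top_precisions=top_precisions,
        jackknife=jackknife_curve(ranked, ess, depth),
        auroc=auroc,
        aupr=aupr,
        max_f1=max_f1,
        f1_at_essential_count=f1_at,
        roc_points=roc_points,
        pr_points=pr_points,
    )


def degree_baseline_ranking(network: PPINetwork) -> list[tuple[str, float, int]]:
    """Plain degree-centrality ranking, the sanity baseline."""
    from .ranking import ScoreVector

    degrees = network.degrees().astype(float)
    return rank_proteins(ScoreVector(values=degrees), network.node_ids)


def run_ablation(
    network: PPINetwork,
    expr: ExpressionTable,
    loc: LocalizationTable,
    orth: OrthologyTable,
    essential: set[str],
    cfg: IterationConfig | None = None,
    top_percents: tuple[float, ...] = DEFAULT_TOP_PERCENTS,
    jackknife_depth: int = 1000,
) -> dict[str, EvaluationReport]:
    """Evaluate the five PCIN variants on identical inputs.

    InitPPI uses unit edge weights (the unweighted-PPI control); ADN/CEN/CLN
    keep a single layer; PCIN is the full fusion.  All variants share the
    network, the seed vector, the iteration config, and the essential set.
    """
    cfg = cfg or IterationConfig()
    depth = min(jackknife_depth, network.n_nodes)
    reports: dict[str, EvaluationReport] = {}
    for name, layer_subset in ABLATION_VARIANTS.items():
        result = run_pipeline(
            network, expr, loc, orth, cfg=cfg, layers=layer_subset
        )
        reports[name] = evaluate_ranking(
            result.ranked, essential, top_percents, depth
        )
    return reports
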