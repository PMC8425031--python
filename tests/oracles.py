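"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — dict-of-sets graphs, explicit Python
loops, textbook formulas — and never calls into the package's own numerics.
"""

from __future__ import annotations

import math


def edge_set(pairs):
    """Canonical undirected edge set from raw ID pairs (self-pairs dropped)."""
    return {frozenset(p) for p in pairs if p[0] != p[1]}


def adjacency_dict(n, edges):
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def dbn(adj, u, v):
    shared = len(adj[u] & adj[v])
    return (shared + 1) / min(len(adj[u]), len(adj[v]))


def pcc(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((a - my) ** 2 for a in y) / (n - 1))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / ((n - 1) * sx * sy)


def connection(adj, profiles, u, v):
    """profiles: dict index -> list of floats or None for uncovered."""

    def safe_pcc(a, b):
        if profiles.get(a) is None or profiles.get(b) is None:
            return 0.0
        return pcc(profiles[a], profiles[b])

    value = safe_pcc(u, v)
    for eps in adj[u] & adj[v]:
        value += safe_pcc(u, eps) * safe_pcc(v, eps)
    return max(value, 0.0)


def sub_scores(location_sets):
    """Compartment -> relative frequency, counting proteins per compartment."""
    counts = {}
    for comps in location_sets.values():
        for c in comps:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    return {c: k / total for c, k in counts.items()}


def s_score(scores, comps):
    return sum(scores.get(c, 0.0) for c in comps)


def colo_sub(scores, lu, lv):
    union = lu | lv
    if not union:
        return 0.0
    jac = len(lu & lv) / len(union)
    return jac * (s_score(scores, lu) + s_score(scores, lv)) / 2.0


def lsg(adj, profiles, location_sets, u, scores=None):
    """``scores`` defaults to frequencies of the given sets; pass the
    table-wide frequencies when the annotation database exceeds the network."""
    if scores is None:
        scores = sub_scores(location_sets) if any(location_sets.values()) else {}
    total = 0.0
    for v in adj[u]:
        total += dbn(adj, u, v) * (
            colo_sub(scores, location_sets.get(u, frozenset()),
                     location_sets.get(v, frozenset()))
            + connection(adj, profiles, u, v)
        )
    return total


def pcin_dense(adj, lsg_values, edge_restricted=True):
    """Dense PCIN as a list of lists."""
    n = len(lsg_values)
    total = sum(lsg_values)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        out[i][i] = lsg_values[i] / total
        for j in range(n):
            if i == j:
                continue
            if edge_restricted and j not in adj[i]:
                continue
            out[i][j] = min(lsg_values[i], lsg_values[j]) / total
    return out


def auroc_mann_whitney(scores, labels):
    """AUROC as the normalized Mann–Whitney U (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def max_f1_exhaustive(scores, labels):
    """Max F1 over every top-n cutoff of the score-sorted list."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    best = 0.0
    tp = 0
    for n, i in enumerate(order, start=1):
        tp += int(labels[i])
        if tp:
            prec = tp / n
            rec = tp / n_pos
            best = max(best, 2 * prec * rec / (prec + rec))
    return best
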