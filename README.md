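# tgso — essential-protein ranking from multi-source weighted PPI networks

Essential proteins are those a cell cannot survive without; finding them in a
protein–protein interaction (PPI) network matters for understanding minimal
cellular machinery and for prioritizing drug targets. Pure topology-based
centrality measures suffer from the noise of high-throughput interaction
data, so this package fuses the network's local density with three biological
data sources — gene-expression time courses, subcellular localization, and
orthology conservation — into a single iterative ranking.

Intended users: computational/systems biologists ranking candidate essential
genes in a PPI dataset (e.g. yeast DIP/Krogan/Gavin-style edge lists) with
accompanying expression, localization and orthology tables.

## Method

Given the undirected PPI graph `G = (V, E)` with `N` proteins, three
edge-weighted versions of `G` are built:

* **ADN** (aggregation degree): each edge `(u, v)` gets
  `DBN(u,v) = (|NG(u) ∩ NG(v)| + 1) / min(|NG(u)|, |NG(v)|)`,
  a neighbourhood-density weight reflecting that essential proteins sit in
  tightly connected modules.
* **CEN** (co-expression): with `PCC` the sample Pearson correlation of
  expression profiles,
  `Connection(u,v) = PCC(u,v) + Σ_{ε ∈ NG(u)∩NG(v)} PCC(u,ε)·PCC(v,ε)`,
  floored at 0.
* **CLN** (co-localization): compartment frequencies
  `sub_score(i) = sub(i) / Σ_k sub(k)` give each protein a self-localization
  score `S_score(u) = Σ_{i∈L(u)} sub_score(i)`, and each edge
  `colo_sub(u,v) = |L(u)∩L(v)|/|L(u)∪L(v)| · (S_score(u)+S_score(v))/2`.

The layers are fused per protein,
`LSG(u) = Σ_{v∈NG(u)} DBN(u,v)·(colo_sub(u,v) + Connection(u,v))`,
and assembled into the comprehensive transition matrix

```
PCIN(i,i) = LSG(i) / Σ_k LSG(k)
PCIN(i,j) = min(LSG(i), LSG(j)) / Σ_k LSG(k)   for (i,j) ∈ E
```

which is symmetric, nonnegative and column-sub-stochastic. Ortholog counts
`I(i)` (number of reference organisms with an ortholog) are normalized into
the seed `P0`, and scores follow the damped fixed-point iteration

```
P_{t+1} = (1 − α)·PCIN·P_t + α·P0        (α = 0.3 by default)
```

until `‖P_{t+1} − P_t‖₁ / |E| < γ`. Proteins are ranked by the converged
score, descending. Sub-stochasticity makes the update a contraction with
factor ≤ (1 − α), so convergence is geometric for every α > 0.

## Worked example

Everything below runs offline on a synthetic benchmark bundle whose planted
structure matches the method's assumptions (dense essential module, shared
essential expression signal, compartment enrichment, elevated ortholog
counts):

```
$ tgso simulate --out demo --seed 42 --n 300
wrote bundle: N=300, |E|=693, 60 essential -> demo

$ tgso -v run --ppi demo/ppi.tsv --expr demo/expression.tsv \
      --subcell demo/localization.tsv --ortho demo/orthology.tsv \
      -o demo/ranking.tsv
INFO tgso: iterations = 8
INFO tgso: residual = 9.834451983855676e-12

$ head -4 demo/ranking.tsv
rank    protein score
1       P0183   0.0027147332883821888
2       P0138   0.0026193973139805398
3       P0201   0.0025158504765858541

$ tgso evaluate --ranking demo/ranking.tsv --essential demo/essential.txt \
      --jackknife-depth 100 -o demo/report.json
```

The report contains `auroc = 1.0`, `aupr = 1.0`, `max_f1 = 1.0` and
top-K precisions `{1%: 1.0, 5%: 1.0, 10%: 1.0, 15%: 1.0, 20%: 1.0,
25%: 0.8}`: on this bundle all 60 planted essential proteins are recovered
ahead of every background protein (the top 25% cut contains 75 proteins, so
its precision ceiling is 60/75 = 0.8). The scores themselves are on the
scale of `1/N`-normalized probability mass; only their order matters for the
ranking.

`tgso ablate` evaluates five variants on identical inputs — unweighted PPI
control, each single layer, and the full fusion — and `tgso simulate --null`
generates a matched null bundle with every essential/background distinction
removed (ranking there is chance-level, AUROC ≈ 0.5).

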