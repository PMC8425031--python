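# Methods

## Model

The ranking treats essentiality as a diffusion problem on a re-weighted PPI
graph. Three weighted copies of the graph encode, per edge, (i) local module
density (ADN), (ii) co-expression of the endpoints and their shared
neighbours (CEN), and (iii) compartment co-membership scaled by how populous
those compartments are (CLN). The per-protein fusion
`LSG(u) = Σ_v DBN·(colo_sub + Connection)` rewards proteins whose
neighbourhoods are simultaneously dense, co-expressed and co-localized. The
transition matrix `PCIN` divides `LSG`-derived entries by the global sum
`Σ_k LSG(k)`; because `min(LSG(i), LSG(j)) ≤ LSG(j)`, every column sums to at
most 1 (sub-stochastic), which makes the damped update
`P_{t+1} = (1−α)·PCIN·P_t + α·P0` an L1 contraction with ratio ≤ (1−α) and
guarantees a unique fixed point reached geometrically for any α > 0. The
seed `P0` normalizes ortholog counts, so conservation information enters as
a prior rather than as an edge weight.

Assumptions inherited from the model: essential proteins form dense modules,
share expression dynamics, co-occur in compartments, and are conserved more
broadly than background proteins. Data that violate these premises (e.g.
date hubs with time-shifted expression) weaken the corresponding layer but
do not break the pipeline — each layer degrades gracefully to zero weight.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.3 | seed teleport weight; 1 returns the conservation prior, 0 is pure propagation |
| `gamma` | 1e-10 | stop threshold on the per-edge L1 residual |
| `max_iterations` | 1000 | hard cap; at α = 0.3 convergence takes < 10 steps in practice |
| `residual_divisor` | `edges` | the residual is divided by \|E\| (switchable to N) |

The residual is divided by the edge count, which on realistic networks
(\|E\| ~ 10⁴) makes a loose γ stop immediately; γ = 1e-10 was chosen so the
stop rule binds meaningfully at score magnitudes of order 1/N while leaving
the iteration far below the cap. Both the divisor and the L1 norm choice are
exposed in `IterationConfig`.

## Conventions for incomplete data

Real expression, localization and orthology tables never cover the whole
network. The conventions, applied consistently:

* a protein without an expression profile, or with a zero-variance profile,
  contributes `PCC = 0` to every pair it touches;
* `Connection` is floored at 0 after evaluation — correlations can be
  negative but the fusion and the iteration presuppose nonnegative weights;
* a protein pair with no compartment annotation on either side has
  co-localization 0 (empty Jaccard union is defined as 0, not an error);
* a protein absent from the orthology table has `I = 0`; if *all* counts are
  zero the seed falls back to uniform `1/N` with a warning;
* compartment frequencies `sub_score` are normalized over the compartment
  vocabulary (a distribution over the 11 compartments), and the counts are
  taken over the full annotation table, which may exceed the network;
* proteins left with `LSG = 0` (isolated or fully uncovered) are retained;
  their final score is driven by the seed through the α-term alone. Only the
  fully degenerate case `Σ LSG = 0` is an error.

## Design choices that were genuinely open

* **Edge-restricted PCIN.** The `min(LSG)/ΣLSG` rule applied to *every* pair
  would produce a dense matrix that ignores the interaction topology and
  makes the three layer constructions irrelevant to the stationary
  distribution. Off-diagonal entries are therefore restricted to edges of E;
  the dense all-pairs variant remains available (`dense=True`,
  `--dense-pcin`) for comparison. Both variants are sub-stochastic.
* **Diagonal term.** The self-entry `LSG(i)/ΣLSG` is kept inside the
  matrix–vector product, i.e. it acts as a self-loop during propagation.
* **Tie rule.** Equal scores are ordered by ascending protein ID so that
  rankings are bit-reproducible.
* **Top-K count.** `round(N·K/100)` with half-up rounding — consistent with
  cut sizes of 51 at N = 5093 and 37 at N = 3672 for K = 1.
* **Layer subsets.** For ablation and the `--layers` flag, the fusion
  generalizes as `LSG = Σ_v M·S` with M = ADN if selected (else 1 on edges)
  and S = the sum of selected CEN/CLN (else 1 on edges). The full set gives
  the standard fusion, singletons give single-layer row sums, and the empty
  set gives plain degree — the unweighted-PPI control.
* **F1 reporting.** Published F1 comparisons rarely state the cutoff; the
  evaluation reports both the maximum F1 over the threshold sweep and F1 at
  the cutoff equal to the number of essentials, labelled separately.
* **PR convention.** Average precision (step interpolation), the
  conservative choice for the heavily skewed essential/background balance;
  essential IDs absent from the ranked network are excluded from all
  denominators with a logged count.

## Synthetic benchmark

`tgso.synthetic` generates complete five-file input bundles with the planted
structure the method assumes: a two-block Bernoulli graph (essential–
essential edge probability 0.08 vs 0.015 mixed and 0.01 background, N = 500,
20% essential), expression over T = 36 time points where essential proteins
share one sinusoidal latent signal (random phase per bundle, noise sd 0.3)
and background proteins are independent noise (sd 1.0), localization over an
11-compartment vocabulary with essential proteins carrying a designated
enriched compartment with probability 0.7, and ortholog counts
Binomial(99, 0.6) for essential vs Binomial(99, 0.2) for background
proteins. A block model was preferred over preferential attachment because
the topological signal being tested is neighbourhood overlap, which a
planted dense block exercises directly and controllably; a
degree-heterogeneous variant (lognormal propensities) is available as a
config option. All randomness derives from one integer seed through named
`SeedSequence` child streams (labels/topology/expression/localization/
orthology), so bundles regenerate bit-identically and the components are
independently perturbable. Nodes left isolated by the Bernoulli draw are
attached to one random partner, since an edge-list file cannot represent
degree-0 proteins and evaluation percentages should not silently change on
a write/read round trip.

What the generator does **not** emulate: scale-free degree tails of real
interactomes, correlated noise or periodic harmonics beyond one sinusoid,
hierarchical compartment ontology, partial table coverage (real expression
tables cover fewer proteins than the PPI), and ID mismatches between
sources. Passing the planted-recovery tests therefore demonstrates that the
implementation exploits each signal when present and stays calibrated when
absent (null AUROC ≈ 0.5) — not that comparable accuracy would be achieved
on any specific real dataset.

## Problem sizes

Unit and oracle tests run at N ≤ 15 (exhaustive brute-force cross-checks to
1e-12) and N ≤ 200 (closed-form linear-solve comparison of the fixed
point). The stochastic benchmark uses the default N = 500 over 5 seeds, with
10 seeds for the null calibration; the full suite and the acceptance script
each complete in seconds on one CPU.

## Known limitations

* Identifier matching is exact string equality; reconciling accession
  schemes across databases is left to data preparation.
* The co-expression layer is O(Σ_edges |common neighbours| · T) computed
  per edge; adequate for networks of ~10⁴–10⁵ edges, not tuned beyond that.
* Negative co-expression information is discarded by the nonnegativity
  floor; alternative treatments (shifting, absolute value) were not
  explored.
* No statistical comparison between methods is provided — the degree
  baseline is a sanity reference, not a benchmark suite of centrality
  measures.
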