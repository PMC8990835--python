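# Methods

## The model

A disease is represented as an undirected simple graph `G = (V, E)`:
nodes are disease-associated gene/protein symbols, edges are
protein–protein interactions passing a confidence cutoff.  A
multi-target drug is a set of target symbols; its *attack* deletes
every target present in the network together with all incident edges.
The premise is that a drug which dismantles the topology of a disease
network (or of a process-specific subnetwork) is a candidate modulator
of that disease or process.

Four whole-graph statistics summarize robustness:

- **AD**, average degree: `Σ_v deg(v) / n` (= `2m/n`).
- **ASPL**, average shortest path length: mean of `d(s,t)` over ordered
  reachable pairs `s ≠ t`.
- **DC**, Freeman degree centralization:
  `Σ_v [deg(v*) − deg(v)] / ((n−1)(n−2))`, `v*` the maximal-degree
  node.  1 on a star, 0 on any vertex-transitive graph.
- **CC**, closeness centralization:
  `Σ_v [clo(v#) − clo(v)] / ((n−1)(n−2)/(2n−3))`, `v#` the
  maximal-closeness node, with the same extremes.

The per-metric **robustness index** is the relative change
`RI = (after − before)/before` across the attack.  Raw RIs depend on
network size and density, so each is normalized against a permutation
null: `n_reps` uniform `G(n, m)` random graphs on the *same node label
set* (node and edge counts preserved, so the identical attack applies),
each attacked by the same drug.  `Normalized RI = (RI_real − mean_null)/sd_null`
is a z-score.  The composite

```
Total Score = z_ASPL − z_AD − z_DC − z_CC
```

is signed so that larger always means more destabilizing (a damaging
attack lengthens paths and lowers degree and centralization).  Agents
are compared by the percentage of a reference panel they strictly beat.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `gda_cutoff` | 0.01 | gene–disease association score must be **strictly greater** to enter |
| `ppi_cutoff` | 0.4 | PPI confidence must be strictly greater (0–1000 columns auto-scaled by 1/1000) |
| `max_edge_occurrence` | 4 | an interaction present in more than this many functional subnetworks is pruned from all of them |
| `n_reps` | 100 | null replicates per (drug, network) cell |
| `seed` | 0 | master seed; every replicate seed derives from it |

The cutoff comparisons are deliberately strict inequalities, and genes
left without any passing interaction are dropped at construction, so a
disease network's node count is usually below its gene count.

## Conventions for fragmented graphs

Attacks routinely disconnect a network, so the statistics carry
explicit conventions rather than failing:

- ASPL averages over *reachable* ordered pairs only; with no reachable
  pair (edgeless graph) it is undefined and carried as NaN, never 0.
- Closeness uses the Wasserman–Faust component scaling
  `clo(v) = ((n_C−1)/(n−1)) · ((n_C−1)/Σ_{t∈C} d(v,t))`, which reduces
  to the classic form on connected graphs; isolated nodes get 0.
- Centralizations need `n ≥ 3`; smaller graphs return 0 with a logged
  warning so a heavily attacked subnetwork still yields a profile.
- `RI = 0/0` (a zero metric that stays zero, e.g. the empty attack on a
  vertex-transitive graph) is 0 — the identity attack changes nothing;
  a zero before-metric that *changes* makes that RI undefined (NaN).
- A null SD of 0 (e.g. a drug with no hits, where every replicate's RI
  is identically 0) makes the z-score and total undefined.  Undefined
  values propagate as NaN end to end and are written as empty cells
  with a reason column — never coerced to 0, which is a meaningful
  score.
- Attack survivors that become isolated are retained, so before/after
  profiles compare the same residual node set.

The null SD is the sample SD (ddof = 1): the null is itself estimated
from finitely many draws.  At 100 replicates the difference from the
population SD is below 1%.

## Numerical and determinism choices

All distances are unweighted and computed by igraph's C breadth-first
search; every statistic is a closed-form reduction of one distance
matrix, so a profile costs a single pass.  The test suite checks the
production route against an independent Floyd–Warshall implementation
to 1e-12 on random graphs.

`G(n, m)` nulls are drawn by sampling `m` of the `C(n,2)` pair indices
without replacement (numpy Generator) and decoding them, which is
uniform over simple graphs with exactly those counts.  Seeds follow a
counter scheme — `stage seed = master + stage offset`, `cell seed =
stage seed + cell index · n_reps`, `replicate seed = cell seed +
replicate index`, all mod 2³¹ — so every cell of a score matrix is
independently reproducible from the run manifest, and identical
config + seed reproduces output files byte for byte.

Maximal-degree and maximal-closeness ties need no tie-breaking: the
centralization formulas depend only on the maximal *value*.

The disease network keeps all non-isolated nodes; it is not restricted
to its largest connected component (the choice is recorded in the run
manifest).

## Functional subnetworks

Each clustered pathological process (a gene → cluster table; genes may
belong to several clusters) induces a subnetwork on its genes.  Edges
occurring in more than `max_edge_occurrence` subnetworks carry no
process-specific signal and are pruned from all subnetworks; the pruned
edges are written to a side file for inspection but are not scored as
an additional subnetwork.  Clusters left with fewer than 3 nodes are
kept but flagged (their centralizations are degenerate).

## Compound content aggregation

A compound's chromatographic peak-area ratio proxies its relative
content.  Per-target sums simply add the ratios of all compounds
hitting the target.  Per-process sums count each compound **once** even
if it hits several of the process's targets: the ratio is a mass proxy
and double-counting could exceed total content.  The per-target sums
are deliberately left un-deduplicated.

## What the synthetic generator emulates — and what it does not

Real inputs are snapshots of curated databases that cannot be
redistributed, so validation runs on synthetic data with known ground
truth.  The generator draws a planted-partition (stochastic block)
graph — by default 600 genes in 6 equal modules with `p_within = 0.10`
and `p_between = 0.0102`, giving ~4500 expected edges, the scale of the
emulated disease networks — and emits exactly the table dialects the
readers consume, including a 10% fraction of decoy genes and edges
below the cutoffs that must be filtered out on the way back in.

Synthetic drugs have a target count, an optional focus module, a
specificity (fraction of targets from the focus module) and a hub bias.
A focused drug's module targets are drawn with probability
`deg^hub_bias` where degree is measured *inside the module's induced
subgraph* — a module-specific drug targets the hubs of that module —
while its off-module remainder models nonspecific leakage and is drawn
uniformly.  An unfocused drug applies the hub bias to whole-network
degree.

Limitations to keep in mind when interpreting green tests:

- Planted-partition blocks are internally Erdős–Rényi; real PPI
  networks are heavy-tailed and locally clustered.  Hub-deletion
  effects here are therefore conservative relative to scale-free
  topologies.
- The total score is sensitive to single lucky hub hits: deleting one
  node that happens to be a module's top hub can score 7–8 against the
  `G(n, m)` null.  With ≥10% nonspecific target leakage this
  occasionally outranks a genuinely module-focused attack, so module
  attribution for low-specificity drugs should be read with care.
- Gene symbols, association scores and confidences are structurally
  faithful but carry no biology; nothing here validates identifier
  mapping against real databases.

## Validation problem sizes

The suite validates the null calibration on `G(60, 180)` draws
(200 experiments × 100-rep nulls: each z-score metric must be
standard-normal to Monte-Carlo precision), module recovery on 50 runs
at the full 600-node scale, and an end-to-end run at the emulated
disease scale (600 genes, ~4500 edges, 40 agents, 6 subnetworks,
100-rep nulls) — sizes chosen to match the emulated study while
keeping a laptop-class run practical.
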