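# robustnet

Quantifying how hard a multi-target drug hits a disease network.

Complex diseases — the motivating case is retinal degeneration
(age-related macular degeneration, diabetic retinopathy) treated with
multi-component preparations — are modeled as protein–protein
interaction (PPI) networks over disease-associated genes.  A drug's
effect is simulated as an *attack*: every network node in the drug's
target set is deleted with its incident edges.  The more the attack
degrades the network's topology, relative to what the same attack does
to size-matched random networks, the stronger the predicted
intervention.  The same machinery scores attacks on process-specific
subnetworks (oxidative stress, inflammation, angiogenesis, ...) to
position a drug against individual pathological processes, and a
compound-content module aggregates chromatographic peak-area ratios
over targets and processes.

The package is aimed at network-pharmacology analyses: it consumes
database-style exports (gene–disease association tables, PPI edge
lists with confidence scores, drug–target tables, gene–cluster tables,
compound tables) and is exercised end to end on synthetic data with
known ground truth.

## The score

For a network `G` with `n` nodes, four whole-graph statistics are
tracked: average degree `AD = Σ deg(v)/n`, average shortest path
length `ASPL` (over reachable ordered pairs), Freeman degree
centralization `DC = Σ[deg(v*)−deg(v)]/((n−1)(n−2))` and closeness
centralization `CC = Σ[clo(v#)−clo(v)]/((n−1)(n−2)/(2n−3))`.  Each
statistic yields a robustness index `RI = (after − before)/before`
across the attack, normalized to a z-score against 100 random
`G(n, m)` networks (same nodes, same edge count) subjected to the
identical attack:

```
Normalized RI = (RI_real − mean_null) / sd_null
Total Score   = z_ASPL − z_AD − z_DC − z_CC
```

Larger total = more destabilizing attack.  Agents are ranked by the
percentage of a reference panel they strictly beat.

## Worked example

Generate a synthetic disease network (120 genes, 3 planted functional
modules, one module-focused drug plus 5 unfocused reference drugs) and
run the full pipeline:

```sh
robustnet simulate --n-genes 120 --n-modules 3 --p-within 0.25 \
    --p-between 0.02 --n-drugs 6 --seed 42 --out demo/data
robustnet run-all --gda demo/data/gda.tsv --ppi demo/data/ppi.tsv \
    --targets demo/data/drug_targets.tsv --clusters demo/data/clusters.tsv \
    --compounds demo/data/compounds.csv --reps 100 --seed 7 --out demo/out
# pipeline complete: 120-node network, 6 drug(s), 3 subnetwork(s) -> demo/out
```

`demo/out/subnetwork_scores.tsv` is the (drug × subnetwork) total-score
matrix:

```
        module_1                module_2                module_3
FOCUSED001      3.3510767798700742      -0.6813924713755624
REF001  -3.363569449051277      -0.8146993579294449     0.4035627668947843
...
```

`FOCUSED001` (targets drawn from module 1's hubs) scores 3.35 on its
own module and ≤ 0 elsewhere; its module_3 cell is *empty* because the
drug hits no node there — an undefined score is reported as a missing
value with a reason in `subnetwork_cells.tsv`, never as 0.
`demo/out/rankings.tsv` ranks it against the reference panel:

```
drug_id     network_id  total         pct_superior
FOCUSED001  disease     2.213145861   80
FOCUSED001  module_1    3.35107678    75
```

i.e. on the whole disease network its attack is superior to 80% of the
reference drugs.  Note the module_1 column also shows an unfocused
reference drug scoring high by chance — with few targets, a single
lucky hub hit is genuinely destabilizing; see `docs/methods.md` for
this and the other conventions.  `manifest.json` records every seed,
cutoff and convention needed to reproduce the bundle byte for byte.

The same stages are scriptable from Python (`robustnet.score_attack`,
`robustnet.score_subnetworks`, ...) — see the module docstrings.

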