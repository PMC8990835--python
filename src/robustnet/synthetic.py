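"""Synthetic disease-network data with known ground truth.

Real disease networks are assembled from database snapshots that are
not redistributable, so every pipeline stage is exercised instead on
synthetic data whose structure is known by construction:

* a planted-partition (stochastic block model) disease network —
  higher within-module than between-module edge probability, where the
  planted modules stand in for clustered pathological processes;
* association and confidence tables straddling the assembly cutoffs,
  written in exactly the TSV dialects the readers consume (a controlled
  fraction of decoy genes and decoy edges falls below cutoff and must
  be filtered out on the way back in);
* drug target sets with tunable module specificity and hub bias;
* a compound table with peak-area ratios and target lists.

The defaults emulate a disease network of ~600 nodes and ~4500 edges
with six functional modules.  Everything is deterministic given the
spec seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .assembly import DrugTargetSet, PPIEdge
from .compounds import CompoundRecord
from .subnetworks import ClusterAssignment

__all__ = [
    "SyntheticSpec",
    "SyntheticDrugSpec",
    "SyntheticNetwork",
    "default_spec",
    "generate_disease_network",
    "generate_drug",
    "generate_drug_panel",
    "generate_compound_table",
    "write_tables",
]

#: Fraction of decoy (below-cutoff) genes and edges added to the tables.
DECOY_FRACTION = 0.1
GDA_CUTOFF = 0.01
PPI_CUTOFF = 0.4


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-partition disease network."""

    n_genes: int = 600
    n_modules: int = 6
    p_within: float = 0.10
    p_between: float = 0.0102
    module_sizes: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.module_sizes
        if not sizes:
            base, extra = divmod(self.n_genes, self.n_modules)
            sizes = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_modules)
            )
            object.__setattr__(self, "module_sizes", sizes)
        if len(sizes) != self.n_modules or sum(sizes) != self.n_genes:
            raise ValueError(
                f"module_sizes {sizes} must be {self.n_modules} counts "
                f"summing to {self.n_genes}"
            )
        if not 0.0 <= self.p_between < self.p_within <= 1.0:
            raise ValueError(
                "need 0 <= p_between < p_within <= 1, got "
                f"p_within={self.p_within}, p_between={self.p_between}"
            )

    @property
    def expected_edges(self) -> float:
        within_pairs = sum(s * (s - 1) // 2 for s in self.module_sizes)
        all_pairs = self.n_genes * (self.n_genes - 1) // 2
        return (
            within_pairs * self.p_within
            + (all_pairs - within_pairs) * self.p_between
        )


@dataclass(frozen=True)
class SyntheticDrugSpec:
    """Parameters of a synthetic multi-target drug.

    ``specificity`` is the fraction of targets drawn from the focus
    module (0 means uniform targeting regardless of module);
    ``hub_bias`` is the exponent of degree-proportional sampling
    (0 = uniform, larger = hubs preferred).
    """

    drug_id: str
    n_targets: int = 30
    focus_module: str | None = None
    specificity: float = 0.0
    hub_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError("specificity must lie in [0, 1]")
        if self.specificity > 0 and self.focus_module is None:
            raise ValueError("specificity > 0 requires a focus_module")
        if self.hub_bias < 0:
            raise ValueError("hub_bias must be >= 0")


@dataclass(frozen=True)
class SyntheticNetwork:
    """A generated network together with its emitted tables and
    ground-truth manifest."""

    network: nx.Graph
    assignments: list[ClusterAssignment]
    gda_rows: list[tuple[str, str, float]]
    ppi_rows: list[tuple[str, str, float]]
    manifest: dict = field(default_factory=dict)

    @property
    def modules(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a in self.assignments:
            out.setdefault(a.cluster, set()).add(a.gene)
        return out


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The standard study conditions: 600 genes, 6 equal modules,
    ~4500 expected edges."""
    return SyntheticSpec(seed=seed)


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def generate_disease_network(spec: SyntheticSpec) -> SyntheticNetwork:
    """Draw a planted-partition disease network and its input tables.

    The graph is a stochastic block model on ``spec.module_sizes``
    blocks.  The GDA table assigns every network gene a score above the
    0.01 cutoff and adds a decoy fraction of extra genes below it; the
    PPI table assigns every planted edge a confidence above the 0.4
    cutoff and adds decoy edges below it.  Round-tripping the tables
    through the assembly readers therefore reconstructs exactly the
    planted network (minus any isolated genes).
    """
    if spec.expected_edges > spec.n_genes * (spec.n_genes - 1) // 2:
        raise ValueError("infeasible spec: expected edges exceed simple-graph capacity")
    rng = np.random.default_rng(spec.seed)
    sizes = list(spec.module_sizes)
    p = [
        [spec.p_within if i == j else spec.p_between for j in range(spec.n_modules)]
        for i in range(spec.n_modules)
    ]
    sbm_seed = int(rng.integers(0, 2**31))
    g = nx.stochastic_block_model(sizes, p, seed=sbm_seed)
    symbols = _gene_symbols(spec.n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(symbols)))
    for attr in ("partition",):  # SBM bookkeeping is re-derived from the manifest
        g.graph.pop(attr, None)

    module_labels = [f"module_{i + 1}" for i in range(spec.n_modules)]
    assignments: list[ClusterAssignment] = []
    membership: dict[str, str] = {}
    start = 0
    for label, size in zip(module_labels, sizes):
        for sym in symbols[start : start + size]:
            assignments.append(ClusterAssignment(gene=sym, cluster=label))
            membership[sym] = label
        start += size

    # GDA table: every planted gene passes; decoys fall at or below cutoff.
    n_decoy_genes = round(DECOY_FRACTION * spec.n_genes)
    gda_rows: list[tuple[str, str, float]] = []
    pass_scores = rng.uniform(GDA_CUTOFF + 1e-6, 1.0, size=spec.n_genes)
    for sym, score in zip(symbols, pass_scores):
        gda_rows.append((sym, "SYNTH0001", round(float(score), 6)))
    decoy_syms = [f"D{i + 1:06d}" for i in range(n_decoy_genes)]
    decoy_scores = rng.uniform(0.0, GDA_CUTOFF, size=n_decoy_genes)
    for sym, score in zip(decoy_syms, decoy_scores):
        gda_rows.append((sym, "SYNTH0001", round(float(score), 6)))

    # PPI table: planted edges pass the 0.4 cutoff; decoy edges do not.
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    m = len(edges)
    ppi_rows: list[tuple[str, str, float]] = []
    confs = rng.uniform(PPI_CUTOFF + 1e-6, 1.0, size=m)
    for (a, b), c in zip(edges, confs):
        ppi_rows.append((a, b, round(float(c), 6)))
    n_decoy_edges = round(DECOY_FRACTION * m)
    edge_set = set(edges)
    added = 0
    while added < n_decoy_edges:
        i, j = rng.integers(0, spec.n_genes, size=2)
        if i == j:
            continue
        a, b = sorted((symbols[int(i)], symbols[int(j)]))
        if (a, b) in edge_set:
            continue
        edge_set.add((a, b))
        ppi_rows.append((a, b, round(float(rng.uniform(0.0, PPI_CUTOFF)), 6)))
        added += 1

    manifest = {
        "generator": "planted-partition",
        "seed": int(spec.seed),
        "n_genes": spec.n_genes,
        "n_modules": spec.n_modules,
        "module_sizes": list(spec.module_sizes),
        "p_within": spec.p_within,
        "p_between": spec.p_between,
        "n_edges": m,
        "expected_edges": spec.expected_edges,
        "n_decoy_genes": n_decoy_genes,
        "n_decoy_edges": n_decoy_edges,
        "gda_cutoff": GDA_CUTOFF,
        "ppi_cutoff": PPI_CUTOFF,
        "membership": membership,
    }
    return SyntheticNetwork(
        network=g,
        assignments=assignments,
        gda_rows=gda_rows,
        ppi_rows=ppi_rows,
        manifest=manifest,
    )


def generate_drug(
    spec: SyntheticDrugSpec,
    net: nx.Graph,
    modules: list[ClusterAssignment],
) -> DrugTargetSet:
    """Sample a drug target set from the network nodes.

    ``round(specificity * n_targets)`` targets come from the focus
    module, drawn without replacement with probability proportional to
    ``degree ** hub_bias`` where degree is measured inside the module's
    induced subgraph (a module-focused drug targets the hubs *of that
    module*).  The remaining targets model nonspecific off-target
    leakage and are drawn uniformly from the rest of the network.  For
    an unfocused drug (specificity 0) the hub bias applies to the
    whole-network degree instead.
    """
    nodes = sorted(net.nodes)
    if spec.n_targets > len(nodes):
        raise ValueError(
            f"n_targets={spec.n_targets} exceeds available genes ({len(nodes)})"
        )
    rng = np.random.default_rng(spec.seed)
    by_module: dict[str, set[str]] = {}
    for a in modules:
        by_module.setdefault(a.cluster, set()).add(a.gene)

    n_focus = round(spec.specificity * spec.n_targets)
    if n_focus > 0:
        focus_pool = sorted(by_module.get(spec.focus_module, set()) & set(nodes))
        if n_focus > len(focus_pool):
            raise ValueError(
                f"n_targets at specificity {spec.specificity} needs {n_focus} "
                f"genes from module {spec.focus_module!r}, which has "
                f"{len(focus_pool)} in the network"
            )
    else:
        focus_pool = []

    def _draw(pool: list[str], k: int, degree_of) -> list[str]:
        if k == 0:
            return []
        if spec.hub_bias == 0 or degree_of is None:
            weights = np.full(len(pool), 1.0 / len(pool))
        else:
            deg = np.array([degree_of(v) for v in pool], dtype=float)
            weights = np.power(np.maximum(deg, 1e-12), spec.hub_bias)
            weights = weights / weights.sum()
        idx = rng.choice(len(pool), size=k, replace=False, p=weights)
        return [pool[int(i)] for i in idx]

    if n_focus > 0:
        module_graph = net.subgraph(focus_pool)
        targets = set(_draw(focus_pool, n_focus, module_graph.degree))
        rest_pool = [v for v in nodes if v not in targets]
        targets.update(_draw(rest_pool, spec.n_targets - n_focus, None))
    else:
        targets = set(_draw(nodes, spec.n_targets, net.degree))
    return DrugTargetSet(drug_id=spec.drug_id, targets=frozenset(targets))


def generate_drug_panel(
    net: nx.Graph,
    modules: list[ClusterAssignment],
    n_drugs: int = 39,
    n_targets: int = 30,
    seed: int = 0,
) -> list[DrugTargetSet]:
    """An unfocused reference panel of ``n_drugs`` drugs (uniform
    targeting, no hub bias), emulating an FDA-approved comparison set."""
    panel = []
    for i in range(n_drugs):
        spec = SyntheticDrugSpec(
            drug_id=f"REF{i + 1:03d}",
            n_targets=n_targets,
            seed=(int(seed) + i) % 2**31,
        )
        panel.append(generate_drug(spec, net, modules))
    return panel


def generate_compound_table(
    net: nx.Graph,
    n_compounds: int = 39,
    max_targets: int = 5,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Synthetic compound table: peak-area ratios from a Dirichlet
    draw (summing to 100%), each compound hitting 0..max_targets
    network nodes."""
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    ratios = 100.0 * rng.dirichlet(np.ones(n_compounds))
    records = []
    for i in range(n_compounds):
        k = int(rng.integers(0, max_targets + 1))
        targets = frozenset(
            nodes[int(j)] for j in rng.choice(len(nodes), size=k, replace=False)
        )
        records.append(
            CompoundRecord(
                compound=f"CPD{i + 1:03d}",
                peak_area_ratio=round(float(ratios[i]), 4),
                targets=targets,
            )
        )
    return records


def write_tables(
    synth: SyntheticNetwork,
    outdir: str | Path,
    drugs: list[DrugTargetSet] | None = None,
    compounds: list[CompoundRecord] | None = None,
) -> dict[str, Path]:
    """Write the generated data in the exact dialects the readers
    consume, plus the ground-truth JSON manifest.  Deterministic: the
    same inputs produce byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "gda.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tdisease_id\tscore\n")
        for gene, disease, score in synth.gda_rows:
            fh.write(f"{gene}\t{disease}\t{score:.6f}\n")
    paths["gda"] = p

    p = outdir / "ppi.tsv"
    with open(p, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, c in synth.ppi_rows:
            fh.write(f"{a}\t{b}\t{c:.6f}\n")
    paths["ppi"] = p

    p = outdir / "clusters.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tcluster\n")
        for a in synth.assignments:
            fh.write(f"{a.gene}\t{a.cluster}\n")
    paths["clusters"] = p

    if drugs is not None:
        p = outdir / "drug_targets.tsv"
        with open(p, "w") as fh:
            fh.write("drug_id\ttarget\n")
            for drug in sorted(drugs, key=lambda d: d.drug_id):
                for t in sorted(drug.targets):
                    fh.write(f"{drug.drug_id}\t{t}\n")
        paths["targets"] = p

    if compounds is not None:
        p = outdir / "compounds.csv"
        with open(p, "w") as fh:
            fh.write("compound,peak_area_ratio,targets\n")
            for c in compounds:
                fh.write(
                    f"{c.compound},{c.peak_area_ratio:.4f},"
                    f"{';'.join(sorted(c.targets))}\n"
                )
        paths["compounds"] = p

    p = outdir / "ground_truth.json"
    with open(p, "w") as fh:
        json.dump(synth.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = p
    return paths
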