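"""Functional subnetworks of pathological processes.

Disease genes are annotated to clustered functional processes (e.g.
"oxidative stress", "inflammation", "angiogenesis"; a gene may belong
to several).  Each process yields a subnetwork: the induced PPI
subgraph on that process's genes.  Interactions shared by too many
subnetworks carry no process-specific information, so any edge
occurring in more than ``max_occurrence`` subnetworks (default 4) is
pruned from all of them; the pruned edges are kept inspectable on the
side.  Isolated nodes are dropped, as in disease-network assembly.

Scoring a panel of agents against the subnetworks produces the
(agent x process) total-score matrix that drives process-level drug
positioning.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .assembly import DrugTargetSet, PPIEdge, _read_table, normalize_symbol
from .scoring import AttackScore, score_attack

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "SubnetworkSet",
    "load_clusters",
    "build_subnetworks",
    "score_subnetworks",
    "write_subnetworks",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ClusterAssignment:
    gene: str
    cluster: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))


@dataclass(frozen=True)
class SubnetworkSet:
    """Per-process subnetworks after shared-edge pruning.

    ``edge_occurrence`` maps each canonical edge to the number of
    subnetworks containing it *before* pruning; ``pruned_edges`` lists
    the edges removed for exceeding ``max_occurrence``.
    """

    subnetworks: dict[str, nx.Graph]
    edge_occurrence: dict[tuple[str, str], int]
    pruned_edges: list[tuple[str, str]]
    max_occurrence: int
    flagged_small: tuple[str, ...] = ()

    def __iter__(self):
        return iter(sorted(self.subnetworks.items()))


def load_clusters(path: str | Path) -> list[ClusterAssignment]:
    """Load a gene-to-cluster table (TSV columns ``gene``,
    ``cluster``); a gene may appear under several clusters."""
    df = _read_table(path, ["gene", "cluster"])
    return [
        ClusterAssignment(gene=row.gene, cluster=str(row.cluster))
        for row in df.itertuples(index=False)
    ]


def build_subnetworks(
    assignments: list[ClusterAssignment],
    edges: list[PPIEdge],
    max_occurrence: int = 4,
) -> SubnetworkSet:
    """Induce one subnetwork per cluster, then prune every edge that
    occurs in more than ``max_occurrence`` subnetworks.

    ``edges`` must already be cutoff-filtered.  Clusters whose
    subnetwork retains fewer than 3 nodes are kept but flagged, since
    their centralization statistics are degenerate.
    """
    if not assignments:
        raise ValueError("no cluster assignments given")
    members: dict[str, set[str]] = {}
    for a in assignments:
        members.setdefault(a.cluster, set()).add(a.gene)

    raw: dict[str, set[tuple[str, str]]] = {}
    occurrence: Counter[tuple[str, str]] = Counter()
    for cluster, genes in members.items():
        sub = {
            e.pair for e in edges if e.protein_a in genes and e.protein_b in genes
        }
        raw[cluster] = sub
        occurrence.update(sub)

    over_shared = {e for e, k in occurrence.items() if k > max_occurrence}
    if over_shared:
        logger.info(
            "pruning %d edge(s) shared by more than %d subnetworks",
            len(over_shared),
            max_occurrence,
        )

    subnetworks: dict[str, nx.Graph] = {}
    flagged: list[str] = []
    for cluster, sub in raw.items():
        g = nx.Graph()
        g.add_edges_from(sub - over_shared)  # isolates never enter
        subnetworks[cluster] = g
        if g.number_of_nodes() < 3:
            flagged.append(cluster)
            logger.warning(
                "subnetwork %r has %d node(s) after pruning; "
                "centralization will be degenerate",
                cluster,
                g.number_of_nodes(),
            )
    return SubnetworkSet(
        subnetworks=subnetworks,
        edge_occurrence=dict(occurrence),
        pruned_edges=sorted(over_shared),
        max_occurrence=max_occurrence,
        flagged_small=tuple(sorted(flagged)),
    )


def score_subnetworks(
    subnets: SubnetworkSet,
    drugs: list[DrugTargetSet],
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], AttackScore]]:
    """Score every (drug, subnetwork) pair through the full
    attack -> RI -> null -> z-score -> total pipeline.

    Returns the total-score matrix (rows = drugs, columns =
    subnetworks, both sorted; NaN marks undefined cells) and the
    per-cell :class:`AttackScore` details.  Each cell's null seed is
    derived from the master seed by cell index in row-major order of
    the sorted matrix, with a stride leaving room for the per-replicate
    counter, so cells are independent and individually reproducible.
    """
    if not drugs:
        raise ValueError("no drugs to score")
    drug_ids = sorted(d.drug_id for d in drugs)
    if len(set(drug_ids)) != len(drug_ids):
        raise ValueError("duplicate drug ids in panel")
    by_id = {d.drug_id: d for d in drugs}
    clusters = sorted(subnets.subnetworks)
    matrix = pd.DataFrame(index=drug_ids, columns=clusters, dtype=float)
    details: dict[tuple[str, str], AttackScore] = {}
    for i, drug_id in enumerate(drug_ids):
        for j, cluster in enumerate(clusters):
            cell_seed = (int(seed) + (i * len(clusters) + j) * n_reps) % _SEED_MOD
            net = subnets.subnetworks[cluster]
            if net.number_of_nodes() == 0:
                matrix.loc[drug_id, cluster] = math.nan
                continue
            try:
                score = score_attack(
                    net, by_id[drug_id], network_id=cluster, n_reps=n_reps, seed=cell_seed
                )
            except ValueError as exc:
                logger.warning(
                    "cell (%s, %s) undefined: %s", drug_id, cluster, exc
                )
                matrix.loc[drug_id, cluster] = math.nan
                continue
            details[(drug_id, cluster)] = score
            matrix.loc[drug_id, cluster] = score.total
    return matrix, details


def write_subnetworks(subnets: SubnetworkSet, outdir: str | Path) -> None:
    """Write one edge-list TSV per cluster plus a pruned-edges TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .assembly import write_edgelist

    for cluster, net in subnets:
        safe = cluster.replace("/", "_").replace(" ", "_")
        write_edgelist(net, outdir / f"subnetwork_{safe}.tsv")
    with open(outdir / "pruned_edges.tsv", "w") as fh:
        fh.write("protein1\tprotein2\n")
        for a, b in subnets.pruned_edges:
            fh.write(f"{a}\t{b}\n")
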