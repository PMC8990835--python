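"""End-to-end pipeline: assemble -> subnetworks -> attacks ->
permutation scores -> rankings -> compound scores.

A single :class:`RunConfig` (defaults equal the standard cutoffs:
GDA > 0.01, PPI confidence > 0.4, shared-edge limit 4, 100 null
replicates) drives the full analysis and writes a reproducible output
bundle: score matrices, per-cell z-scores with reasons for undefined
cells, percent-superior rankings against a designated reference panel,
compound process scores, and a JSON manifest recording versions, seeds
and conventions.  Identical config + master seed reproduces the bundle
byte for byte.

Seed plumbing: each stage receives ``master_seed + stage offset``; a
stage hands cell ``k`` the base seed ``stage_seed + k * n_reps`` and a
null's replicate ``i`` uses ``base + i`` (all reduced mod 2**31), so
every number in the bundle is reconstructible from the manifest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .assembly import (
    DrugTargetSet,
    build_network,
    load_drug_targets,
    load_gda,
    load_ppi,
    write_edgelist,
)
from .attack import METRICS
from .compounds import load_compounds, process_score_table
from .metrics import CONVENTIONS, topology_profile
from .scoring import rank_against_reference, score_attack
from .subnetworks import build_subnetworks, load_clusters, score_subnetworks, write_subnetworks

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_SEED_MOD = 2**31
#: Stage offsets keep the seed streams of different stages disjoint for
#: any n_reps <= 10000 and panel sizes used here.
_STAGE_OFFSET = {"disease": 0, "subnets": 50_000_000}


@dataclass(frozen=True)
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    gda: str
    ppi: str
    targets: str
    clusters: str | None = None
    compounds: str | None = None
    outdir: str = "robustnet_out"
    gda_cutoff: float = 0.01
    ppi_cutoff: float = 0.4
    max_edge_occurrence: int = 4
    n_reps: int = 100
    seed: int = 0
    #: drug ids forming the reference panel for percent-superior
    #: ranking; if empty, ids starting with "REF" are used.
    reference_drugs: tuple[str, ...] = field(default_factory=tuple)
    network_id: str = "disease"

    def as_dict(self) -> dict:
        return {
            "gda": self.gda,
            "ppi": self.ppi,
            "targets": self.targets,
            "clusters": self.clusters,
            "compounds": self.compounds,
            "outdir": self.outdir,
            "gda_cutoff": self.gda_cutoff,
            "ppi_cutoff": self.ppi_cutoff,
            "max_edge_occurrence": self.max_edge_occurrence,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "reference_drugs": list(self.reference_drugs),
            "network_id": self.network_id,
        }


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "reference_drugs" in raw and raw["reference_drugs"] is not None:
        raw["reference_drugs"] = tuple(raw["reference_drugs"])
    return RunConfig(**raw)


def _fmt(x: float) -> str:
    return "" if (isinstance(x, float) and math.isnan(x)) else f"{x:.10g}"


def _score_table(details: dict, drug_ids: list[str], columns: list[str]) -> pd.DataFrame:
    """Long-format per-cell table with z-scores, total, hit counts and
    a reason column for undefined cells (empty cells are never 0)."""
    rows = []
    for drug_id in drug_ids:
        for col in columns:
            score = details.get((drug_id, col))
            if score is None:
                rows.append(
                    {
                        "drug_id": drug_id,
                        "network_id": col,
                        "n_hits": "",
                        "z_ad": "",
                        "z_aspl": "",
                        "z_dc": "",
                        "z_cc": "",
                        "total": "",
                        "reason": "cell errored or empty subnetwork",
                    }
                )
                continue
            z = score.normalized
            undefined = [
                m
                for m, v in zip(METRICS, (z.z_ad, z.z_aspl, z.z_dc, z.z_cc))
                if math.isnan(v)
            ]
            reason = ""
            if math.isnan(score.total):
                reason = f"undefined z-score(s): {','.join(undefined)}"
            rows.append(
                {
                    "drug_id": drug_id,
                    "network_id": col,
                    "n_hits": score.n_hits,
                    "z_ad": _fmt(z.z_ad),
                    "z_aspl": _fmt(z.z_aspl),
                    "z_dc": _fmt(z.z_dc),
                    "z_cc": _fmt(z.z_cc),
                    "total": _fmt(score.total),
                    "reason": reason,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Returns the manifest dictionary (also written as
    ``manifest.json``).  Any stage failure raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # -- stage: assemble ------------------------------------------------
    try:
        genes = load_gda(config.gda, score_cutoff=config.gda_cutoff)
        edges = load_ppi(config.ppi, confidence_cutoff=config.ppi_cutoff)
        disease_net = build_network(genes, edges)
        drugs = load_drug_targets(config.targets)
    except Exception as exc:
        raise RuntimeError(f"stage 'assemble' failed: {exc}") from exc
    write_edgelist(disease_net, outdir / "disease_network.tsv")
    profile = topology_profile(disease_net)
    pd.DataFrame([profile.as_dict()]).to_csv(
        outdir / "disease_profile.tsv", sep="\t", index=False
    )

    drug_ids = [d.drug_id for d in drugs]

    # -- stage: disease-level attack scores -----------------------------
    disease_details = {}
    disease_seed = (config.seed + _STAGE_OFFSET["disease"]) % _SEED_MOD
    try:
        for i, drug in enumerate(drugs):
            cell_seed = (disease_seed + i * config.n_reps) % _SEED_MOD
            disease_details[(drug.drug_id, config.network_id)] = score_attack(
                disease_net,
                drug,
                network_id=config.network_id,
                n_reps=config.n_reps,
                seed=cell_seed,
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'attack' failed: {exc}") from exc
    disease_table = _score_table(disease_details, drug_ids, [config.network_id])
    disease_table.to_csv(outdir / "disease_scores.tsv", sep="\t", index=False)

    # -- stage: subnetworks ---------------------------------------------
    matrix = None
    subnet_details: dict = {}
    n_subnets = 0
    if config.clusters:
        try:
            assignments = load_clusters(config.clusters)
            subnets = build_subnetworks(
                assignments, edges, max_occurrence=config.max_edge_occurrence
            )
            n_subnets = len(subnets.subnetworks)
            write_subnetworks(subnets, outdir / "subnetworks")
            matrix, subnet_details = score_subnetworks(
                subnets,
                drugs,
                n_reps=config.n_reps,
                seed=(config.seed + _STAGE_OFFSET["subnets"]) % _SEED_MOD,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'subnets' failed: {exc}") from exc
        matrix.to_csv(outdir / "subnetwork_scores.tsv", sep="\t", na_rep="")
        _score_table(subnet_details, sorted(drug_ids), sorted(matrix.columns)).to_csv(
            outdir / "subnetwork_cells.tsv", sep="\t", index=False
        )

    # -- stage: rankings -------------------------------------------------
    reference = list(config.reference_drugs) or [
        d for d in drug_ids if d.startswith("REF")
    ]
    rank_rows = []
    if reference:
        ref_set = set(reference)
        candidates = [d for d in drug_ids if d not in ref_set]
        ref_disease = [
            disease_details[(r, config.network_id)].total
            for r in reference
            if not math.isnan(disease_details[(r, config.network_id)].total)
        ]
        for drug_id in candidates:
            total = disease_details[(drug_id, config.network_id)].total
            row = {"drug_id": drug_id, "network_id": config.network_id}
            if math.isnan(total) or not ref_disease:
                row["total"], row["pct_superior"], row["reason"] = "", "", "undefined"
            else:
                row["total"] = _fmt(total)
                row["pct_superior"] = _fmt(
                    rank_against_reference(total, ref_disease)
                )
                row["reason"] = ""
            rank_rows.append(row)
        if matrix is not None:
            for col in matrix.columns:
                ref_scores = [
                    matrix.loc[r, col]
                    for r in reference
                    if r in matrix.index and not math.isnan(matrix.loc[r, col])
                ]
                for drug_id in candidates:
                    total = matrix.loc[drug_id, col]
                    row = {"drug_id": drug_id, "network_id": col}
                    if math.isnan(total) or not ref_scores:
                        row["total"], row["pct_superior"], row["reason"] = (
                            "",
                            "",
                            "undefined",
                        )
                    else:
                        row["total"] = _fmt(total)
                        row["pct_superior"] = _fmt(
                            rank_against_reference(total, ref_scores)
                        )
                        row["reason"] = ""
                    rank_rows.append(row)
        pd.DataFrame(rank_rows).to_csv(outdir / "rankings.tsv", sep="\t", index=False)
    else:
        warnings.append("no reference panel designated; rankings skipped")

    # -- stage: compounds -------------------------------------------------
    if config.compounds and config.clusters:
        try:
            records = load_compounds(config.compounds)
            processes = {}
            for a in load_clusters(config.clusters):
                processes.setdefault(a.cluster, set()).add(a.gene)
            table = process_score_table(records, processes)
        except Exception as exc:
            raise RuntimeError(f"stage 'compounds' failed: {exc}") from exc
        table.to_csv(outdir / "compound_scores.tsv", sep="\t", index=False)

    excluded = {
        f"{drug_id}|{net_id}": score.null.n_excluded
        for (drug_id, net_id), score in {**disease_details, **subnet_details}.items()
        if any(score.null.n_excluded.values())
    }
    manifest = {
        "package": "robustnet",
        "version": __version__,
        "networkx": nx.__version__,
        "config": config.as_dict(),
        "conventions": CONVENTIONS,
        "connected_components_retained": "all non-isolated nodes (not restricted to the largest component)",
        "seed_scheme": (
            "stage_seed = master + stage_offset; cell_seed = stage_seed + "
            "cell_index * n_reps; replicate_seed = cell_seed + replicate_index "
            "(mod 2**31)"
        ),
        "stage_offsets": _STAGE_OFFSET,
        "disease_network": {
            "n_nodes": disease_net.number_of_nodes(),
            "n_edges": disease_net.number_of_edges(),
        },
        "n_drugs": len(drugs),
        "n_subnetworks": n_subnets,
        "null_excluded_draws": excluded,
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
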