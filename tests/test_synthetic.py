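"""Synthetic-data generator: determinism, planted structure, cutoff
straddling, drug sampling biases, and round-trips through the readers."""

import json
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from robustnet.assembly import build_network, load_gda, load_ppi
from robustnet.synthetic import (
    SyntheticDrugSpec,
    SyntheticSpec,
    default_spec,
    generate_compound_table,
    generate_disease_network,
    generate_drug,
    write_tables,
)


@pytest.fixture(scope="module")
def small_synth():
    spec = SyntheticSpec(n_genes=60, n_modules=3, p_within=0.35, p_between=0.03, seed=5)
    return spec, generate_disease_network(spec)


class TestSpecValidation:
    def test_p_ordering_enforced(self):
        with pytest.raises(ValueError, match="p_between"):
            SyntheticSpec(p_within=0.05, p_between=0.05)

    def test_module_sizes_must_sum(self):
        with pytest.raises(ValueError, match="module_sizes"):
            SyntheticSpec(n_genes=10, n_modules=2, module_sizes=(4, 4))

    def test_default_sizes_partition_genes(self):
        spec = SyntheticSpec(n_genes=10, n_modules=3)
        assert sum(spec.module_sizes) == 10 and len(spec.module_sizes) == 3


def test_default_spec_expected_edges_near_target():
    """At the default block probabilities a 600-gene, 6-module network
    expects ~4500 edges (the emulated disease-network scale)."""
    spec = default_spec()
    # n_within*p_within + n_between*p_between, evaluated independently
    within_pairs = 6 * (100 * 99 // 2)
    between_pairs = 600 * 599 // 2 - within_pairs
    expected = within_pairs * spec.p_within + between_pairs * spec.p_between
    assert expected == pytest.approx(spec.expected_edges)
    assert abs(expected - 4500) / 4500 < 0.10


def test_realized_edge_count_near_expectation(small_synth):
    spec, synth = small_synth
    m = synth.network.number_of_edges()
    # Poisson-binomial SD bound: sqrt(expected) is close enough here
    assert abs(m - spec.expected_edges) < 4 * math.sqrt(spec.expected_edges)


def test_same_seed_byte_identical_files(tmp_path):
    spec = SyntheticSpec(n_genes=40, n_modules=2, p_within=0.3, p_between=0.05, seed=11)
    for d in ("a", "b"):
        synth = generate_disease_network(spec)
        compounds = generate_compound_table(synth.network, n_compounds=10, seed=2)
        write_tables(synth, tmp_path / d, compounds=compounds)
    for name in ("gda.tsv", "ppi.tsv", "clusters.tsv", "compounds.csv", "ground_truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes()


def test_tables_round_trip_through_readers(tmp_path, small_synth):
    """Applying the standard cutoffs to the emitted tables
    reconstructs exactly the planted network (decoys filtered out)."""
    _, synth = small_synth
    write_tables(synth, tmp_path)
    genes = load_gda(tmp_path / "gda.tsv", score_cutoff=0.01)
    edges = load_ppi(tmp_path / "ppi.tsv", confidence_cutoff=0.4)
    net = build_network(genes, edges)
    planted = synth.network
    planted_connected = {v for v in planted if planted.degree(v) > 0}
    assert set(net.nodes) == planted_connected
    assert {tuple(sorted(e)) for e in net.edges} == {
        tuple(sorted(e)) for e in planted.edges
    }
    # decoys exist and straddle the cutoffs
    manifest = json.loads((tmp_path / "ground_truth.json").read_text())
    assert manifest["n_decoy_genes"] > 0 and manifest["n_decoy_edges"] > 0
    all_genes = load_gda(tmp_path / "gda.tsv", score_cutoff=0.0)
    assert len(all_genes) > len(genes)


class TestGenerateDrug:
    def test_full_specificity_stays_in_module(self, small_synth):
        _, synth = small_synth
        drug = generate_drug(
            SyntheticDrugSpec(
                drug_id="d",
                n_targets=10,
                focus_module="module_1",
                specificity=1.0,
                seed=3,
            ),
            synth.network,
            synth.assignments,
        )
        assert drug.targets <= synth.modules["module_1"]

    def test_specificity_requires_room(self, small_synth):
        _, synth = small_synth
        with pytest.raises(ValueError, match="module"):
            generate_drug(
                SyntheticDrugSpec(
                    drug_id="d",
                    n_targets=50,
                    focus_module="module_1",
                    specificity=1.0,
                    seed=3,
                ),
                synth.network,
                synth.assignments,
            )

    def test_unfocused_overlap_matches_hypergeometric(self, small_synth):
        """With specificity 0 the overlap between targets and any one
        module follows the hypergeometric law: the mean over 200 seeds
        must sit within Monte-Carlo error of N*K/n."""
        _, synth = small_synth
        net = synth.network
        module = synth.modules["module_1"] & set(net.nodes)
        n_pool, k_targets = net.number_of_nodes(), 12
        overlaps = []
        for seed in range(200):
            drug = generate_drug(
                SyntheticDrugSpec(drug_id="d", n_targets=k_targets, seed=seed),
                net,
                synth.assignments,
            )
            overlaps.append(len(drug.targets & module))
        rv = hypergeom(n_pool, len(module), k_targets)
        se = rv.std() / math.sqrt(len(overlaps))
        assert abs(np.mean(overlaps) - rv.mean()) < 4 * se

    def test_hub_bias_raises_mean_target_degree(self, small_synth):
        _, synth = small_synth
        net = synth.network
        mean_deg = 2 * net.number_of_edges() / net.number_of_nodes()
        biased_means = []
        for seed in range(30):
            drug = generate_drug(
                SyntheticDrugSpec(drug_id="d", n_targets=10, hub_bias=3.0, seed=seed),
                net,
                synth.assignments,
            )
            biased_means.append(np.mean([net.degree(t) for t in drug.targets]))
        assert np.mean(biased_means) > mean_deg

    def test_too_many_targets_rejected(self, small_synth):
        _, synth = small_synth
        with pytest.raises(ValueError, match="exceeds"):
            generate_drug(
                SyntheticDrugSpec(drug_id="d", n_targets=10_000, seed=0),
                synth.network,
                synth.assignments,
            )


def test_null_construction_has_no_modularity():
    """With p_within == p_between + epsilon -> planted labels carry no
    signal; modularity of the planted partition hovers near 0."""
    import networkx as nx

    spec = SyntheticSpec(
        n_genes=60, n_modules=3, p_within=0.1500001, p_between=0.15, seed=8
    )
    synth = generate_disease_network(spec)
    communities = [
        {g for g in members if g in synth.network}
        for members in synth.modules.values()
    ]
    q = nx.algorithms.community.modularity(synth.network, communities)
    assert abs(q) < 0.1
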