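"""Random-network null, z-score normalization, total score and
percent-superior ranking."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_aspl, oracle_average_degree, oracle_cc, oracle_dc
from robustnet.assembly import DrugTargetSet
from robustnet.scoring import (
    NormalizedRI,
    NullDistribution,
    normalized_ri,
    null_distribution,
    random_network,
    rank_against_reference,
    score_attack,
    total_score,
)


def drug(*targets: str) -> DrugTargetSet:
    return DrugTargetSet("test-drug", frozenset(targets))


class TestRandomNetwork:
    def test_preserves_nodes_and_edge_count(self):
        g = nx.gnm_random_graph(12, 20, seed=4)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        r = random_network(g, seed=9)
        assert set(r.nodes) == set(g.nodes)
        assert r.number_of_edges() == g.number_of_edges()
        assert nx.number_of_selfloops(r) == 0

    def test_forced_complete_graph(self, k4):
        for seed in (0, 1, 99):
            r = random_network(k4, seed=seed)
            assert r.number_of_edges() == 6  # only one graph with n=4, m=6

    def test_zero_edges(self):
        g = nx.empty_graph(5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        assert random_network(g, seed=3).number_of_edges() == 0

    def test_deterministic(self):
        g = nx.gnm_random_graph(15, 30, seed=8)
        a = random_network(g, seed=42)
        b = random_network(g, seed=42)
        assert set(a.edges) == set(b.edges)

    def test_uniformity_over_seeds(self):
        """Each of the C(4,2)=6 possible edges of a 4-node, 1-edge draw
        appears with roughly equal frequency."""
        g = nx.Graph()
        g.add_nodes_from("ABCD")
        g.add_edge("A", "B")
        counts: dict = {}
        n = 1200
        for seed in range(n):
            (e,) = random_network(g, seed=seed).edges
            counts[tuple(sorted(e))] = counts.get(tuple(sorted(e)), 0) + 1
        assert len(counts) == 6
        for c in counts.values():
            assert abs(c - n / 6) < 5 * math.sqrt(n * (1 / 6) * (5 / 6))


class TestNullDistribution:
    def test_no_hit_drug_gives_degenerate_null(self):
        g = nx.gnm_random_graph(10, 20, seed=1)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        null = null_distribution(g, drug("ZZZ"), n_reps=10, seed=0)
        for metric in ("ad", "aspl", "dc", "cc"):
            assert null.mean[metric] == 0.0
            assert null.sd[metric] == 0.0

    def test_bit_identical_rerun(self):
        g = nx.gnm_random_graph(10, 20, seed=1)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        d = drug("N1", "N2", "N3")
        a = null_distribution(g, d, n_reps=20, seed=7)
        b = null_distribution(g, d, n_reps=20, seed=7)
        for metric in ("ad", "aspl", "dc", "cc"):
            assert np.array_equal(a.values[metric], b.values[metric])
        assert a.n_excluded == b.n_excluded

    def test_n_reps_validation(self, k4):
        with pytest.raises(ValueError, match="n_reps"):
            null_distribution(k4, drug("A"), n_reps=1, seed=0)

    def test_matches_brute_force_reestimate(self):
        """Null means from 100 replicates agree with an independent
        10,000-replicate Monte-Carlo oracle (labeled G(n, m) draws via
        networkx, brute-force statistics) within 3 standard errors."""
        g = nx.gnm_random_graph(10, 20, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        targets = ("N0", "N3", "N7")
        null = null_distribution(g, drug(*targets), n_reps=100, seed=5)

        rng = np.random.default_rng(2026)
        draws: dict = {m: [] for m in ("ad", "aspl", "dc", "cc")}
        for _ in range(10_000):
            r = nx.gnm_random_graph(10, 20, seed=int(rng.integers(2**31)))
            r = nx.relabel_nodes(r, {i: f"N{i}" for i in r.nodes})
            before = (
                oracle_average_degree(r),
                oracle_aspl(r),
                oracle_dc(r),
                oracle_cc(r),
            )
            r.remove_nodes_from(targets)
            after = (
                oracle_average_degree(r),
                oracle_aspl(r),
                oracle_dc(r),
                oracle_cc(r),
            )
            for metric, b, a in zip(("ad", "aspl", "dc", "cc"), before, after):
                if not (math.isnan(b) or math.isnan(a)) and b != 0:
                    draws[metric].append((a - b) / b)
        for metric in ("ad", "aspl", "dc", "cc"):
            vec = np.asarray(draws[metric])
            se = vec.std(ddof=1) * math.sqrt(
                1 / len(vec) + 1 / len(null.values[metric])
            )
            assert abs(null.mean[metric] - vec.mean()) < 3 * se, metric


class TestNormalization:
    def test_zscore_arithmetic(self):
        null = NullDistribution(
            values={m: np.array([0.0, 0.2]) for m in ("ad", "aspl", "dc", "cc")},
            mean={"ad": 0.1, "aspl": 0.1, "dc": 0.1, "cc": 0.1},
            sd={"ad": 0.05, "aspl": 0.05, "dc": 0.05, "cc": 0.05},
            n_excluded={m: 0 for m in ("ad", "aspl", "dc", "cc")},
            n_reps=2,
            seed=0,
        )

        class FakeRI:
            def as_tuple(self):
                return (0.2, 0.1, 0.05, float("nan"))

        z = normalized_ri(FakeRI(), null)
        assert z.z_ad == pytest.approx(2.0)
        assert z.z_aspl == pytest.approx(0.0)
        assert z.z_dc == pytest.approx(-1.0)
        assert math.isnan(z.z_cc)

    def test_zero_sd_guarded(self):
        null = NullDistribution(
            values={m: np.zeros(5) for m in ("ad", "aspl", "dc", "cc")},
            mean={m: 0.0 for m in ("ad", "aspl", "dc", "cc")},
            sd={m: 0.0 for m in ("ad", "aspl", "dc", "cc")},
            n_excluded={m: 0 for m in ("ad", "aspl", "dc", "cc")},
            n_reps=5,
            seed=0,
        )

        class FakeRI:
            def as_tuple(self):
                return (0.1, 0.1, 0.1, 0.1)

        z = normalized_ri(FakeRI(), null)
        assert all(math.isnan(v) for v in z.as_tuple())


class TestTotalScore:
    def test_all_zero(self):
        assert total_score(NormalizedRI(0.0, 0.0, 0.0, 0.0)) == 0.0

    def test_undefined_component_gives_nan(self):
        nri = NormalizedRI(z_ad=1.0, z_aspl=float("nan"), z_dc=0.0, z_cc=0.0)
        assert math.isnan(total_score(nri))

    @settings(max_examples=50, deadline=None)
    @given(
        st.tuples(
            *[
                st.floats(-50, 50, allow_nan=False)
                for _ in range(4)
            ]
        ),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_linearity_with_signs(self, zs, delta):
        """Perturbing z_aspl by +d changes the total by +d; perturbing
        any of z_ad, z_dc, z_cc by +d changes it by -d."""
        z_ad, z_aspl, z_dc, z_cc = zs
        base = total_score(NormalizedRI(z_ad, z_aspl, z_dc, z_cc))
        up = total_score(NormalizedRI(z_ad, z_aspl + delta, z_dc, z_cc))
        assert up - base == pytest.approx(delta, abs=1e-9)
        for bumped in (
            NormalizedRI(z_ad + delta, z_aspl, z_dc, z_cc),
            NormalizedRI(z_ad, z_aspl, z_dc + delta, z_cc),
            NormalizedRI(z_ad, z_aspl, z_dc, z_cc + delta),
        ):
            assert total_score(bumped) - base == pytest.approx(-delta, abs=1e-9)


class TestRanking:
    @pytest.mark.parametrize(
        "score,refs,expected",
        [
            (5.0, [1.0, 2.0, 3.0], 100.0),
            (5.0, [6.0, 7.0], 0.0),
            (5.0, [5.0, 4.0], 50.0),  # strict inequality: the tie does not count
        ],
    )
    def test_percent_superior(self, score, refs, expected):
        assert rank_against_reference(score, refs) == expected

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            rank_against_reference(1.0, [])


def test_score_attack_deterministic():
    g = nx.gnm_random_graph(20, 50, seed=3)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    d = drug("N1", "N4", "N9")
    a = score_attack(g, d, n_reps=30, seed=17)
    b = score_attack(g, d, n_reps=30, seed=17)
    assert a.total == b.total
    assert a.normalized == b.normalized
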