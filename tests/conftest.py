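import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(["A", "B", "C", "D"])


@pytest.fixture
def path4() -> nx.Graph:
    g = nx.Graph()
    nx.add_path(g, ["A", "B", "C", "D"])
    return g


@pytest.fixture
def star4() -> nx.Graph:
    """Star K1,3 with center HUB."""
    g = nx.Graph()
    g.add_edges_from([("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3")])
    return g


@pytest.fixture
def gda_file(tmp_path: Path) -> Path:
    p = tmp_path / "gda.tsv"
    p.write_text(
        "gene\tdisease_id\tscore\n"
        "CFH\tC0242383\t0.70\n"
        "GENEX\tC0242383\t0.01\n"
        "vegfa \tC0242383\t0.35\n"
        "IL6\tC0242383\t0.009\n"
    )
    return p


@pytest.fixture
def ppi_file(tmp_path: Path) -> Path:
    p = tmp_path / "ppi.tsv"
    p.write_text(
        "protein1\tprotein2\tcombined_score\n"
        "9606.CFH\tVEGFA\t0.9\n"
        "VEGFA\tIL6\t0.41\n"
        "CFH\tCFH\t0.9\n"
        "IL6\tTNF\t0.2\n"
    )
    return p


def random_graphs(n_graphs: int, max_n: int = 15, seed: int = 20260923):
    """Seeded stream of small random graphs (possibly disconnected)."""
    import random

    rng = random.Random(seed)
    graphs = []
    for _ in range(n_graphs):
        n = rng.randint(3, max_n)
        p = rng.uniform(0.05, 0.8)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        graphs.append(g)
    return graphs
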