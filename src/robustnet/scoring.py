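"""Permutation-test normalization of robustness indices and the
composite attack score.

A raw robustness index depends on network size and density, so it is
normalized against a null distribution: random simple graphs with the
same node labels and edge count (uniform G(n, m)), each subjected to
the *same* drug attack.  The normalized RI is the z-score of the real
network's RI against the null mean and standard deviation.

The composite total score combines the four z-scores with signs chosen
so that larger always means a more destabilizing attack::

    total = z_aspl - z_ad - z_dc - z_cc

(a destabilizing attack lengthens paths and lowers degree and
centralization).  Agents are ranked by the fraction of a reference
panel they strictly beat.

Determinism: every replicate's graph is generated from a seed derived
from the master seed by a counter scheme (``master + replicate index``,
reduced mod 2**31), so a fixed master seed reproduces the null — and
every downstream score matrix — bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .assembly import DrugTargetSet
from .attack import METRICS, RobustnessIndex, attack, robustness_index
from .metrics import profile_from_edges, topology_profile

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "NormalizedRI",
    "AttackScore",
    "random_network",
    "null_distribution",
    "normalized_ri",
    "total_score",
    "rank_against_reference",
    "score_attack",
]

_SEED_MOD = 2**31


def _replicate_seed(master: int, index: int) -> int:
    return (int(master) + index) % _SEED_MOD


def _sample_gnm_edges(n: int, m: int, seed: int) -> np.ndarray:
    """Draw a uniform G(n, m) simple graph as an (m, 2) integer edge
    array over nodes ``0..n-1``: sample m of the C(n, 2) possible
    pairs without replacement and decode the linear pair indices."""
    total = n * (n - 1) // 2
    if m > total:
        raise ValueError(f"m={m} exceeds simple-graph capacity C({n},2)={total}")
    rng = np.random.default_rng(int(seed))
    k = rng.choice(total, size=m, replace=False)
    # pair index k lists (i, j), i < j, in row-major order of i
    offsets = np.concatenate(([0], np.cumsum(np.arange(n - 1, 0, -1))))
    i = np.searchsorted(offsets, k, side="right") - 1
    j = k - offsets[i] + i + 1
    return np.column_stack([i, j]).astype(np.int64)


def random_network(net: nx.Graph, seed: int) -> nx.Graph:
    """Uniform random simple graph with the same node label set and
    edge count as ``net`` (an Erdos-Renyi G(n, m) draw).

    Keeping the labels lets the identical drug attack be applied to
    every null replicate.  Deterministic given ``seed``.
    """
    labels = sorted(net.nodes)
    n, m = len(labels), net.number_of_edges()
    edges = _sample_gnm_edges(n, m, seed)
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[int(a)], labels[int(b)]) for a, b in edges)
    return g


@dataclass(frozen=True)
class NullDistribution:
    """Per-metric null RI vectors from random-network attacks.

    ``values[metric]`` holds the defined draws only; ``n_excluded``
    counts replicates whose RI was undefined for that metric
    (e.g. a fragmented random graph with a zero before-statistic).
    Means and SDs (sample SD, ddof=1) summarize each vector.
    """

    values: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    n_excluded: dict[str, int]
    n_reps: int
    seed: int


def null_distribution(
    net: nx.Graph,
    drug: DrugTargetSet,
    n_reps: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Build the null RI distribution: ``n_reps`` G(n, m) draws, each
    attacked by the same drug.

    Replicates with an undefined RI for some metric are excluded from
    that metric's vector and counted.  Raises if any metric retains
    fewer than 2 defined draws.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    labels = sorted(net.nodes)
    n, m = len(labels), net.number_of_edges()
    hit_idx = np.array(
        [i for i, v in enumerate(labels) if v in drug.targets], dtype=np.int64
    )
    if len(hit_idx) == n:
        raise ValueError(
            f"network annihilated: drug {drug.drug_id!r} targets all {n} nodes"
        )
    keep = np.ones(n, dtype=bool)
    keep[hit_idx] = False
    new_index = np.cumsum(keep) - 1  # survivor reindexing 0..n-h-1
    draws: dict[str, list[float]] = {metric: [] for metric in METRICS}
    excluded = {metric: 0 for metric in METRICS}
    for i in range(n_reps):
        edges = _sample_gnm_edges(n, m, _replicate_seed(seed, i))
        before = profile_from_edges(n, edges)
        surviving = edges[keep[edges[:, 0]] & keep[edges[:, 1]]]
        after = profile_from_edges(n - len(hit_idx), new_index[surviving])
        ri = robustness_index(before, after)
        for metric, value in zip(METRICS, ri.as_tuple()):
            if math.isnan(value):
                excluded[metric] += 1
            else:
                draws[metric].append(value)
    values: dict[str, np.ndarray] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for metric in METRICS:
        vec = np.asarray(draws[metric], dtype=float)
        if vec.size < 2:
            raise ValueError(
                f"null distribution for metric {metric!r} has "
                f"{vec.size} defined draw(s); need at least 2"
            )
        values[metric] = vec
        mean[metric] = float(vec.mean())
        sd[metric] = float(vec.std(ddof=1))
    return NullDistribution(
        values=values,
        mean=mean,
        sd=sd,
        n_excluded=excluded,
        n_reps=n_reps,
        seed=int(seed),
    )


@dataclass(frozen=True)
class NormalizedRI:
    """Z-scores of the real network's RIs against the null."""

    z_ad: float
    z_aspl: float
    z_dc: float
    z_cc: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.z_ad, self.z_aspl, self.z_dc, self.z_cc)


def _zscore(real: float, mean: float, sd: float, metric: str) -> float:
    if math.isnan(real):
        return math.nan
    if sd == 0.0:
        logger.warning(
            "normalized RI undefined for %s: null SD is 0 (division guarded)", metric
        )
        return math.nan
    return (real - mean) / sd


def normalized_ri(real: RobustnessIndex, null: NullDistribution) -> NormalizedRI:
    """Per-metric ``(RI_real - null mean) / null SD``; NaN where the
    null SD is 0 or the real RI is undefined."""
    z = {
        metric: _zscore(value, null.mean[metric], null.sd[metric], metric)
        for metric, value in zip(METRICS, real.as_tuple())
    }
    return NormalizedRI(z_ad=z["ad"], z_aspl=z["aspl"], z_dc=z["dc"], z_cc=z["cc"])


def total_score(nri: NormalizedRI) -> float:
    """Composite score ``z_aspl - z_ad - z_dc - z_cc``; NaN (with a
    warning naming the offending z-scores) if any component is
    undefined."""
    undefined = [
        metric
        for metric, z in zip(METRICS, (nri.z_ad, nri.z_aspl, nri.z_dc, nri.z_cc))
        if math.isnan(z)
    ]
    if undefined:
        logger.warning("total score undefined: z-score(s) %s undefined", undefined)
        return math.nan
    return nri.z_aspl - nri.z_ad - nri.z_dc - nri.z_cc


def rank_against_reference(score: float, reference_scores: list[float]) -> float:
    """Percentage of reference scores strictly below ``score``
    ("superior to X% of the panel")."""
    if not reference_scores:
        raise ValueError("reference score list is empty")
    below = sum(1 for r in reference_scores if r < score)
    return 100.0 * below / len(reference_scores)


@dataclass(frozen=True)
class AttackScore:
    """Scored attack of one agent on one network."""

    drug_id: str
    network_id: str
    normalized: NormalizedRI
    total: float
    real_ri: RobustnessIndex
    null: NullDistribution
    n_hits: int


def score_attack(
    net: nx.Graph,
    drug: DrugTargetSet,
    network_id: str = "network",
    n_reps: int = 100,
    seed: int = 0,
) -> AttackScore:
    """Full per-pair pipeline: attack the real network, build the null,
    normalize, and combine into the total score."""
    before = topology_profile(net)
    result = attack(net, drug)
    after = topology_profile(result.attacked_network)
    ri = robustness_index(before, after)
    null = null_distribution(net, drug, n_reps=n_reps, seed=seed)
    nri = normalized_ri(ri, null)
    return AttackScore(
        drug_id=drug.drug_id,
        network_id=network_id,
        normalized=nri,
        total=total_score(nri),
        real_ri=ri,
        null=null,
        n_hits=result.n_hits,
    )
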