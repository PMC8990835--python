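"""Multi-target drug attacks by node deletion, and the per-metric
robustness index.

A drug attack deletes every network node that appears in the drug's
target set, together with all incident edges.  Targets absent from the
network are ignored (but counted); survivors that become isolated are
retained, so the post-attack node count reflects deletion only and the
before/after topologies compare the same residual node set.

The robustness index (RI) of each statistic is its relative change,
``(after - before) / before``.  A before-value of 0 (or an undefined
before/after value) makes the corresponding RI undefined; undefined
values are carried as NaN and never coerced to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .assembly import DrugTargetSet
from .metrics import TopologyProfile, topology_profile

logger = logging.getLogger(__name__)

__all__ = ["AttackResult", "RobustnessIndex", "attack", "robustness_index", "attack_ri"]

METRICS = ("ad", "aspl", "dc", "cc")


@dataclass(frozen=True)
class AttackResult:
    attacked_network: nx.Graph
    hit_targets: frozenset[str]
    n_hits: int


@dataclass(frozen=True)
class RobustnessIndex:
    """Per-metric relative topology change of one attack.

    Each ``ri_*`` is ``(after - before)/before`` for that statistic;
    NaN flags an undefined value (before-metric 0 or undefined).
    """

    ri_ad: float
    ri_aspl: float
    ri_dc: float
    ri_cc: float
    before: TopologyProfile
    after: TopologyProfile

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.ri_ad, self.ri_aspl, self.ri_dc, self.ri_cc)


def attack(net: nx.Graph, drug: DrugTargetSet) -> AttackResult:
    """Delete the drug's targets (and incident edges) from the network.

    Deterministic; survivors are kept even if isolated.  Raises if the
    attack would remove every node.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot attack an empty network")
    hits = frozenset(drug.targets) & set(net.nodes)
    if len(hits) == net.number_of_nodes():
        raise ValueError(
            f"network annihilated: drug {drug.drug_id!r} targets all "
            f"{net.number_of_nodes()} nodes"
        )
    attacked = net.copy()
    attacked.remove_nodes_from(hits)
    return AttackResult(attacked_network=attacked, hit_targets=hits, n_hits=len(hits))


def _relative_change(before: float, after: float) -> float:
    if math.isnan(before) or math.isnan(after):
        return math.nan
    if before == 0.0:
        if after == 0.0:
            return 0.0  # identity case: no change is a zero relative change
        logger.warning("robustness index undefined: before-attack metric is 0")
        return math.nan
    return (after - before) / before


def robustness_index(before: TopologyProfile, after: TopologyProfile) -> RobustnessIndex:
    """Per-metric relative change between the pre- and post-attack
    profiles (NaN-propagating)."""
    return RobustnessIndex(
        ri_ad=_relative_change(before.ad, after.ad),
        ri_aspl=_relative_change(before.aspl, after.aspl),
        ri_dc=_relative_change(before.dc, after.dc),
        ri_cc=_relative_change(before.cc, after.cc),
        before=before,
        after=after,
    )


def attack_ri(net: nx.Graph, drug: DrugTargetSet) -> tuple[AttackResult, RobustnessIndex]:
    """Convenience: attack a network and compute the robustness index
    in one call (one profile per side)."""
    before = topology_profile(net)
    result = attack(net, drug)
    after = topology_profile(result.attacked_network)
    return result, robustness_index(before, after)
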