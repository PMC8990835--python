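"""Disease-network assembly from tabular exports.

Reads gene-disease association (GDA) tables, PPI edge tables and
drug-target tables in the column dialects of the common public
databases, applies score cutoffs, and builds simple undirected
:class:`networkx.Graph` disease networks.

Conventions
-----------
* Symbols are normalized: uppercased, whitespace-stripped, and a
  leading NCBI taxon prefix (e.g. ``9606.``) is removed so STRING-style
  protein identifiers match plain gene symbols.
* Cutoffs are strict: a record passes only if its score is strictly
  greater than the cutoff.
* Edges are stored with lexicographically ordered endpoints; self-pairs
  are dropped, duplicates collapse.
* Nodes with no passing interaction are dropped at construction, so the
  node count of a disease network can be below the input gene count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDiseaseRecord",
    "PPIEdge",
    "DrugTargetSet",
    "InputFormatError",
    "normalize_symbol",
    "load_gda",
    "load_ppi",
    "load_drug_targets",
    "build_network",
    "write_edgelist",
    "read_edgelist",
]

_TAXON_PREFIX = re.compile(r"^\d+\.")


class InputFormatError(ValueError):
    """A table is missing columns or contains an unparseable row."""


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a gene/protein identifier.

    Uppercases, strips surrounding whitespace, and removes a leading
    numeric species prefix (``9606.ENSP...`` -> ``ENSP...``).
    """
    s = str(symbol).strip()
    s = _TAXON_PREFIX.sub("", s)
    return s.upper()


@dataclass(frozen=True)
class GeneDiseaseRecord:
    gene: str
    disease_id: str
    gda_score: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not 0.0 <= self.gda_score <= 1.0:
            raise ValueError(f"gda_score {self.gda_score} outside [0, 1]")


@dataclass(frozen=True)
class PPIEdge:
    """Undirected protein-protein interaction with a confidence score.

    Endpoints are stored lexicographically ordered so that equal edges
    compare (and hash) equal regardless of input orientation.
    """

    protein_a: str
    protein_b: str
    confidence: float

    def __post_init__(self) -> None:
        a, b = sorted((self.protein_a, self.protein_b))
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not a valid edge")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class DrugTargetSet:
    """A drug (or herb, or formula) and its potential target symbols."""

    drug_id: str
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", frozenset(normalize_symbol(t) for t in self.targets)
        )
        if not self.targets:
            raise ValueError(f"drug {self.drug_id!r} has an empty target set")


def _read_table(path: str | Path, required: Iterable[str], sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _parse_score(raw: str, path: str | Path, row: int, column: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise InputFormatError(
            f"{path}: row {row}: unparseable {column} value {raw!r}"
        ) from None


def load_gda(path: str | Path, score_cutoff: float = 0.01) -> set[str]:
    """Load a gene-disease association table, keeping genes with
    score strictly greater than ``score_cutoff``.

    Expects tab-separated columns ``gene``, ``disease_id``, ``score``.
    Returns the deduplicated set of normalized gene symbols.
    """
    if not 0.0 <= score_cutoff <= 1.0:
        raise ValueError("score_cutoff must lie in [0, 1]")
    df = _read_table(path, ["gene", "score"])
    genes: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        score = _parse_score(row.score, path, idx, "score")
        if score > score_cutoff:
            genes.add(normalize_symbol(row.gene))
    return genes


def load_ppi(
    path: str | Path,
    confidence_cutoff: float = 0.4,
    score_scale: float | None = None,
) -> list[PPIEdge]:
    """Load a PPI edge table, keeping edges with confidence strictly
    greater than ``confidence_cutoff``.

    Expects tab-separated columns ``protein1``, ``protein2``,
    ``combined_score``. STRING exports use either a 0-1 probability or
    a 0-1000 integer score; if any value exceeds 1 the whole column is
    divided by 1000 (override by passing ``score_scale`` explicitly).

    Self-pairs are dropped with a warning; duplicate edges collapse,
    keeping the highest confidence seen.
    """
    df = _read_table(path, ["protein1", "protein2", "combined_score"])
    scores = [
        _parse_score(v, path, i, "combined_score")
        for i, v in enumerate(df["combined_score"], start=2)
    ]
    if score_scale is None:
        score_scale = 1000.0 if any(s > 1.0 for s in scores) else 1.0
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for (_, row), score in zip(df.iterrows(), scores):
        a = normalize_symbol(row["protein1"])
        b = normalize_symbol(row["protein2"])
        conf = score / score_scale
        if a == b:
            n_self += 1
            continue
        if conf > confidence_cutoff:
            pair = (a, b) if a < b else (b, a)
            if conf > best.get(pair, -1.0):
                best[pair] = conf
    if n_self:
        logger.warning("%s: dropped %d self-interaction row(s)", path, n_self)
    return [PPIEdge(a, b, c) for (a, b), c in sorted(best.items())]


def load_drug_targets(path: str | Path) -> list[DrugTargetSet]:
    """Load a long-format drug-target table (columns ``drug_id``,
    ``target``; one row per pair) into a list of target sets, ordered
    by drug id."""
    df = _read_table(path, ["drug_id", "target"])
    grouped: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(str(row.drug_id), set()).add(normalize_symbol(row.target))
    return [DrugTargetSet(d, frozenset(t)) for d, t in sorted(grouped.items())]


def build_network(genes: Iterable[str], edges: Iterable[PPIEdge]) -> nx.Graph:
    """Build the disease network: the induced subgraph of the passing
    PPI edges on the disease gene set.

    Only edges with both endpoints in ``genes`` enter the network, and
    genes left with no interaction are dropped — which is why, e.g., a
    685-gene input can yield a 636-node network.

    Raises
    ------
    ValueError
        If no edge connects two disease genes ("no connected disease
        genes").
    """
    gene_set = {normalize_symbol(g) for g in genes}
    g = nx.Graph()
    for e in edges:
        if e.protein_a in gene_set and e.protein_b in gene_set:
            g.add_edge(e.protein_a, e.protein_b, confidence=e.confidence)
    if g.number_of_edges() == 0:
        raise ValueError("no connected disease genes: resulting network is empty")
    return g


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a deterministic two-column TSV edge list
    (canonically ordered endpoints, sorted rows)."""
    rows = sorted(tuple(sorted(e)) for e in net.edges())
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list written by :func:`write_edgelist`."""
    df = _read_table(path, ["protein1", "protein2"])
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = normalize_symbol(row.protein1), normalize_symbol(row.protein2)
        if a == b:
            logger.warning("%s: dropped self-loop %s", path, a)
            continue
        g.add_edge(a, b)
    return g
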