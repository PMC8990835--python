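"""Content-weighted aggregation of compound peak-area ratios.

The chromatographic peak area ratio of a compound is a proxy for its
relative content in a multi-compound preparation.  Summing the ratios
of the compounds that hit a target ranks targets by content-weighted
intensity; summing over the targets of a pathological process ranks
processes.  At the process level a compound hitting several of the
process's targets is counted once — the ratio is a mass proxy and
double-counting would exceed total content — while per-target sums are
deliberately not deduplicated (the same compound legitimately
contributes to each of its targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assembly import InputFormatError, normalize_symbol

__all__ = [
    "CompoundRecord",
    "ProcessScore",
    "load_compounds",
    "target_peak_sum",
    "process_peak_sum",
    "process_score_table",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One identified compound: name, peak area ratio (percent, >= 0),
    and the symbols it targets (possibly empty)."""

    compound: str
    peak_area_ratio: float
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.peak_area_ratio < 0:
            raise ValueError(
                f"{self.compound}: peak_area_ratio must be >= 0, "
                f"got {self.peak_area_ratio}"
            )
        object.__setattr__(
            self, "targets", frozenset(normalize_symbol(t) for t in self.targets)
        )


@dataclass(frozen=True)
class ProcessScore:
    """Peak-area sums for one pathological process."""

    process: str
    target_sums: dict[str, float]
    process_sum: float


def load_compounds(path: str | Path) -> list[CompoundRecord]:
    """Load a compound CSV with columns ``compound``,
    ``peak_area_ratio``, ``targets`` (semicolon-separated symbols;
    empty allowed)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("compound", "peak_area_ratio", "targets") if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required column(s) {missing}")
    records: list[CompoundRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ratio = float(row.peak_area_ratio)
        except (TypeError, ValueError):
            raise InputFormatError(
                f"{path}: row {idx}: unparseable peak_area_ratio "
                f"{row.peak_area_ratio!r}"
            ) from None
        raw = str(row.targets)
        targets = frozenset(t for t in (s.strip() for s in raw.split(";")) if t)
        records.append(CompoundRecord(str(row.compound), ratio, targets))
    return records


def target_peak_sum(compounds: list[CompoundRecord], target: str) -> float:
    """Sum of peak area ratios over compounds whose target set contains
    ``target`` (0 if none does)."""
    t = normalize_symbol(target)
    return sum(c.peak_area_ratio for c in compounds if t in c.targets)


def process_peak_sum(
    compounds: list[CompoundRecord],
    process_targets: set[str],
    process: str = "process",
) -> ProcessScore:
    """Aggregate compound content over one process's target set.

    ``process_sum`` counts each compound once even if it hits several
    of the process's targets; ``target_sums`` are the per-target
    (un-deduplicated) sums.
    """
    if not process_targets:
        raise ValueError(f"process {process!r} has an empty target set")
    targets = {normalize_symbol(t) for t in process_targets}
    target_sums = {t: target_peak_sum(compounds, t) for t in sorted(targets)}
    process_sum = sum(
        c.peak_area_ratio for c in compounds if c.targets & targets
    )
    return ProcessScore(process=process, target_sums=target_sums, process_sum=process_sum)


def process_score_table(
    compounds: list[CompoundRecord],
    processes: dict[str, set[str]],
) -> pd.DataFrame:
    """Tidy (process, target, target_sum, process_sum) table for a
    mapping of process label -> target set."""
    rows = []
    for process in sorted(processes):
        score = process_peak_sum(compounds, processes[process], process=process)
        for target, s in score.target_sums.items():
            rows.append(
                {
                    "process": process,
                    "target": target,
                    "target_sum": s,
                    "process_sum": score.process_sum,
                }
            )
    return pd.DataFrame(rows, columns=["process", "target", "target_sum", "process_sum"])
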