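"""Corpus-level quality key numbers.

Aggregates per-compound verification results the way a journal-corpus audit
table does: entry count, average molecular weight, mean Δδ_C, the count and
percentage of compounds with at least one gross deviation, and optional
rows restricted to compounds containing a named substructure.  Δδ_C is
averaged per compound first and then unweighted across compounds (declared
in the output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem_core import Molecule, molecular_weight, substructure_match
from .hose import DEFAULT_MIN_CONTRIBUTORS, HoseIndex
from .verification import ClassificationThresholds, PeakList, verify

__all__ = ["CorpusStats", "corpus_keynumbers"]


@dataclass
class CorpusStats:
    entry_count: int
    excluded_count: int
    average_mw: Optional[float]
    mean_delta: Optional[float]  # corpus mean Δδ_C, ppm
    gross_count: int
    gross_percent: Optional[float]
    restricted: list[tuple[str, int, Optional[float]]] = field(default_factory=list)
    aggregation: str = "per-compound mean, unweighted across compounds"

    def to_tsv(self) -> str:
        lines = [
            f"Entries\t{self.entry_count}",
            f"Excluded (structure errors)\t{self.excluded_count}",
            f"Average MWT (amu)\t{_fmt(self.average_mw)}",
            f"DeltaDeltaC (ppm)\t{_fmt(self.mean_delta)}",
            f"DeltaDeltaC > gross\t{self.gross_count}/"
            f"{_fmt(self.gross_percent)}%",
        ]
        for name, count, delta in self.restricted:
            lines.append(f"DeltaDeltaC (ppm) {name}\t{_fmt(delta)}\t(n={count})")
        lines.append(f"# aggregation: {self.aggregation}")
        return "\n".join(lines)


def _fmt(x: Optional[float]) -> str:
    return "n/a" if x is None else f"{x:.2f}"


def corpus_keynumbers(
    entries: Sequence[tuple[Molecule, PeakList]],
    index: HoseIndex,
    thresholds: Optional[ClassificationThresholds] = None,
    queries: Sequence[tuple[str, Molecule]] = (),
    min_contributors: int = DEFAULT_MIN_CONTRIBUTORS,
    mode: str = "authors",
) -> CorpusStats:
    """Verify every entry and aggregate the Table-style key numbers."""
    t = thresholds or ClassificationThresholds()
    per_compound: list[float] = []
    weights: list[float] = []
    gross = 0
    excluded = 0
    kept: list[tuple[Molecule, Optional[float], bool]] = []
    for m, p in entries:
        report = verify(m, p, index, thresholds=t, mode=mode,
                        min_contributors=min_contributors)
        if report.status == "structure-error":
            excluded += 1
            continue
        kept.append((m, report.delta_mean, report.gross_error))
        if report.delta_mean is not None:
            per_compound.append(report.delta_mean)
        if report.gross_error:
            gross += 1

    n = len(kept)
    mean_delta = sum(per_compound) / len(per_compound) if per_compound else None
    mws = [molecular_weight(m) for m, _, _ in kept]
    average_mw = sum(mws) / n if n else None
    gross_percent = 100.0 * gross / n if n else None

    restricted: list[tuple[str, int, Optional[float]]] = []
    for name, query in queries:
        deltas = [
            d for m, d, _ in kept
            if d is not None and substructure_match(m, query, all_mappings=False)[0]
        ]
        restricted.append(
            (name, len(deltas), sum(deltas) / len(deltas) if deltas else None)
        )

    return CorpusStats(
        entry_count=n,
        excluded_count=excluded,
        average_mw=average_mw,
        mean_delta=mean_delta,
        gross_count=gross,
        gross_percent=gross_percent,
        restricted=restricted,
    )
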