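"""Identical-structure search, identical-pattern search and dereplication.

Two independent checks catch "same data twice" publications: an identity
search on the canonical structure identifier, and a spectral-pattern search
that flags reference records whose full shift multiset coincides with the
query peak list within a tolerance.  Dereplication ranks a whole candidate
collection of predicted spectra against an (assigned or unassigned) peak
list by the mean absolute difference under the optimal signal pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem_core import Molecule, canonical_identifier
from .hose import ReferenceRecord
from .verification import PeakList

__all__ = [
    "SpectralPattern",
    "PatternMatch",
    "DereplicationHit",
    "find_identical_structures",
    "find_identical_patterns",
    "dereplicate",
]

DEFAULT_BIN_RESOLUTION = 0.1  # ppm, pattern-hash prefilter
DEFAULT_PATTERN_TOLERANCE = 0.1  # ppm
DEFAULT_REPORTING_THRESHOLD = 10.0  # ppm, dereplication hits above are flagged


@dataclass(frozen=True)
class SpectralPattern:
    shifts: tuple[float, ...]  # sorted ascending
    record_id: Optional[int] = None
    resolution: float = DEFAULT_BIN_RESOLUTION

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("binning resolution must be > 0")
        object.__setattr__(self, "shifts", tuple(sorted(self.shifts)))

    @property
    def bins(self) -> tuple[int, ...]:
        return tuple(int(round(s / self.resolution)) for s in self.shifts)


@dataclass
class PatternMatch:
    record_id: int
    max_difference: float  # largest pairwise |difference| under sorted pairing
    same_data_different_structure: bool = False


@dataclass
class DereplicationHit:
    record_id: object
    score: float  # mean |difference| under optimal pairing, ppm
    rank: int = 0
    above_threshold: bool = False


def find_identical_structures(
    m: Molecule, db: Sequence[ReferenceRecord]
) -> list[int]:
    """Record ids of database entries with the same canonical identifier."""
    query = canonical_identifier(m).text
    return [
        i for i, rec in enumerate(db) if canonical_identifier(rec.molecule).text == query
    ]


def _pattern_of(record: ReferenceRecord) -> tuple[float, ...]:
    """Distinct per-class shifts of a record (symmetry-equivalent carbons
    contribute one value, as they produce one signal)."""
    from .chem_core import equivalence_classes

    partition = equivalence_classes(record.molecule)
    return tuple(sorted(record.shifts[atoms[0]] for atoms in partition.classes))


def find_identical_patterns(
    p: PeakList,
    db: Sequence[ReferenceRecord],
    tolerance: float = DEFAULT_PATTERN_TOLERANCE,
    query_structure: Optional[Molecule] = None,
) -> list[PatternMatch]:
    """Database records whose shift multiset matches the peak list pairwise
    within ``tolerance``; equal cardinality is required.  When the query
    structure is supplied, matches with a *different* canonical identifier
    are flagged as the same-data-twice error class."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    query = tuple(sorted(p.shifts))
    query_id = (
        canonical_identifier(query_structure).text if query_structure is not None else None
    )
    matches = []
    for i, rec in enumerate(db):
        pattern = _pattern_of(rec)
        if len(pattern) != len(query):
            continue
        diffs = [abs(a - b) for a, b in zip(query, pattern)]
        worst = max(diffs) if diffs else 0.0
        if worst <= tolerance + 1e-9:
            different = (
                query_id is not None
                and canonical_identifier(rec.molecule).text != query_id
            )
            matches.append(
                PatternMatch(
                    record_id=i,
                    max_difference=worst,
                    same_data_different_structure=different,
                )
            )
    return matches


UNPAIRED_PENALTY = 10.0  # ppm; signals/classes the pairing cannot explain


def _pairing_score(query: Sequence[float], candidate: Sequence[float]) -> float:
    """Mean |difference| under the optimal pairing of the two shift lists.

    With unequal cardinality, min(n, m) signals are paired and every
    leftover position enters the mean at a 10 ppm penalty — otherwise a
    candidate with a single carbon environment would trivially "explain"
    any query through its one paired signal.
    """
    if not query or not candidate:
        return float("inf")
    cost = np.abs(np.subtract.outer(np.asarray(query), np.asarray(candidate)))
    rows, cols = linear_sum_assignment(cost)
    leftover = max(len(query), len(candidate)) - len(rows)
    total = float(cost[rows, cols].sum()) + UNPAIRED_PENALTY * leftover
    return total / (len(rows) + leftover)


def dereplicate(
    p: PeakList,
    predicted_index: Sequence[tuple[object, Sequence[float]]],
    reporting_threshold: float = DEFAULT_REPORTING_THRESHOLD,
) -> list[DereplicationHit]:
    """Rank candidate predicted spectra against the peak list.

    ``predicted_index`` holds ``(record id, predicted shift multiset)``
    pairs, typically built by running predict_shifts over a structure
    collection.  Hits are sorted by ascending score; ties break on the
    textual order of the record id.
    """
    query = sorted(p.shifts)
    hits = [
        DereplicationHit(
            record_id=rec_id,
            score=_pairing_score(query, sorted(shifts)),
            above_threshold=False,
        )
        for rec_id, shifts in predicted_index
    ]
    hits.sort(key=lambda h: (h.score, str(h.record_id)))
    for rank, h in enumerate(hits, start=1):
        h.rank = rank
        h.above_threshold = h.score > reporting_threshold
    return hits
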