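"""Peak-list checks, signal assignment and structure/data coincidence.

The referee compares a structure proposal against its reported carbon
shifts: every experimental signal is paired with a symmetry-equivalence
class of the structure (authors' assignment where given, optimal matching
otherwise), the shift of each class is predicted from the reference
database, and the per-class deviations are classified green / yellow / red.
The mean absolute deviation over the predicted classes
(:math:`\\Delta\\delta_C`) summarizes the compound; any deviation beyond
the gross-error threshold (default 20 ppm) raises the gross-error flag that
typically marks typos, misassignments or wrong structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem_core import (
    EquivalencePartition,
    Finding,
    Molecule,
    StructureCheckResult,
    check_structure,
    equivalence_classes,
)
from .hose import (
    DEFAULT_MIN_CONTRIBUTORS,
    HoseIndex,
    ShiftPrediction,
    predict_shifts,
)

__all__ = [
    "Signal",
    "PeakList",
    "ClassificationThresholds",
    "AtomDeviation",
    "Assignment",
    "VerificationReport",
    "read_peaklists",
    "write_peaklists",
    "check_peaklist",
    "assign_signals",
    "classify_deviation",
    "verify",
]

SHIFT_SANITY_WINDOW = (-20.0, 250.0)
_EQUAL_SHIFT_TOL = 0.005  # ppm; "the same value" for symmetry checks


@dataclass
class Signal:
    shift: float
    atoms: tuple[int, ...] = ()  # authors' assignment; empty = unassigned
    xgroup: Optional[str] = None  # exchangeable-assignment tag
    intensity: Optional[float] = None

    @property
    def assigned(self) -> bool:
        return bool(self.atoms)


@dataclass
class PeakList:
    signals: list[Signal] = field(default_factory=list)
    key: str = ""  # cross-reference key to the SDF record

    @property
    def shifts(self) -> list[float]:
        return [s.shift for s in self.signals]


@dataclass
class ClassificationThresholds:
    green_below: float = 5.0
    red_above: float = 10.0
    gross_error: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.green_below <= self.red_above < self.gross_error):
            raise ValueError(
                "thresholds must satisfy 0 < green_below <= red_above < gross_error"
            )


def classify_deviation(delta: float, t: ClassificationThresholds) -> str:
    """Green below 5 ppm, yellow between 5 and 10 ppm (inclusive at both
    boundaries), red above 10 ppm (defaults)."""
    d = abs(delta)
    if d < t.green_below:
        return "green"
    if d <= t.red_above:
        return "yellow"
    return "red"


# ---------------------------------------------------------------------------
# peak-list file format: one compound per block
#   #compound<TAB>KEY
#   shift<TAB>comma-separated atoms (empty = unassigned)<TAB>xgroup tag
# ---------------------------------------------------------------------------


def write_peaklists(peaklists: Sequence[PeakList]) -> str:
    out = []
    for p in peaklists:
        out.append(f"#compound\t{p.key}")
        for s in p.signals:
            atoms = ",".join(str(a) for a in s.atoms)
            out.append(f"{s.shift:.2f}\t{atoms}\t{s.xgroup or ''}")
        out.append("")
    return "\n".join(out)


def read_peaklists(text: str) -> list[PeakList]:
    peaklists: list[PeakList] = []
    current: Optional[PeakList] = None
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#compound"):
            parts = line.split("\t")
            current = PeakList(key=parts[1].strip() if len(parts) > 1 else "")
            peaklists.append(current)
            continue
        if line.startswith("#"):
            continue
        if current is None:
            current = PeakList()
            peaklists.append(current)
        fields = line.split("\t")
        shift = float(fields[0])
        atoms: tuple[int, ...] = ()
        if len(fields) > 1 and fields[1].strip():
            atoms = tuple(int(tok) for tok in fields[1].split(",") if tok.strip())
        xgroup = fields[2].strip() or None if len(fields) > 2 else None
        current.signals.append(Signal(shift=shift, atoms=atoms, xgroup=xgroup))
    return peaklists


# ---------------------------------------------------------------------------
# formal peak-list checks
# ---------------------------------------------------------------------------


def check_peaklist(m: Molecule, p: PeakList) -> list[Finding]:
    findings: list[Finding] = []
    partition = equivalence_classes(m)

    lo, hi = SHIFT_SANITY_WINDOW
    for i, s in enumerate(p.signals):
        if not np.isfinite(s.shift) or not (lo <= s.shift <= hi):
            findings.append(
                Finding(
                    "warning",
                    "shift-window",
                    f"signal {i + 1} at {s.shift} ppm is outside the "
                    f"{lo}..{hi} ppm sanity window",
                )
            )

    if len(p.signals) != partition.n_classes:
        findings.append(
            Finding(
                "warning",
                "signal-count",
                f"{len(p.signals)} signals reported but the structure has "
                f"{partition.n_classes} carbon equivalence classes",
            )
        )

    carbon_set = set(m.carbons())
    class_shifts: dict[int, list[float]] = {}
    for i, s in enumerate(p.signals):
        for a in s.atoms:
            if a not in carbon_set:
                findings.append(
                    Finding(
                        "error",
                        "assignment-atom",
                        f"signal {i + 1} ({s.shift} ppm) is assigned to atom {a}, "
                        "which is not a carbon of the structure",
                        (a,),
                    )
                )
            else:
                class_shifts.setdefault(partition.class_of[a], []).append(s.shift)

    for cid, shifts in sorted(class_shifts.items()):
        if max(shifts) - min(shifts) > _EQUAL_SHIFT_TOL:
            atoms = partition.atoms_of(cid)
            findings.append(
                Finding(
                    "error",
                    "symmetry",
                    f"symmetry-equivalent carbons {list(atoms)} carry unequal "
                    f"shifts {sorted(set(shifts))}; equivalent positions must "
                    "resonate at one value",
                    atoms,
                )
            )

    group_counts: dict[str, int] = {}
    for s in p.signals:
        if s.xgroup:
            group_counts[s.xgroup] = group_counts.get(s.xgroup, 0) + 1
    for tag, count in sorted(group_counts.items()):
        if count < 2:
            findings.append(
                Finding(
                    "warning",
                    "xgroup",
                    f"exchangeable group {tag!r} tags only one signal",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


@dataclass
class Assignment:
    pairs: list[tuple[int, int, str]]  # (class id, signal index, provenance)
    unmatched_classes: list[int] = field(default_factory=list)
    unmatched_signals: list[int] = field(default_factory=list)
    findings: list[Finding] = field(default_factory=list)

    def signal_for(self, class_id: int) -> Optional[int]:
        for cid, sig, _ in self.pairs:
            if cid == class_id:
                return sig
        return None

    def total_abs_delta(self, predictions: Sequence[ShiftPrediction], p: PeakList) -> float:
        by_id = {pr.class_id: pr for pr in predictions}
        total = 0.0
        for cid, sig, _ in self.pairs:
            pr = by_id.get(cid)
            if pr is not None and pr.predicted:
                total += abs(p.signals[sig].shift - pr.shift)
        return total


def _match_free(
    predictions: Sequence[ShiftPrediction],
    signals: Sequence[tuple[int, float]],
    classes: Sequence[int],
    provenance: str,
) -> tuple[list[tuple[int, int, str]], list[int], list[int]]:
    """Minimum-total-|delta| bipartite matching (rectangular allowed)."""
    if not signals or not classes:
        return [], list(classes), [i for i, _ in signals]
    by_id = {pr.class_id: pr for pr in predictions}
    cost = np.array(
        [[abs(shift - by_id[cid].shift) for cid in classes] for _, shift in signals]
    )
    rows, cols = linear_sum_assignment(cost)
    pairs = [(classes[c], signals[r][0], provenance) for r, c in zip(rows, cols)]
    used_classes = {classes[c] for c in cols}
    used_signals = {signals[r][0] for r in rows}
    return (
        pairs,
        [c for c in classes if c not in used_classes],
        [i for i, _ in signals if i not in used_signals],
    )


def assign_signals(
    predictions: Sequence[ShiftPrediction],
    p: PeakList,
    partition: Optional[EquivalencePartition] = None,
    mode: str = "authors",
) -> Assignment:
    """Pair experimental signals with carbon equivalence classes.

    ``mode="authors"`` honors the published assignment: author-assigned
    signals keep their class, exchangeable-tagged signals are permuted only
    within their tag group (exhaustively — groups are small), and the
    remaining unassigned signals are matched to the remaining predicted
    classes by minimum-total-|delta| bipartite matching.  ``mode="auto"``
    discards the published assignment and matches everything optimally.
    """
    if mode not in ("authors", "auto"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    findings: list[Finding] = []
    by_id = {pr.class_id: pr for pr in predictions}
    predicted_ids = [pr.class_id for pr in predictions if pr.predicted]

    class_of: dict[int, int] = {}
    if partition is not None:
        class_of = partition.class_of
    else:
        for pr in predictions:
            for a in pr.atoms:
                class_of[a] = pr.class_id

    pairs: list[tuple[int, int, str]] = []
    taken_classes: set[int] = set()
    taken_signals: set[int] = set()

    if mode == "authors":
        # authors' fixed assignments
        for i, s in enumerate(p.signals):
            if not s.assigned or s.xgroup:
                continue
            cids = {class_of.get(a) for a in s.atoms if class_of.get(a) is not None}
            if not cids:
                continue
            if len(cids) > 1:
                findings.append(
                    Finding(
                        "warning",
                        "assignment-span",
                        f"signal {i + 1} ({s.shift} ppm) spans several "
                        "equivalence classes; first class used",
                    )
                )
            cid = sorted(cids)[0]
            if cid in taken_classes:
                continue
            pairs.append((cid, i, "authors"))
            taken_classes.add(cid)
            taken_signals.add(i)

        # exchangeable groups: permute signals within the tag group over the
        # classes the group was assigned to
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(p.signals):
            if s.xgroup and s.assigned:
                groups.setdefault(s.xgroup, []).append(i)
        for tag in sorted(groups):
            members = groups[tag]
            cids = []
            for i in members:
                c = {class_of.get(a) for a in p.signals[i].atoms} - {None}
                cids.append(sorted(c)[0] if c else None)
            slots = [c for c in cids if c is not None and c not in taken_classes]
            usable = [
                i for i in members if i not in taken_signals
            ][: len(slots)]
            best = None
            for perm in itertools.permutations(usable):
                cost = 0.0
                for cid, i in zip(slots, perm):
                    pr = by_id.get(cid)
                    if pr is not None and pr.predicted:
                        cost += abs(p.signals[i].shift - pr.shift)
                if best is None or cost < best[0]:
                    best = (cost, perm)
            if best is not None:
                for cid, i in zip(slots, best[1]):
                    pairs.append((cid, i, "exchangeable"))
                    taken_classes.add(cid)
                    taken_signals.add(i)

    free_signals = [
        (i, s.shift) for i, s in enumerate(p.signals) if i not in taken_signals
    ]
    free_classes = [cid for cid in predicted_ids if cid not in taken_classes]
    auto_pairs, unmatched_classes, unmatched_signals = _match_free(
        predictions, free_signals, free_classes, "auto"
    )
    pairs.extend(auto_pairs)

    unpredicted = [pr.class_id for pr in predictions if not pr.predicted]
    unmatched_classes = sorted(
        set(unmatched_classes)
        | (set(unpredicted) - taken_classes)
    )
    if unmatched_signals:
        findings.append(
            Finding(
                "warning",
                "unmatched-signals",
                f"{len(unmatched_signals)} signal(s) could not be paired with "
                "an equivalence class",
            )
        )
    pairs.sort(key=lambda t: t[0])
    return Assignment(
        pairs=pairs,
        unmatched_classes=unmatched_classes,
        unmatched_signals=sorted(unmatched_signals),
        findings=findings,
    )


# ---------------------------------------------------------------------------
# the coincidence report
# ---------------------------------------------------------------------------


@dataclass
class AtomDeviation:
    class_id: int
    atoms: tuple[int, ...]
    experimental: Optional[float]
    predicted: Optional[float]
    delta: Optional[float]  # experimental - predicted, ppm
    color: str  # green | yellow | red | unpredicted | unmatched
    n: int = 0
    std: float = 0.0
    sphere: int = 0
    provenance: str = ""  # authors | exchangeable | auto | ""


@dataclass
class VerificationReport:
    structure_findings: list[Finding]
    peaklist_findings: list[Finding]
    predictions: list[ShiftPrediction]
    assignment: Optional[Assignment]
    deviations: list[AtomDeviation]
    delta_mean: Optional[float]  # mean |delta| over matched, predicted classes
    delta_max: Optional[float]
    gross_error: bool
    thresholds: ClassificationThresholds
    assignment_mode: str
    status: str  # "ok" | "structure-error" | "insufficient reference data"

    @property
    def findings(self) -> list[Finding]:
        out = list(self.structure_findings) + list(self.peaklist_findings)
        if self.assignment is not None:
            out.extend(self.assignment.findings)
        return out

    def color_counts(self) -> dict[str, int]:
        counts = {"green": 0, "yellow": 0, "red": 0, "unpredicted": 0, "unmatched": 0}
        for d in self.deviations:
            counts[d.color] += 1
        return counts

    @property
    def all_green(self) -> bool:
        return all(d.color == "green" for d in self.deviations if d.delta is not None) and any(
            d.delta is not None for d in self.deviations
        )


def verify(
    m: Molecule,
    p: PeakList,
    index: HoseIndex,
    thresholds: Optional[ClassificationThresholds] = None,
    mode: str = "authors",
    min_contributors: int = DEFAULT_MIN_CONTRIBUTORS,
    exclude_records: Iterable[int] = (),
) -> VerificationReport:
    """Full structure/data coincidence check for one compound."""
    t = thresholds or ClassificationThresholds()
    structure_result = check_structure(m)
    if not structure_result.ok:
        return VerificationReport(
            structure_findings=structure_result.findings,
            peaklist_findings=[],
            predictions=[],
            assignment=None,
            deviations=[],
            delta_mean=None,
            delta_max=None,
            gross_error=False,
            thresholds=t,
            assignment_mode=mode,
            status="structure-error",
        )

    peak_findings = check_peaklist(m, p)
    partition = equivalence_classes(m)
    predictions = predict_shifts(
        m, index, min_contributors=min_contributors, exclude_records=exclude_records
    )

    if all(not pr.predicted for pr in predictions):
        return VerificationReport(
            structure_findings=structure_result.findings,
            peaklist_findings=peak_findings,
            predictions=predictions,
            assignment=None,
            deviations=[
                AtomDeviation(pr.class_id, pr.atoms, None, None, None, "unpredicted")
                for pr in predictions
            ],
            delta_mean=None,
            delta_max=None,
            gross_error=False,
            thresholds=t,
            assignment_mode=mode,
            status="insufficient reference data",
        )

    assignment = assign_signals(predictions, p, partition=partition, mode=mode)

    deviations: list[AtomDeviation] = []
    abs_deltas: list[float] = []
    signal_of = {cid: (sig, prov) for cid, sig, prov in assignment.pairs}
    for pr in predictions:
        if not pr.predicted:
            deviations.append(
                AtomDeviation(pr.class_id, pr.atoms, None, None, None, "unpredicted")
            )
            continue
        hit = signal_of.get(pr.class_id)
        if hit is None:
            # predicted but no signal available (incomplete peak list);
            # surfaced via unmatched_classes, excluded from the mean
            deviations.append(
                AtomDeviation(
                    pr.class_id,
                    pr.atoms,
                    None,
                    pr.shift,
                    None,
                    "unmatched",
                    n=pr.n,
                    std=pr.std,
                    sphere=pr.sphere,
                )
            )
            continue
        sig, prov = hit
        exp = p.signals[sig].shift
        delta = exp - pr.shift
        deviations.append(
            AtomDeviation(
                pr.class_id,
                pr.atoms,
                exp,
                pr.shift,
                delta,
                classify_deviation(delta, t),
                n=pr.n,
                std=pr.std,
                sphere=pr.sphere,
                provenance=prov,
            )
        )
        abs_deltas.append(abs(delta))

    delta_mean = sum(abs_deltas) / len(abs_deltas) if abs_deltas else None
    delta_max = max(abs_deltas) if abs_deltas else None
    gross = any(d > t.gross_error for d in abs_deltas)
    return VerificationReport(
        structure_findings=structure_result.findings,
        peaklist_findings=peak_findings,
        predictions=predictions,
        assignment=assignment,
        deviations=deviations,
        delta_mean=delta_mean,
        delta_max=delta_max,
        gross_error=gross,
        thresholds=t,
        assignment_mode=mode,
        status="ok",
    )
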