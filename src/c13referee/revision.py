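"""Automatic structure revision.

When the coincidence report localizes large deviations on particular
positions, a structure generator enumerates alternatives that modify the
topology only at those positions (and their direct neighbors), predicts the
spectrum of every alternative and ranks all candidates — the original
proposal included — by the mean absolute deviation against the experimental
peak list.  A better-ranked alternative is a concrete revision proposal.

Move kinds (formula-preserving by default):

* ``relocate``      — detach a pendant substituent and reattach it elsewhere
* ``swap``          — exchange two pendant substituents between their sites
* ``shift-dbond``   — slide a non-aromatic double bond to an adjacent bond
* ``hetero-swap``   — exchange a heteroatom with a neighboring position
* ``add-remove``    — add/remove a small substituent (opt-in; changes the
  molecular formula)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from . import chem_core
from .chem_core import Bond, Molecule, allowed_valences, check_structure
from .hose import DEFAULT_MIN_CONTRIBUTORS, HoseIndex, predict_shifts
from .verification import (
    Assignment,
    PeakList,
    VerificationReport,
    assign_signals,
)

__all__ = [
    "RevisionMove",
    "CandidateStructure",
    "RankedCandidates",
    "flag_positions",
    "generate_candidates",
    "rank_candidates",
]

DEFAULT_BUDGET = 5000
MAX_BRANCH_ATOMS = 4  # pendant branches larger than this are not moved

_COLOR_ORDER = {"green": 0, "yellow": 1, "red": 2}


@dataclass(frozen=True)
class RevisionMove:
    kind: str
    sites: tuple[int, ...]
    detail: str = ""


@dataclass
class CandidateStructure:
    molecule: Molecule
    moves: tuple[RevisionMove, ...] = ()
    identifier: str = ""
    score: Optional[float] = None  # mean |delta| vs experimental, ppm
    rank: int = 0
    is_input: bool = False
    flagged: str = ""  # e.g. "no-predictable-carbons"


@dataclass
class RankedCandidates:
    candidates: list[CandidateStructure]
    input_rank: int
    truncated: bool = False

    @property
    def revision_recommended(self) -> bool:
        return self.input_rank > 1


# ---------------------------------------------------------------------------
# flagged positions
# ---------------------------------------------------------------------------


def flag_positions(
    report: VerificationReport,
    level: str = "red",
    include_neighbors: bool = True,
    molecule: Optional[Molecule] = None,
) -> set[int]:
    """Atoms of every class whose deviation color is at or above ``level``
    (red, or yellow-and-red with ``level="yellow"``); direct neighbors are
    included by default so bonds at the flagged position may be rewired.
    Predicted classes left without an experimental counterpart (color
    ``unmatched``) are positions the data does not explain and are flagged
    at every level."""
    if level not in _COLOR_ORDER:
        raise ValueError(f"unknown color level {level!r}")
    threshold = _COLOR_ORDER[level]
    flagged: set[int] = set()
    for d in report.deviations:
        if d.color == "unmatched" or (
            d.color in _COLOR_ORDER and _COLOR_ORDER[d.color] >= threshold
        ):
            flagged.update(d.atoms)
    # experimental signals left unexplained mean the proposal collapses too
    # many positions by symmetry: the multi-atom classes are the suspects
    if report.assignment is not None and report.assignment.unmatched_signals:
        for d in report.deviations:
            if len(d.atoms) >= 2:
                flagged.update(d.atoms)
    if include_neighbors and molecule is not None:
        for a in list(flagged):
            flagged.update(molecule.neighbors(a))
    return flagged


# ---------------------------------------------------------------------------
# graph-editing helpers
# ---------------------------------------------------------------------------


def _recompute_implicit_h(m: Molecule) -> bool:
    """Refill implicit hydrogens from the valence table; False if an atom
    cannot reach an allowed valence."""
    for i in range(1, m.n_atoms + 1):
        a = m.atom(i)
        allowed = allowed_valences(a.element, a.charge)
        bsum = m.bond_order_sum(i)
        if allowed is None:
            a.implicit_h = 0
            continue
        fitting = [v for v in allowed if v >= bsum]
        if not fitting:
            return False
        a.implicit_h = min(fitting) - bsum
    return True


def _edited(m: Molecule, bonds: list[Bond]) -> Optional[Molecule]:
    """Build a normalized molecule from edited atoms/bonds; None when the
    edit is chemically invalid."""
    try:
        cand = Molecule(
            atoms=[replace(a, coords=None) for a in m.atoms],
            bonds=[replace(b, aromatic=False) for b in bonds],
            name=m.name,
        )
    except ValueError:
        return None
    if not _recompute_implicit_h(cand):
        return None
    try:
        normalized = chem_core.from_rdkit(cand.to_rdkit(), name=m.name)
    except Exception:
        return None
    if not check_structure(normalized).ok:
        return None
    return normalized


def _pendant_branches(m: Molecule) -> list[tuple[int, int, int, frozenset[int]]]:
    """(site, first branch atom, bond order, branch atoms) for every
    non-ring bond whose far side is a small pendant branch."""
    ring = m.ring_bonds()
    branches = []
    for b in m.bonds:
        if frozenset((b.a1, b.a2)) in ring:
            continue
        for site, first in ((b.a1, b.a2), (b.a2, b.a1)):
            # collect the component on the `first` side with the bond removed
            seen = {site, first}
            stack = [first]
            comp = {first}
            while stack:
                v = stack.pop()
                for w in m.neighbors(v):
                    if w not in seen:
                        seen.add(w)
                        comp.add(w)
                        stack.append(w)
            if site in comp:
                continue
            if len(comp) <= MAX_BRANCH_ATOMS and len(comp) < m.n_atoms - 1:
                branches.append((site, first, b.order, frozenset(comp)))
    return branches


def _free_valence(m: Molecule, idx: int) -> int:
    a = m.atom(idx)
    return a.implicit_h


def _remove_bond(bonds: list[Bond], a1: int, a2: int) -> list[Bond]:
    key = frozenset((a1, a2))
    return [b for b in bonds if frozenset((b.a1, b.a2)) != key]


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------


def generate_candidates(
    m: Molecule,
    flagged: Iterable[int],
    budget: int = DEFAULT_BUDGET,
    allow_add_remove: bool = False,
) -> tuple[list[CandidateStructure], bool]:
    """Enumerate alternative structures touching the flagged positions.

    Returns the candidate list (input structure first, no duplicate
    canonical identifiers) and a truncation flag.  An empty flagged set
    yields the input structure alone.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    flagged = set(flagged)
    input_id = chem_core.canonical_identifier(m).text
    candidates = [
        CandidateStructure(molecule=m, identifier=input_id, is_input=True)
    ]
    if not flagged:
        return candidates, False
    sites = set(flagged)
    for a in flagged:
        sites.update(m.neighbors(a))

    seen = {input_id}
    truncated = False

    def admit(mol: Optional[Molecule], move: RevisionMove) -> bool:
        nonlocal truncated
        if mol is None:
            return True
        ident = chem_core.canonical_identifier(mol).text
        if ident in seen:
            return True
        if len(candidates) >= budget:
            truncated = True
            return False
        seen.add(ident)
        candidates.append(
            CandidateStructure(molecule=mol, moves=(move,), identifier=ident)
        )
        return True

    branches = _pendant_branches(m)
    touching = [br for br in branches if br[0] in sites or (br[3] & sites)]

    # 1. relocate: move a pendant branch to any atom with free valence,
    #    provided the move touches the flagged neighborhood on either end
    for site, first, order, comp in branches:
        for target in range(1, m.n_atoms + 1):
            if target == site or target in comp:
                continue
            if not (site in sites or target in sites or (comp & sites)):
                continue
            if m.atom(target).element == "H":
                continue
            if _free_valence(m, target) < order:
                continue
            bonds = _remove_bond(m.bonds, site, first)
            bonds.append(Bond(target, first, order=order))
            move = RevisionMove("relocate", (site, target), f"branch@{first}")
            if not admit(_edited(m, bonds), move):
                return candidates, truncated

    # 2. swap: exchange two pendant branches (bond orders travel with the
    #    branch); covers e.g. hydroxy/keto position exchanges
    for i, (s1, f1, o1, c1) in enumerate(branches):
        for s2, f2, o2, c2 in branches[i + 1 :]:
            if s1 == s2 or f1 in c2 or f2 in c1 or (c1 & c2):
                continue
            if s1 not in sites and s2 not in sites:
                continue
            if s2 in c1 or s1 in c2:
                continue
            if _free_valence(m, s1) + o1 < o2 or _free_valence(m, s2) + o2 < o1:
                continue
            bonds = _remove_bond(_remove_bond(m.bonds, s1, f1), s2, f2)
            bonds.append(Bond(s1, f2, order=o2))
            bonds.append(Bond(s2, f1, order=o1))
            move = RevisionMove("swap", (s1, s2), f"{f1}<->{f2}")
            if not admit(_edited(m, bonds), move):
                return candidates, truncated

    # 3. shift a non-aromatic double bond to an adjacent bond
    for b in m.bonds:
        if b.order != 2 or b.aromatic:
            continue
        if b.a1 not in sites and b.a2 not in sites:
            continue
        for anchor, far in ((b.a1, b.a2), (b.a2, b.a1)):
            for nb in m.bonds_of(anchor):
                c = nb.other(anchor)
                if c == far or nb.order != 1 or nb.aromatic:
                    continue
                bonds = []
                for ob in m.bonds:
                    nb_key = frozenset((ob.a1, ob.a2))
                    if nb_key == frozenset((b.a1, b.a2)):
                        bonds.append(replace(ob, order=1))
                    elif nb_key == frozenset((anchor, c)):
                        bonds.append(replace(ob, order=2))
                    else:
                        bonds.append(replace(ob))
                move = RevisionMove(
                    "shift-dbond", (far, anchor, c), f"{far}={anchor}->{anchor}={c}"
                )
                if not admit(_edited(m, bonds), move):
                    return candidates, truncated

    # 4. exchange a heteroatom with a neighboring position
    for b in m.bonds:
        e1 = m.atom(b.a1).element
        e2 = m.atom(b.a2).element
        if e1 == e2 or "H" in (e1, e2):
            continue
        if e1 == "C" and e2 == "C":
            continue
        if b.a1 not in sites and b.a2 not in sites:
            continue
        swapped = m.copy()
        swapped.atom(b.a1).element = e2
        swapped.atom(b.a2).element = e1
        swapped.atom(b.a1).coords = None
        swapped.atom(b.a2).coords = None
        move = RevisionMove("hetero-swap", (b.a1, b.a2), f"{e1}<->{e2}")
        if not admit(_edited(swapped, swapped.bonds), move):
            return candidates, truncated

    # 5. add/remove a small substituent (changes the formula; opt-in)
    if allow_add_remove:
        for site, first, order, comp in touching:
            bonds = _remove_bond(m.bonds, site, first)
            keep = sorted(set(range(1, m.n_atoms + 1)) - comp)
            remap = {old: new for new, old in enumerate(keep, start=1)}
            atoms = [replace(m.atoms[old - 1], coords=None) for old in keep]
            kept_bonds = [
                Bond(remap[bb.a1], remap[bb.a2], order=bb.order)
                for bb in bonds
                if bb.a1 in remap and bb.a2 in remap
            ]
            try:
                stripped = Molecule(atoms=atoms, bonds=kept_bonds, name=m.name)
            except ValueError:
                continue
            if not _recompute_implicit_h(stripped):
                continue
            move = RevisionMove("add-remove", (site,), f"-branch@{first}")
            if not admit(_edited(stripped, stripped.bonds), move):
                return candidates, truncated
        for elem in ("O",):
            for site in sorted(sites):
                if m.atom(site).element == "H" or _free_valence(m, site) < 1:
                    continue
                atoms = [replace(a, coords=None) for a in m.atoms]
                atoms.append(chem_core.Atom(element=elem))
                bonds = [replace(bb) for bb in m.bonds]
                bonds.append(Bond(site, len(atoms), order=1))
                try:
                    grown = Molecule(atoms=atoms, bonds=bonds, name=m.name)
                except ValueError:
                    continue
                if not _recompute_implicit_h(grown):
                    continue
                move = RevisionMove("add-remove", (site,), f"+{elem}H")
                if not admit(_edited(grown, grown.bonds), move):
                    return candidates, truncated

    # paired relocations among flagged sites (reachable two-step revisions)
    singles = [c for c in candidates if len(c.moves) == 1 and c.moves[0].kind == "relocate"]
    for c in singles:
        base = c.molecule
        for site, first, order, comp in _pendant_branches(base):
            if site not in flagged and not (comp & flagged):
                continue
            for target in sorted(flagged):
                if target == site or target in comp:
                    continue
                if target > base.n_atoms or base.atom(target).element == "H":
                    continue
                if _free_valence(base, target) < order:
                    continue
                bonds = _remove_bond(base.bonds, site, first)
                bonds.append(Bond(target, first, order=order))
                move = RevisionMove(
                    "relocate", (site, target), f"paired-after:{c.moves[0].detail}"
                )
                cand = _edited(base, bonds)
                if cand is None:
                    continue
                ident = chem_core.canonical_identifier(cand).text
                if ident in seen:
                    continue
                if len(candidates) >= budget:
                    return candidates, True
                seen.add(ident)
                candidates.append(
                    CandidateStructure(
                        molecule=cand, moves=c.moves + (move,), identifier=ident
                    )
                )
    return candidates, truncated


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


UNMATCHED_PENALTY = 10.0  # ppm; a signal or class the pairing cannot explain


def rank_candidates(
    candidates: Sequence[CandidateStructure],
    p: PeakList,
    index: HoseIndex,
    min_contributors: int = DEFAULT_MIN_CONTRIBUTORS,
    exclude_records: Iterable[int] = (),
    truncated: bool = False,
    unmatched_penalty: float = UNMATCHED_PENALTY,
) -> RankedCandidates:
    """Predict, optimally assign and score every candidate; ascending sort
    by score with canonical-identifier tie-break; dense ranks from 1.

    The score is the mean |delta| over the optimal class/signal pairing;
    every experimental signal or predicted class that the pairing cannot
    explain (cardinality mismatch, unpredictable environment) enters the
    mean at ``unmatched_penalty`` — otherwise a wrong proposal with fewer
    distinct positions than the data would absorb the spectrum unpunished.
    """
    if not candidates:
        raise ValueError("candidate collection must not be empty")
    exclude = tuple(exclude_records)
    scored = []
    for cand in candidates:
        predictions = predict_shifts(
            cand.molecule,
            index,
            min_contributors=min_contributors,
            exclude_records=exclude,
        )
        predicted = [pr for pr in predictions if pr.predicted]
        if not predicted:
            cand.score = float("inf")
            cand.flagged = "no-predictable-carbons"
            scored.append(cand)
            continue
        assignment = assign_signals(predictions, p, mode="auto")
        by_id = {pr.class_id: pr for pr in predicted}
        deltas = [
            abs(p.signals[sig].shift - by_id[cid].shift)
            for cid, sig, _ in assignment.pairs
            if cid in by_id
        ]
        n_unexplained = len(assignment.unmatched_signals) + (
            len(predictions) - len(assignment.pairs)
        )
        total = sum(deltas) + unmatched_penalty * n_unexplained
        count = len(deltas) + n_unexplained
        cand.score = total / count if count else float("inf")
        scored.append(cand)
    scored.sort(key=lambda c: (c.score, c.identifier))
    input_rank = 0
    for rank, cand in enumerate(scored, start=1):
        cand.rank = rank
        if cand.is_input:
            input_rank = rank
    return RankedCandidates(
        candidates=scored, input_rank=input_rank, truncated=truncated
    )
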