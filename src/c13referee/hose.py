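"""HOSE-code generation, reference-database indexing and shift prediction.

A HOSE code (Hierarchically Ordered Spherical Environment) is a canonical
string describing an atom's bonded environment sphere by sphere: sphere 1
holds the direct neighbors, sphere 2 their neighbors, and so on.  Carbons
with identical codes sit in (near-)identical environments and are expected
to resonate at (near-)identical chemical shifts, which turns a database of
assigned spectra into a nearest-environment shift predictor.

The grammar used here is deliberately simple and unambiguous rather than
byte-compatible with any historical implementation:

* the code opens with the center descriptor (element + charge),
* each sphere is appended after a ``/`` separator,
* within a sphere, every expanded atom contributes a parenthesized,
  comma-separated neighbor list,
* a neighbor descriptor is ``bond symbol + element + charge + ring flag``
  with bond symbols ``=`` (double), ``#`` (triple), ``%`` (aromatic) and
  nothing for single bonds; ``@`` marks ring membership; ``&`` marks a ring
  closure back onto an already-visited atom; implicit hydrogens appear as
  ``H``.

Neighbor order is fixed by a priority table (higher bond order first, then
element, then ring membership), with remaining ties broken by the canonical
atom ranking, so the code is deterministic under atom relabeling and equal
for symmetry-equivalent atoms.  The code at sphere k is a prefix of the code
at sphere k+1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import chem_core
from .chem_core import Molecule, check_structure, equivalence_classes

__all__ = [
    "HoseCode",
    "ReferenceRecord",
    "HoseIndex",
    "ShiftPrediction",
    "generate_hose",
    "build_index",
    "predict_shifts",
    "read_reference_sdf",
    "write_reference_sdf",
]

DEFAULT_MAX_SPHERE = 4
DEFAULT_MIN_CONTRIBUTORS = 3

SHIFT_FIELD = "C13_SHIFTS"
SOURCE_FIELD = "SOURCE"

# element priority for neighbor ordering; lower sorts first, H always last
_ELEMENT_PRIORITY = {
    "C": 0, "O": 1, "N": 2, "S": 3, "P": 4, "Si": 5, "B": 6,
    "F": 7, "Cl": 8, "Br": 9, "I": 10,
}
_BOND_SYMBOL = {1: "", 2: "=", 3: "#"}


def _elem_prio(element: str) -> tuple[int, str]:
    if element == "H":
        return (99, "H")
    return (_ELEMENT_PRIORITY.get(element, 50), element)


def _charge_text(charge: int) -> str:
    if charge > 0:
        return "+" * charge
    if charge < 0:
        return "-" * (-charge)
    return ""


@dataclass(frozen=True)
class HoseCode:
    center: int  # 1-based atom index
    max_sphere: int
    codes: tuple[str, ...]  # cumulative code per sphere, codes[k-1] = sphere k

    @property
    def text(self) -> str:
        return self.codes[-1]

    def at_sphere(self, sphere: int) -> str:
        return self.codes[sphere - 1]


def generate_hose(m: Molecule, atom: int, max_sphere: int = DEFAULT_MAX_SPHERE) -> HoseCode:
    """Canonical spherical environment code for a carbon atom."""
    if m.atom(atom).element != "C":
        raise ValueError(
            f"HOSE prediction is carbon-only; atom {atom} is {m.atom(atom).element}"
        )
    if max_sphere < 1:
        raise ValueError("max_sphere must be >= 1")

    sym = m.symmetry_classes()
    ranks = m.canonical_ranks()
    ring_atoms = m.ring_atoms()
    center = m.atom(atom)

    def descriptor(bond, b: int, closure: bool) -> str:
        nb = m.atom(b)
        sym_bond = "%" if bond.aromatic else _BOND_SYMBOL[bond.order]
        ring = "@" if b in ring_atoms else ""
        closure_mark = "&" if closure else ""
        return f"{sym_bond}{closure_mark}{nb.element}{_charge_text(nb.charge)}{ring}"

    def sort_key(bond, b: int):
        nb = m.atom(b)
        order = 1.5 if bond.aromatic else float(bond.order)
        return (
            -order,
            _elem_prio(nb.element),
            0 if b in ring_atoms else 1,
            -nb.charge,
            sym[b - 1],
            ranks[b - 1],
        )

    visited = {atom}
    frontier: list[int] = [atom]
    parent: dict[int, Optional[int]] = {atom: None}
    spheres: list[str] = []
    for _ in range(max_sphere):
        groups: list[str] = []
        next_frontier: list[int] = []
        for a in frontier:
            entries = []
            for bond in m.bonds_of(a):
                b = bond.other(a)
                if b == parent[a]:
                    continue
                entries.append((sort_key(bond, b), bond, b))
            entries.sort(key=lambda e: e[0])
            descs = []
            for _, bond, b in entries:
                if b in visited:
                    descs.append(descriptor(bond, b, closure=True))
                else:
                    visited.add(b)
                    parent[b] = a
                    next_frontier.append(b)
                    descs.append(descriptor(bond, b, closure=False))
            descs.extend(["H"] * m.atom(a).implicit_h)
            groups.append("(" + ",".join(descs) + ")")
        spheres.append("".join(groups))
        frontier = next_frontier

    head = f"{center.element}{_charge_text(center.charge)}"
    codes = []
    acc = head
    for s in spheres:
        acc = acc + "/" + s
        codes.append(acc)
    return HoseCode(center=atom, max_sphere=max_sphere, codes=tuple(codes))


# ---------------------------------------------------------------------------
# reference records and the index
# ---------------------------------------------------------------------------


@dataclass
class ReferenceRecord:
    """One assigned spectrum: a molecule plus exactly one shift per carbon."""

    molecule: Molecule
    shifts: dict[int, float]  # 1-based carbon atom index -> ppm
    source: str = ""
    name: str = ""

    def validate(self) -> None:
        carbons = set(self.molecule.carbons())
        missing = carbons - set(self.shifts)
        extra = set(self.shifts) - carbons
        if missing:
            raise ValueError(
                f"record {self.name or self.source!r}: carbons without a shift: "
                f"{sorted(missing)}"
            )
        if extra:
            raise ValueError(
                f"record {self.name or self.source!r}: shifts assigned to "
                f"non-carbon atoms: {sorted(extra)}"
            )


@dataclass
class HoseIndex:
    """Per-sphere mapping code -> [(record id, atom index, shift ppm)]."""

    max_sphere: int = DEFAULT_MAX_SPHERE
    levels: dict[int, dict[str, list[tuple[int, int, float]]]] = field(
        default_factory=dict
    )
    n_records: int = 0

    def lookup(self, sphere: int, code: str) -> list[tuple[int, int, float]]:
        return self.levels.get(sphere, {}).get(code, [])

    @property
    def n_entries(self) -> int:
        return sum(
            len(v) for level in self.levels.values() for v in level.values()
        )

    # -- plain-text cache -------------------------------------------------
    CACHE_VERSION = 1

    def dump(self) -> str:
        payload = {
            "format": "c13referee-hose-index",
            "version": self.CACHE_VERSION,
            "max_sphere": self.max_sphere,
            "n_records": self.n_records,
            "levels": {
                str(s): {code: entries for code, entries in level.items()}
                for s, level in self.levels.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def load(cls, text: str) -> "HoseIndex":
        payload = json.loads(text)
        if payload.get("format") != "c13referee-hose-index":
            raise ValueError("not a HOSE index cache")
        if payload.get("version") != cls.CACHE_VERSION:
            raise ValueError(
                f"index cache version {payload.get('version')} not supported"
            )
        levels = {
            int(s): {
                code: [tuple(e) for e in entries] for code, entries in level.items()
            }
            for s, level in payload["levels"].items()
        }
        return cls(
            max_sphere=payload["max_sphere"],
            levels=levels,
            n_records=payload["n_records"],
        )


def build_index(
    records: Sequence[ReferenceRecord], max_sphere: int = DEFAULT_MAX_SPHERE
) -> HoseIndex:
    """Index every carbon of every record at every sphere 1..max_sphere."""
    levels: dict[int, dict[str, list[tuple[int, int, float]]]] = {
        s: {} for s in range(1, max_sphere + 1)
    }
    for rec_id, rec in enumerate(records):
        rec.validate()
        result = check_structure(rec.molecule)
        if not result.ok:
            problems = "; ".join(f.message for f in result.errors())
            raise ValueError(
                f"record {rec_id} ({rec.name or rec.source}) fails the structure "
                f"check: {problems}"
            )
        for carbon in rec.molecule.carbons():
            code = generate_hose(rec.molecule, carbon, max_sphere)
            shift = rec.shifts[carbon]
            for s in range(1, max_sphere + 1):
                levels[s].setdefault(code.at_sphere(s), []).append(
                    (rec_id, carbon, shift)
                )
    return HoseIndex(max_sphere=max_sphere, levels=levels, n_records=len(records))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@dataclass
class ShiftPrediction:
    class_id: int
    atoms: tuple[int, ...]
    shift: Optional[float]  # ppm; None when unpredicted
    n: int
    std: float
    sphere: int
    status: str  # "matched" | "fallback" | "unpredicted"

    @property
    def predicted(self) -> bool:
        return self.status != "unpredicted"

    @property
    def low_confidence(self) -> bool:
        return self.predicted and self.n == 1


def predict_shifts(
    m: Molecule,
    index: HoseIndex,
    min_contributors: int = DEFAULT_MIN_CONTRIBUTORS,
    exclude_records: Iterable[int] = (),
) -> list[ShiftPrediction]:
    """Predict one shift per carbon equivalence class.

    The sphere-``max`` code is looked up first; if it gathers fewer than
    ``min_contributors`` reference atoms the code is truncated sphere by
    sphere down to sphere 1.  The first sphere reaching the contributor
    quorum wins; if no sphere reaches it, the deepest sphere achieving the
    maximal available count is used.  Classes without a single sphere-1 hit
    are reported as unpredicted.  ``exclude_records`` supports leave-one-out
    protocols without rebuilding the index.
    """
    excluded = set(exclude_records)
    partition = equivalence_classes(m)
    predictions = []
    for cid, atoms in enumerate(partition.classes, start=1):
        code = generate_hose(m, atoms[0], index.max_sphere)
        chosen: Optional[tuple[int, list[tuple[int, int, float]]]] = None
        best: Optional[tuple[int, list[tuple[int, int, float]]]] = None
        for s in range(index.max_sphere, 0, -1):
            hits = index.lookup(s, code.at_sphere(s))
            if excluded:
                hits = [h for h in hits if h[0] not in excluded]
            if not hits:
                continue
            if best is None or len(hits) > len(best[1]):
                best = (s, hits)
            if len(hits) >= min_contributors:
                chosen = (s, hits)
                break
        if chosen is None:
            chosen = best
        if chosen is None:
            predictions.append(
                ShiftPrediction(cid, atoms, None, 0, 0.0, 0, "unpredicted")
            )
            continue
        sphere, hits = chosen
        values = [h[2] for h in hits]
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / len(values)
        status = "matched" if sphere == index.max_sphere else "fallback"
        predictions.append(
            ShiftPrediction(
                cid, atoms, mean, len(values), math.sqrt(var), sphere, status
            )
        )
    return predictions


# ---------------------------------------------------------------------------
# reference-database SDF I/O
# ---------------------------------------------------------------------------


def write_reference_sdf(records: Sequence[ReferenceRecord]) -> str:
    props = []
    for rec in records:
        rec.validate()
        shift_lines = "\n".join(
            f"{atom}:{rec.shifts[atom]:.2f}" for atom in sorted(rec.shifts)
        )
        props.append(
            {"NAME": rec.name, SHIFT_FIELD: shift_lines, SOURCE_FIELD: rec.source}
        )
    return chem_core.write_sdf([r.molecule for r in records], props)


def read_reference_sdf(text: str) -> list[ReferenceRecord]:
    records = []
    for mol in chem_core.parse_sdf(text):
        raw = mol.properties.get(SHIFT_FIELD, "")
        shifts: dict[int, float] = {}
        for token in raw.replace(";", "\n").split():
            atom_text, _, shift_text = token.partition(":")
            shifts[int(atom_text)] = float(shift_text)
        rec = ReferenceRecord(
            molecule=mol,
            shifts=shifts,
            source=mol.properties.get(SOURCE_FIELD, ""),
            name=mol.name,
        )
        rec.validate()
        records.append(rec)
    return records
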