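"""Synthetic reference spectra and error injection.

A desk-scale stand-in for a curated literature shift collection: structure
families (n-alkanes, substituted benzenes, chromones, fused toy scaffolds)
are enumerated deterministically and their carbons receive shifts from an
additive increment model (Grant–Paul-style chain increments, classic
ipso/ortho/meta/para aromatic substituent increments, simple sp2/carbonyl
rules) plus per-equivalence-class Gaussian noise.  The model is a pure
function of the three-bond environment, so carbons with equal sphere-3
environment codes share their base value — exactly the regularity a
spherical-environment predictor exploits.

The error injector produces the characteristic mistakes seen in published
carbon data: digit-drop typos (132.2 -> 32.2), swapped assignments, rotated
assignment sequences, duplicated peak lists on different structures, and
wrong (positional-isomer) structure proposals.  Every injection keeps the
ground truth alongside so detection pipelines can be scored.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem

from . import chem_core
from .chem_core import Molecule, equivalence_classes, from_rdkit
from .hose import ReferenceRecord
from .verification import PeakList, Signal

__all__ = [
    "IncrementShiftModel",
    "ErrorInjection",
    "CorruptedEntry",
    "load_increment_tables",
    "make_reference_set",
    "standard_database",
    "make_peaklist",
    "inject_errors",
    "named_molecule",
    "FAMILIES",
]

FAMILIES = ("alkanes", "benzenes", "chromones", "fused")
_FAMILY_CODE = {name: i for i, name in enumerate(FAMILIES)}

DEFAULT_FAMILY_SIZES = {
    "alkanes": 15,
    "benzenes": 110,
    "chromones": 61,
    "fused": 30,
}


def load_increment_tables(version: int = 1) -> dict:
    path = importlib.resources.files("c13referee.data").joinpath(
        f"increments_v{version}.yaml"
    )
    return yaml.safe_load(path.read_text())


# ---------------------------------------------------------------------------
# the shift model
# ---------------------------------------------------------------------------


class IncrementShiftModel:
    """Deterministic additive shift model over carbon archetypes."""

    def __init__(self, tables: Optional[dict] = None):
        self.tables = tables or load_increment_tables()
        self.noise_sigma = float(self.tables["noise_sigma"])

    # -- carbon archetype helpers ---------------------------------------
    def _aromatic_rings(self, m: Molecule) -> list[tuple[int, ...]]:
        info = m.to_rdkit().GetRingInfo()
        rings = []
        aromatic_atoms = {
            i for i in range(1, m.n_atoms + 1)
            if any(b.aromatic for b in m.bonds_of(i))
        }
        for ring in info.AtomRings():
            atoms = tuple(a + 1 for a in ring)
            if all(a in aromatic_atoms for a in atoms):
                rings.append(atoms)
        return sorted(rings)

    def _substituent_key(self, m: Molecule, bond, s: int) -> str:
        a = m.atom(s)
        if bond.aromatic:
            return "aryl"
        elem = a.element
        if elem == "O":
            if a.implicit_h >= 1:
                return "OH"
            nbr_c = [
                n for n in m.neighbors(s)
                if m.atom(n).element == "C"
            ]
            methyl = any(
                m.atom(n).implicit_h == 3 for n in nbr_c
            )
            return "OMe" if methyl else "OR"
        if elem == "N":
            charged = a.charge != 0
            if charged:
                return "generic"
            return "NH2" if a.implicit_h >= 2 else "NR"
        if elem in ("F", "Cl", "Br", "I"):
            return elem
        if elem == "C":
            for b2 in m.bonds_of(s):
                other = m.atom(b2.other(s))
                if b2.order == 3 and other.element == "N":
                    return "CN"
                if b2.order == 2 and other.element == "O":
                    return "CHO" if a.implicit_h >= 1 else "acyl"
                if b2.order == 2 and other.element == "C":
                    return "vinyl"
            if a.implicit_h == 3:
                return "CH3"
            return "alkyl"
        return "generic"

    def _aromatic_shift(self, m: Molecule, i: int) -> float:
        rings = [r for r in self._aromatic_rings(m) if i in r]
        six = [r for r in rings if len(r) == 6]
        tab = self.tables["aromatic"]
        if six:
            ring = six[0]
            value = float(tab["base"])
            k = ring.index(i)
            n = len(ring)
            for j, r in enumerate(ring):
                dist = min(abs(j - k), n - abs(j - k))
                pos = min(dist, 3)
                for b in m.bonds_of(r):
                    s = b.other(r)
                    if s in ring:
                        continue
                    key = self._substituent_key(m, b, s)
                    inc = tab["substituents"].get(key, tab["substituents"]["generic"])
                    value += float(inc[pos])
            return value
        # five-membered heteroaromatic ring
        ring = rings[0]
        hetero = [r for r in ring if m.atom(r).element != "C"]
        base = 110.0
        if hetero:
            h = hetero[0]
            k, kh = ring.index(i), ring.index(h)
            n = len(ring)
            dist = min(abs(k - kh), n - abs(k - kh))
            elem = m.atom(h).element
            alpha = {"O": 143.0, "N": 118.0, "S": 125.0}.get(elem, 120.0)
            beta = {"O": 110.0, "N": 108.0, "S": 127.0}.get(elem, 115.0)
            base = alpha if dist == 1 else beta
        value = base
        k = ring.index(i)
        n = len(ring)
        for j, r in enumerate(ring):
            dist = min(abs(j - k), n - abs(j - k))
            pos = min(dist, 3)
            for b in m.bonds_of(r):
                s = b.other(r)
                if s in ring:
                    continue
                key = self._substituent_key(m, b, s)
                inc = self.tables["aromatic"]["substituents"].get(
                    key, self.tables["aromatic"]["substituents"]["generic"]
                )
                value += float(inc[pos])
        return value

    def _carbonyl_shift(self, m: Molecule, i: int) -> float:
        tab = self.tables["carbonyl"]
        atom = m.atom(i)
        single_o_h = single_o_r = has_n = False
        conjugated = 0
        for b in m.bonds_of(i):
            nb = b.other(i)
            na = m.atom(nb)
            if b.order == 1 and na.element == "O":
                if na.implicit_h >= 1:
                    single_o_h = True
                else:
                    single_o_r = True
            if b.order == 1 and na.element == "N":
                has_n = True
            if na.element == "C" and (
                any(bb.aromatic for bb in m.bonds_of(nb))
                or any(
                    bb.order == 2 and m.atom(bb.other(nb)).element == "C"
                    for bb in m.bonds_of(nb)
                    if bb.other(nb) != i
                )
            ):
                conjugated += 1
        if single_o_h:
            base = tab["acid"]
        elif single_o_r:
            base = tab["ester"]
        elif has_n:
            base = tab["amide"]
        elif atom.implicit_h >= 1:
            base = tab["aldehyde"]
        else:
            base = tab["ketone"]
        return float(base) + float(tab["conjugation"]) * min(conjugated, 2)

    def _sp2_shift(self, m: Molecule, i: int, partner: int) -> float:
        tab = self.tables["sp2"]
        value = float(tab["base"])
        for b in m.bonds_of(i):
            nb = b.other(i)
            if nb == partner or m.atom(nb).element == "H":
                continue
            if any(bb.aromatic for bb in m.bonds_of(nb)):
                value += float(tab["aromatic_alpha"])
            else:
                value += float(tab["alpha"].get(m.atom(nb).element, tab["alpha"]["C"]))
        for b in m.bonds_of(partner):
            nb = b.other(partner)
            if nb == i or m.atom(nb).element == "H":
                continue
            if any(bb.aromatic for bb in m.bonds_of(nb)):
                value += float(tab["aromatic_beta"])
            else:
                value += float(tab["beta"].get(m.atom(nb).element, tab["beta"]["C"]))
        return value

    def _sp3_shift(self, m: Molecule, i: int) -> float:
        tab = self.tables["sp3"]
        value = float(tab["base"])
        # BFS over heavy atoms to distance 3
        dist = {i: 0}
        frontier = [i]
        for d in (1, 2, 3):
            nxt = []
            for v in frontier:
                for w in m.neighbors(v):
                    if w in dist or m.atom(w).element == "H":
                        continue
                    dist[w] = d
                    nxt.append(w)
            frontier = nxt
        for w, d in dist.items():
            if d == 0:
                continue
            elem = m.atom(w).element
            if elem == "C":
                value += float(tab["carbon"][d - 1])
            else:
                inc = tab["hetero"].get(elem)
                if inc:
                    value += float(inc[d - 1])
        return value

    def shift(self, m: Molecule, i: int) -> float:
        """Noise-free model shift of carbon ``i`` (1-based), ppm."""
        atom = m.atom(i)
        if atom.element != "C":
            raise ValueError(f"atom {i} is {atom.element}, not carbon")
        if any(b.aromatic for b in m.bonds_of(i)):
            return self._aromatic_shift(m, i)
        for b in m.bonds_of(i):
            nb = m.atom(b.other(i))
            if b.order == 2 and nb.element == "O":
                return self._carbonyl_shift(m, i)
            if b.order == 3:
                if nb.element == "N":
                    return float(self.tables["other"]["nitrile"])
                return float(
                    self.tables["other"][
                        "alkyne_terminal" if atom.implicit_h else "alkyne"
                    ]
                )
        for b in m.bonds_of(i):
            if b.order == 2 and m.atom(b.other(i)).element == "C":
                return self._sp2_shift(m, i, b.other(i))
            if b.order == 2 and m.atom(b.other(i)).element == "N":
                return 160.0
        return self._sp3_shift(m, i)

    def spectrum(
        self, m: Molecule, rng: Optional[np.random.Generator] = None,
        noise_sigma: Optional[float] = None,
    ) -> dict[int, float]:
        """One shift per carbon; symmetry-equivalent carbons share their
        value (noise is drawn per equivalence class)."""
        sigma = self.noise_sigma if noise_sigma is None else noise_sigma
        partition = equivalence_classes(m)
        shifts: dict[int, float] = {}
        for atoms in partition.classes:
            value = self.shift(m, atoms[0])
            if rng is not None and sigma > 0:
                value += rng.normal(0.0, sigma)
            for a in atoms:
                shifts[a] = round(value, 2)
        return shifts


# ---------------------------------------------------------------------------
# structure enumeration
# ---------------------------------------------------------------------------

# substituent fragments (SMILES, attachment at fragment atom 0)
_SUBSTITUENTS: list[tuple[str, str]] = [
    ("Me", "C"),
    ("Et", "CC"),
    ("OH", "O"),
    ("OMe", "OC"),
    ("OEt", "OCC"),
    ("NH2", "N"),
    ("NHMe", "NC"),
    ("NMe2", "N(C)C"),
    ("F", "F"),
    ("Cl", "Cl"),
    ("Br", "Br"),
    ("CN", "C#N"),
    ("CHO", "C=O"),
    ("COMe", "C(C)=O"),
]


def _attach(core: Chem.Mol, attachments: Sequence[tuple[int, str]]) -> Chem.Mol:
    """Attach substituent fragments (by SMILES) to core atoms (0-based)."""
    mol = core
    for idx, frag_smiles in attachments:
        frag = Chem.MolFromSmiles(frag_smiles)
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    return mol


def _benzene(subs: dict[int, str]) -> Chem.Mol:
    core = Chem.MolFromSmiles("c1ccccc1")
    return _attach(core, [(pos - 1, frag) for pos, frag in sorted(subs.items())])


def _decoration_sites(mol: Chem.Mol, sub_atoms: Sequence[int]) -> list[int]:
    """Ring CH positions at topological distance >= 4 from every substituted
    atom — decorating there leaves the 3-sphere environment of the
    substituted positions untouched."""
    dm = Chem.GetDistanceMatrix(mol)
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetTotalNumHs() < 1:
            continue
        if not atom.GetIsAromatic():
            continue
        i = atom.GetIdx()
        if all(dm[i][s] >= 4 for s in sub_atoms):
            sites.append(i)
    return sites


def _alkane_entries(size: int) -> list[tuple[str, Chem.Mol]]:
    entries = []
    for n in range(6, 6 + min(size, 35)):  # C6..C40
        entries.append((f"n-C{n}", Chem.MolFromSmiles("C" * n)))
    return entries


def _benzene_entries(size: int) -> list[tuple[str, Chem.Mol]]:
    entries: list[tuple[str, Chem.Mol]] = [("benzene", _benzene({}))]
    # guaranteed brominated members (meta partners keep the ipso ortho clean)
    anchors = [
        ("bromobenzene", {1: "Br"}),
        ("3-bromotoluene", {1: "Br", 3: "C"}),
        ("3-bromoethylbenzene", {1: "Br", 3: "CC"}),
        ("3-bromoanisole", {1: "Br", 3: "OC"}),
        ("3-bromoaniline", {1: "Br", 3: "N"}),
    ]
    for name, subs in anchors:
        entries.append((name, _benzene(subs)))
    for name, frag in _SUBSTITUENTS:
        entries.append((f"{name}-benzene", _benzene({1: frag})))
    pairs = []
    for j in range(len(_SUBSTITUENTS)):
        for i in range(j + 1):
            pairs.append((i, j))
    for i, j in pairs:
        ni, fi = _SUBSTITUENTS[i]
        nj, fj = _SUBSTITUENTS[j]
        for pos, tag in ((4, "para"), (3, "meta")):
            entries.append((f"{tag}-{ni}-{nj}-benzene", _benzene({1: fi, pos: fj})))
            if len(entries) > size + 40:
                return entries
    return entries


_CHROMONE_SMILES = "O=C1C=COc2ccccc21"
# benzo-ring positions of the chromone core (0-based atom indices)
_CHROMONE_POSITIONS = {5: 9, 6: 8, 7: 7, 8: 6, 2: 3, 3: 2}
_COUMARIN_SMILES = "O=C1C=Cc2ccccc2O1"
_COUMARIN_POSITIONS = {3: 2, 4: 3, 5: 5, 6: 6, 7: 7, 8: 8}


def _variants(
    name: str, core_smiles: str, attachments: list[tuple[int, str]]
) -> list[tuple[str, Chem.Mol]]:
    """A structure plus up to two methyl-decorated variants differing only
    beyond the 3-sphere of the substituted positions."""
    core = Chem.MolFromSmiles(core_smiles)
    base = _attach(core, attachments)
    out = [(name, base)]
    sub_atoms = [idx for idx, _ in attachments]
    for k, site in enumerate(_decoration_sites(base, sub_atoms)[:2], start=1):
        out.append((f"{name}-Me{k}", _attach(base, [(site, "C")])))
    return out


def _chromone_entries(size: int) -> list[tuple[str, Chem.Mol]]:
    entries = [("chromone", Chem.MolFromSmiles(_CHROMONE_SMILES))]
    for sub_name, frag in (("OH", "O"), ("OMe", "OC"), ("Me", "C"),
                           ("Br", "Br"), ("Cl", "Cl")):
        for pos in (6, 7, 5, 8):
            entries.extend(
                _variants(
                    f"{pos}-{sub_name}-chromone",
                    _CHROMONE_SMILES,
                    [(_CHROMONE_POSITIONS[pos], frag)],
                )
            )
            if len(entries) > size + 10:
                return entries
    return entries


def _fused_entries(size: int) -> list[tuple[str, Chem.Mol]]:
    entries = [("naphthalene", Chem.MolFromSmiles("c1ccc2ccccc2c1"))]
    for sub_name, frag in (("OH", "O"), ("OMe", "OC"), ("Me", "C"), ("Br", "Br")):
        for site, tag in ((0, "2"), (4, "1")):
            entries.extend(
                _variants(
                    f"{tag}-{sub_name}-naphthalene", "c1ccc2ccccc2c1", [(site, frag)]
                )
            )
    entries.append(("benzofuran", Chem.MolFromSmiles("c1ccc2occc2c1")))
    entries.extend(_variants("coumarin", _COUMARIN_SMILES, []))
    entries.append(
        (
            "esculetin",
            _attach(
                Chem.MolFromSmiles(_COUMARIN_SMILES),
                [(_COUMARIN_POSITIONS[6], "O"), (_COUMARIN_POSITIONS[7], "O")],
            ),
        )
    )
    entries.append(
        (
            "5,7-dihydroxy-2-hydroxymethylchromone",
            _attach(
                Chem.MolFromSmiles(_CHROMONE_SMILES),
                [
                    (_CHROMONE_POSITIONS[2], "CO"),
                    (_CHROMONE_POSITIONS[5], "O"),
                    (_CHROMONE_POSITIONS[7], "O"),
                ],
            ),
        )
    )
    return entries


_FAMILY_BUILDERS: dict[str, Callable[[int], list[tuple[str, Chem.Mol]]]] = {
    "alkanes": _alkane_entries,
    "benzenes": _benzene_entries,
    "chromones": _chromone_entries,
    "fused": _fused_entries,
}


def named_molecule(name: str) -> Molecule:
    """Look up one of the named fixture structures (e.g. 'esculetin')."""
    for family in FAMILIES:
        for entry_name, mol in _FAMILY_BUILDERS[family](500):
            if entry_name == name:
                return from_rdkit(mol, name=name)
    raise KeyError(name)


# ---------------------------------------------------------------------------
# reference sets
# ---------------------------------------------------------------------------


def make_reference_set(
    family: str,
    size: int,
    seed: int,
    noise_sigma: Optional[float] = None,
    model: Optional[IncrementShiftModel] = None,
) -> list[ReferenceRecord]:
    """Deterministic synthetic reference records for one structure family."""
    if family not in _FAMILY_BUILDERS:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if size < 1:
        raise ValueError("size must be >= 1")
    model = model or IncrementShiftModel()
    raw = _FAMILY_BUILDERS[family](size)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for name, rdmol in raw:
        if len(records) >= size:
            break
        ident = Chem.MolToSmiles(rdmol)
        if ident in seen:
            continue
        seen.add(ident)
        mol = from_rdkit(rdmol, name=name)
        rng = np.random.default_rng(
            [max(seed, 0), _FAMILY_CODE[family], len(records)]
        )
        shifts = model.spectrum(mol, rng=rng, noise_sigma=noise_sigma)
        records.append(
            ReferenceRecord(
                molecule=mol,
                shifts=shifts,
                source=f"synthetic:{family}:{name}",
                name=name,
            )
        )
    return records


def standard_database(
    seed: int,
    sizes: Optional[dict[str, int]] = None,
    model: Optional[IncrementShiftModel] = None,
) -> list[ReferenceRecord]:
    """The packaged ~215-structure reference database (all four families)."""
    sizes = sizes or DEFAULT_FAMILY_SIZES
    model = model or IncrementShiftModel()
    records: list[ReferenceRecord] = []
    for family in FAMILIES:
        records.extend(
            make_reference_set(family, sizes[family], seed, model=model)
        )
    return records


def make_peaklist(record: ReferenceRecord, assigned: bool = True) -> PeakList:
    """Peak list of a reference record: one signal per equivalence class."""
    partition = equivalence_classes(record.molecule)
    signals = [
        Signal(
            shift=record.shifts[atoms[0]],
            atoms=atoms if assigned else (),
        )
        for atoms in partition.classes
    ]
    return PeakList(signals=signals, key=record.name or record.source)


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


@dataclass
class ErrorInjection:
    kind: str  # digit-drop | assignment-swap | sequence-shift | duplicate-data | wrong-structure
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class CorruptedEntry:
    molecule: Molecule
    peaklist: PeakList
    truth: dict
    record: ReferenceRecord


WRONG_STRUCTURE_MIN_CHANGE = 6.0  # ppm; the corruption must be detectable

_MODEL_CACHE: list = []


def _default_model() -> "IncrementShiftModel":
    if not _MODEL_CACHE:
        _MODEL_CACHE.append(IncrementShiftModel())
    return _MODEL_CACHE[0]


def _spectrum_change(
    model: "IncrementShiftModel", original: Molecule, candidate: Molecule
) -> float:
    """Largest per-position disagreement between the noise-free model
    spectra of two structures (sorted pairing); infinite when the class
    counts differ (a detectable mismatch by itself)."""
    a = sorted(set(model.spectrum(original).values()))
    b = sorted(set(model.spectrum(candidate).values()))
    if len(a) != len(b):
        return float("inf")
    return max((abs(x - y) for x, y in zip(a, b)), default=0.0)


def _positional_isomer(
    m: Molecule,
    rng: np.random.Generator,
    model: Optional["IncrementShiftModel"] = None,
    min_shift_change: float = WRONG_STRUCTURE_MIN_CHANGE,
) -> Optional[tuple[Molecule, dict]]:
    """Relocate one pendant substituent to a different position.

    A corruption only counts as a wrong-structure case when it would change
    the (noise-free) spectrum by more than the green threshold somewhere —
    an isomer indistinguishable within noise is not an error a referee
    could ever flag.
    """
    from . import revision as _rev

    if model is None and min_shift_change > 0:
        model = _default_model()
    original = chem_core.canonical_identifier(m).text
    branches = _rev._pendant_branches(m)
    options = []
    for site, first, order, comp in branches:
        if len(comp) == m.n_atoms - 1:
            continue
        for target in range(1, m.n_atoms + 1):
            if target == site or target in comp:
                continue
            if m.atom(target).element != "C":
                continue
            if m.atom(target).implicit_h < order:
                continue
            options.append((site, first, order, target))
    rng.shuffle(options)
    for site, first, order, target in options:
        bonds = _rev._remove_bond(m.bonds, site, first)
        bonds.append(chem_core.Bond(target, first, order=order))
        cand = _rev._edited(m, bonds)
        if cand is None:
            continue
        ident = chem_core.canonical_identifier(cand).text
        if ident == original:
            continue
        if min_shift_change > 0 and model is not None:
            if _spectrum_change(model, m, cand) < min_shift_change:
                continue
        return cand, {"from": site, "to": target, "branch": first}
    return None


def inject_errors(
    records: Sequence[ReferenceRecord],
    injections: Sequence[ErrorInjection],
) -> list[CorruptedEntry]:
    """Apply the requested corruptions; each entry carries its ground truth."""
    out: list[CorruptedEntry] = []
    for inj in injections:
        rng = np.random.default_rng([inj.seed, len(out)])
        idx = inj.params.get("record")
        if idx is None:
            idx = int(rng.integers(0, len(records)))
        rec = records[idx]
        plist = make_peaklist(rec, assigned=True)

        if inj.kind == "digit-drop":
            eligible = [
                i for i, s in enumerate(plist.signals) if 100.0 <= s.shift < 200.0
            ]
            if not eligible:
                raise ValueError(
                    f"record {rec.name!r} has no 3-digit shift to corrupt"
                )
            pick = eligible[int(rng.integers(0, len(eligible)))]
            old = plist.signals[pick].shift
            plist.signals[pick].shift = round(old - 100.0, 2)
            truth = {"kind": inj.kind, "record": idx, "signal": pick,
                     "original": old, "corrupted": plist.signals[pick].shift}
            out.append(CorruptedEntry(rec.molecule, plist, truth, rec))

        elif inj.kind == "assignment-swap":
            if len(plist.signals) < 2:
                raise ValueError("assignment swap needs at least two signals")
            i, j = rng.choice(len(plist.signals), size=2, replace=False)
            i, j = int(i), int(j)
            si, sj = plist.signals[i], plist.signals[j]
            si.shift, sj.shift = sj.shift, si.shift
            truth = {"kind": inj.kind, "record": idx, "signals": (i, j)}
            out.append(CorruptedEntry(rec.molecule, plist, truth, rec))

        elif inj.kind == "sequence-shift":
            shifts = [s.shift for s in plist.signals]
            rotated = shifts[1:] + shifts[:1]
            for s, v in zip(plist.signals, rotated):
                s.shift = v
            truth = {"kind": inj.kind, "record": idx, "rotation": 1}
            out.append(CorruptedEntry(rec.molecule, plist, truth, rec))

        elif inj.kind == "duplicate-data":
            src = inj.params.get("source_record")
            if src is None:
                src = int(rng.integers(0, len(records)))
                while src == idx:
                    src = int(rng.integers(0, len(records)))
            source = records[src]
            src_list = make_peaklist(source, assigned=False)
            dup = PeakList(
                signals=[Signal(shift=s.shift) for s in src_list.signals],
                key=rec.name or rec.source,
            )
            truth = {"kind": inj.kind, "record": idx, "source_record": src}
            out.append(CorruptedEntry(rec.molecule, dup, truth, rec))

        elif inj.kind == "wrong-structure":
            result = _positional_isomer(rec.molecule, rng)
            if result is None:
                raise ValueError(
                    f"record {rec.name!r} has no pendant substituent to relocate"
                )
            isomer, move = result
            exp = PeakList(
                signals=[Signal(shift=s.shift) for s in plist.signals],
                key=rec.name or rec.source,
            )
            truth = {"kind": inj.kind, "record": idx, "move": move}
            out.append(CorruptedEntry(isomer, exp, truth, rec))

        else:
            raise ValueError(f"unknown injection kind {inj.kind!r}")
    return out
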