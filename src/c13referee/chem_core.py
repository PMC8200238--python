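"""Structure data model, molfile I/O and formal structure checks.

Molecules are stored as explicit atom/bond graphs with 1-based atom indices
(matching molfile conventions).  Bond orders are kept in Kekulé form with a
separate aromatic flag so that downstream environment codes are independent
of the Kekulé structure chosen by the depositor.  RDKit does the heavy
lifting for aromaticity perception, canonical ranking, canonical identifiers
and substructure matching; the thin fixed-width V2000 reader exists so that
malformed files are rejected with the offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Finding",
    "StructureCheckResult",
    "EquivalencePartition",
    "CanonicalIdentifier",
    "MolfileParseError",
    "parse_molfile",
    "parse_sdf",
    "write_molfile",
    "write_sdf",
    "check_structure",
    "equivalence_classes",
    "canonical_identifier",
    "substructure_match",
    "molecular_weight",
    "from_rdkit",
    "from_smiles",
    "allowed_valences",
]


# standard organic valence table; values are the allowed total valences of the
# neutral element.  Charged forms are derived in allowed_valences().
_VALENCES = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "Si": (4,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

# V2000 atom-block charge codes
_MOLFILE_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_CHARGE_TO_CODE = {v: k for k, v in _MOLFILE_CHARGE.items()}

_BOND_ORDER_TO_RDKIT = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}


def allowed_valences(element: str, charge: int) -> Optional[tuple[int, ...]]:
    """Allowed total valences for an element/charge pair, or None if unknown."""
    base = _VALENCES.get(element)
    if base is None:
        return None
    if charge == 0:
        return base
    if element == "C" and abs(charge) == 1:
        return (3,)
    if element in ("N", "P") and charge == 1:
        return (4,)
    if element in ("N", "P") and charge == -1:
        return (2,)
    if element in ("O", "S") and charge == 1:
        return tuple(v + 1 for v in base)
    if element in ("O", "S") and charge == -1:
        return tuple(v - 1 for v in base if v >= 1)
    if element == "B" and charge == -1:
        return (4,)
    return None


@dataclass
class Atom:
    element: str
    charge: int = 0
    implicit_h: int = 0
    coords: Optional[tuple[float, float]] = None


@dataclass
class Bond:
    a1: int  # 1-based
    a2: int
    order: int = 1  # Kekulé order 1/2/3
    aromatic: bool = False

    def other(self, idx: int) -> int:
        return self.a2 if idx == self.a1 else self.a1


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""
    properties: dict = field(default_factory=dict)
    sanitized: bool = True

    # ---- graph helpers -------------------------------------------------
    def __post_init__(self) -> None:
        self._validate()
        self._cache: dict = {}

    def _validate(self) -> None:
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if b.a1 == b.a2:
                raise ValueError(f"self-bond on atom {b.a1}")
            if not (1 <= b.a1 <= n and 1 <= b.a2 <= n):
                raise ValueError(f"bond {b.a1}-{b.a2} references a nonexistent atom")
            key = frozenset((b.a1, b.a2))
            if key in seen:
                raise ValueError(f"duplicate bond {b.a1}-{b.a2}")
            seen.add(key)

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            name=self.name,
            properties=dict(self.properties),
            sanitized=self.sanitized,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom(self, idx: int) -> Atom:
        return self.atoms[idx - 1]

    def bonds_of(self, idx: int) -> list[Bond]:
        return self._adjacency().get(idx, [])

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.bonds_of(idx)]

    def carbons(self) -> list[int]:
        return [i for i in range(1, self.n_atoms + 1) if self.atoms[i - 1].element == "C"]

    def heavy_degree(self, idx: int) -> int:
        return sum(1 for b in self.bonds_of(idx) if self.atom(b.other(idx)).element != "H")

    def bond_order_sum(self, idx: int) -> int:
        return sum(b.order for b in self.bonds_of(idx))

    def _adjacency(self) -> dict[int, list[Bond]]:
        adj = self._cache.get("adj")
        if adj is None:
            adj = {}
            for b in self.bonds:
                adj.setdefault(b.a1, []).append(b)
                adj.setdefault(b.a2, []).append(b)
            self._cache["adj"] = adj
        return adj

    # ---- ring perception (bridge detection; no sanitization required) --
    def ring_bonds(self) -> set[frozenset[int]]:
        """Bonds that lie on at least one cycle (non-bridges)."""
        rb = self._cache.get("ring_bonds")
        if rb is not None:
            return rb
        n = self.n_atoms
        adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(1, n + 1)}
        for bi, b in enumerate(self.bonds):
            adj[b.a1].append((b.a2, bi))
            adj[b.a2].append((b.a1, bi))
        disc = [0] * (n + 1)
        low = [0] * (n + 1)
        timer = 1
        bridges: set[int] = set()
        for root in range(1, n + 1):
            if disc[root]:
                continue
            stack = [(root, -1, iter(adj[root]))]
            disc[root] = low[root] = timer
            timer += 1
            while stack:
                v, pedge, it = stack[-1]
                advanced = False
                for w, bi in it:
                    if bi == pedge:
                        continue
                    if disc[w]:
                        low[v] = min(low[v], disc[w])
                    else:
                        disc[w] = low[w] = timer
                        timer += 1
                        stack.append((w, bi, iter(adj[w])))
                        advanced = True
                        break
                if advanced:
                    continue
                stack.pop()
                if stack:
                    pv = stack[-1][0]
                    low[pv] = min(low[pv], low[v])
                    if low[v] > disc[pv]:
                        bridges.add(pedge)
        rb = {
            frozenset((b.a1, b.a2))
            for bi, b in enumerate(self.bonds)
            if bi not in bridges
        }
        self._cache["ring_bonds"] = rb
        return rb

    def ring_atoms(self) -> set[int]:
        atoms: set[int] = set()
        for pair in self.ring_bonds():
            atoms.update(pair)
        return atoms

    # ---- RDKit bridge --------------------------------------------------
    def to_rdkit(self) -> Chem.Mol:
        mol = self._cache.get("rdkit")
        if mol is None:
            rw = Chem.RWMol()
            for a in self.atoms:
                ra = Chem.Atom(a.element)
                ra.SetFormalCharge(a.charge)
                rw.AddAtom(ra)
            for b in self.bonds:
                rw.AddBond(b.a1 - 1, b.a2 - 1, _BOND_ORDER_TO_RDKIT[b.order])
            mol = rw.GetMol()
            Chem.SanitizeMol(mol)
            self._cache["rdkit"] = mol
        return mol

    def symmetry_classes(self) -> tuple[int, ...]:
        ranks = self._cache.get("symclasses")
        if ranks is None:
            ranks = tuple(Chem.CanonicalRankAtoms(self.to_rdkit(), breakTies=False))
            self._cache["symclasses"] = ranks
        return ranks

    def canonical_ranks(self) -> tuple[int, ...]:
        ranks = self._cache.get("canranks")
        if ranks is None:
            ranks = tuple(Chem.CanonicalRankAtoms(self.to_rdkit(), breakTies=True))
            self._cache["canranks"] = ranks
        return ranks


# ---------------------------------------------------------------------------
# findings / check results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    atoms: tuple[int, ...] = ()


@dataclass
class StructureCheckResult:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]


@dataclass
class EquivalencePartition:
    """Partition of the carbon atoms into symmetry-equivalence classes."""

    classes: list[tuple[int, ...]]  # 1-based atom indices, each sorted
    class_of: dict[int, int]  # carbon atom index -> class id (1-based)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def atoms_of(self, class_id: int) -> tuple[int, ...]:
        return self.classes[class_id - 1]


@dataclass(frozen=True)
class CanonicalIdentifier:
    text: str


class MolfileParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# molfile / SDF I/O
# ---------------------------------------------------------------------------


def _int_field(line: str, start: int, end: int, lineno: int, what: str) -> int:
    token = line[start:end].strip()
    if not token:
        raise MolfileParseError(f"missing {what}", lineno)
    try:
        return int(token)
    except ValueError:
        raise MolfileParseError(f"malformed {what}: {token!r}", lineno) from None


def parse_molfile(text: str) -> Molecule:
    """Parse a single MDL MOL (V2000) block into a Molecule.

    Aromaticity is perceived from the Kekulé input via RDKit when the
    structure is chemically sane; structures that fail RDKit sanitization
    (e.g. valence violations) are still returned so that check_structure can
    report the problem, with implicit hydrogens filled in from the valence
    table.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("molfile too short: no counts line", 4)
    counts = lines[3]
    version = counts[33:39].strip() if len(counts) >= 34 else ""
    if "V3000" in counts:
        raise MolfileParseError("V3000 molfiles are not supported; supply V2000", 4)
    if version and version != "V2000":
        raise MolfileParseError(f"unsupported molfile version {version!r}", 4)
    n_atoms = _int_field(counts, 0, 3, 4, "atom count")
    n_bonds = _int_field(counts, 3, 6, 4, "bond count")
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileParseError(
            f"molfile truncated: expected {n_atoms} atom and {n_bonds} bond lines",
            len(lines),
        )

    atoms: list[Atom] = []
    for i in range(n_atoms):
        lineno = 5 + i
        line = lines[4 + i]
        if len(line) < 34:
            raise MolfileParseError("atom line too short", lineno)
        element = line[31:34].strip()
        if not element:
            raise MolfileParseError("missing element symbol", lineno)
        try:
            x = float(line[0:10])
            y = float(line[10:20])
        except ValueError:
            raise MolfileParseError("malformed atom coordinates", lineno) from None
        code = line[36:39].strip() if len(line) >= 37 else ""
        charge = _MOLFILE_CHARGE.get(int(code) if code else 0, 0)
        atoms.append(Atom(element=element, charge=charge, coords=(x, y)))

    bonds: list[Bond] = []
    orders: list[int] = []
    for i in range(n_bonds):
        lineno = 5 + n_atoms + i
        line = lines[4 + n_atoms + i]
        a1 = _int_field(line, 0, 3, lineno, "bond atom index")
        a2 = _int_field(line, 3, 6, lineno, "bond atom index")
        btype = _int_field(line, 6, 9, lineno, "bond type")
        for a in (a1, a2):
            if not (1 <= a <= n_atoms):
                raise MolfileParseError(
                    f"bond references atom {a} but the block has {n_atoms} atoms",
                    lineno,
                )
        if a1 == a2:
            raise MolfileParseError(f"self-bond on atom {a1}", lineno)
        if btype not in (1, 2, 3, 4):
            raise MolfileParseError(f"unsupported bond type {btype}", lineno)
        bonds.append(Bond(a1, a2, order=1 if btype == 4 else btype, aromatic=btype == 4))
        orders.append(btype)

    charge_props: dict[int, int] = {}
    saw_chg = False
    for line in lines[4 + n_atoms + n_bonds :]:
        if line.startswith("M  CHG"):
            saw_chg = True
            parts = line.split()
            n = int(parts[2])
            for k in range(n):
                charge_props[int(parts[3 + 2 * k])] = int(parts[4 + 2 * k])
        elif line.startswith("M  END"):
            break
    if saw_chg:
        for a in atoms:
            a.charge = 0
        for idx, chg in charge_props.items():
            atoms[idx - 1].charge = chg

    name = lines[0].strip()
    return _normalize(atoms, bonds, orders, name)


def _normalize(
    atoms: list[Atom], bonds: list[Bond], orders: list[int], name: str
) -> Molecule:
    """Run RDKit perception and settle Kekulé orders, aromatic flags and
    implicit hydrogens; fall back to the valence table when RDKit rejects
    the structure."""
    rw = Chem.RWMol()
    for a in atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.charge)
        rw.AddAtom(ra)
    for b, o in zip(bonds, orders):
        rw.AddBond(b.a1 - 1, b.a2 - 1, _BOND_ORDER_TO_RDKIT[o])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
        sanitized = True
    except Exception:
        sanitized = False

    if sanitized:
        return from_rdkit(mol, name=name)

    bond_sums = [0] * len(atoms)
    for b in bonds:
        bond_sums[b.a1 - 1] += b.order
        bond_sums[b.a2 - 1] += b.order
    for a, bsum in zip(atoms, bond_sums):
        allowed = allowed_valences(a.element, a.charge)
        if allowed:
            fitting = [v for v in allowed if v >= bsum]
            a.implicit_h = (min(fitting) - bsum) if fitting else 0
        else:
            a.implicit_h = 0
    m = Molecule(atoms=atoms, bonds=bonds, name=name, sanitized=False)
    return m


def from_rdkit(mol: Chem.Mol, name: str = "") -> Molecule:
    """Convert a sanitized RDKit molecule (implicit-H model) to a Molecule."""
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    atoms = []
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    for ra in mol.GetAtoms():
        coords = None
        if conf is not None:
            pos = conf.GetAtomPosition(ra.GetIdx())
            coords = (pos.x, pos.y)
        atoms.append(
            Atom(
                element=ra.GetSymbol(),
                charge=ra.GetFormalCharge(),
                implicit_h=ra.GetTotalNumHs(),
                coords=coords,
            )
        )
    bonds = []
    for rb in mol.GetBonds():
        kb = kek.GetBondBetweenAtoms(rb.GetBeginAtomIdx(), rb.GetEndAtomIdx())
        bonds.append(
            Bond(
                rb.GetBeginAtomIdx() + 1,
                rb.GetEndAtomIdx() + 1,
                order=int(kb.GetBondTypeAsDouble()),
                aromatic=rb.GetIsAromatic(),
            )
        )
    if not name and mol.HasProp("_Name"):
        name = mol.GetProp("_Name")
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def from_smiles(smiles: str, name: str = "") -> Molecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return from_rdkit(mol, name=name)


def write_molfile(m: Molecule) -> str:
    mol = m.to_rdkit()
    mol = Chem.Mol(mol)
    mol.SetProp("_Name", m.name)
    return Chem.MolToMolBlock(mol, kekulize=True)


def write_sdf(mols: Sequence[Molecule], props: Optional[Sequence[Mapping]] = None) -> str:
    """Serialize molecules as an SDF string; properties become data fields."""
    out = []
    for i, m in enumerate(mols):
        block = write_molfile(m).rstrip("\n")
        out.append(block)
        fields = dict(m.properties)
        if props is not None:
            fields.update(props[i])
        for key, value in fields.items():
            out.append(f"\n> <{key}>\n{value}\n")
        out.append("\n$$$$\n")
    return "".join(out)


def parse_sdf(text: str) -> list[Molecule]:
    """Parse an SDF (V2000) string into Molecules; data fields land in
    Molecule.properties."""
    mols = []
    chunks = text.split("$$$$")
    for chunk in chunks:
        if not chunk.strip():
            continue
        chunk = chunk.lstrip("\n")
        if "M  END" in chunk:
            molpart, rest = chunk.split("M  END", 1)
            molpart += "M  END"
        else:
            molpart, rest = chunk, ""
        m = parse_molfile(molpart)
        # data fields: "> <TAG>" then value lines until a blank line
        tag = None
        buf: list[str] = []
        for line in rest.splitlines():
            if line.startswith(">"):
                if tag is not None:
                    m.properties[tag] = "\n".join(buf).strip()
                lo = line.find("<")
                hi = line.find(">", lo + 1)
                tag = line[lo + 1 : hi] if lo != -1 and hi != -1 else line[1:].strip()
                buf = []
            elif tag is not None:
                if line.strip() == "":
                    m.properties[tag] = "\n".join(buf).strip()
                    tag = None
                    buf = []
                else:
                    buf.append(line)
        if tag is not None:
            m.properties[tag] = "\n".join(buf).strip()
        if "NAME" in m.properties and not m.name:
            m.name = m.properties["NAME"]
        mols.append(m)
    return mols


# ---------------------------------------------------------------------------
# formal checks
# ---------------------------------------------------------------------------


def check_structure(m: Molecule) -> StructureCheckResult:
    """Formal correctness check: valences against the standard table, net
    charge, aromatic bonds off-ring, and unspecified stereocenters (warning
    only — the shift prediction is constitution-only)."""
    findings: list[Finding] = []

    for i in range(1, m.n_atoms + 1):
        a = m.atom(i)
        allowed = allowed_valences(a.element, a.charge)
        total = m.bond_order_sum(i) + a.implicit_h
        if allowed is None:
            findings.append(
                Finding(
                    "warning",
                    "element",
                    f"atom {i} ({a.element}{a.charge:+d}) is outside the standard "
                    "valence table; valence not checked",
                    (i,),
                )
            )
        elif total not in allowed:
            findings.append(
                Finding(
                    "error",
                    "valence",
                    f"atom {i} ({a.element}) has total valence {total}, "
                    f"allowed: {sorted(allowed)}",
                    (i,),
                )
            )

    net = sum(a.charge for a in m.atoms)
    if net != 0:
        findings.append(
            Finding("warning", "net-charge", f"molecule carries net charge {net:+d}")
        )

    ring = m.ring_bonds()
    for b in m.bonds:
        if b.aromatic and frozenset((b.a1, b.a2)) not in ring:
            findings.append(
                Finding(
                    "error",
                    "aromatic-ring",
                    f"aromatic bond {b.a1}-{b.a2} does not lie on a ring",
                    (b.a1, b.a2),
                )
            )

    if m.sanitized:
        try:
            centers = Chem.FindMolChiralCenters(
                m.to_rdkit(), includeUnassigned=True, useLegacyImplementation=False
            )
            unspecified = [idx + 1 for idx, tag in centers if tag == "?"]
            if unspecified:
                findings.append(
                    Finding(
                        "warning",
                        "stereocenter",
                        f"{len(unspecified)} stereocenter(s) without specified "
                        "configuration; prediction is constitution-only",
                        tuple(unspecified),
                    )
                )
        except Exception:
            pass

    return StructureCheckResult(findings=findings)


def equivalence_classes(m: Molecule) -> EquivalencePartition:
    """Carbon symmetry classes from iterated neighborhood (Morgan-style)
    refinement, as implemented by RDKit's canonical atom ranking."""
    ranks = m.symmetry_classes()
    groups: dict[int, list[int]] = {}
    for i in m.carbons():
        groups.setdefault(ranks[i - 1], []).append(i)
    classes = [tuple(sorted(v)) for _, v in sorted(groups.items())]
    class_of = {}
    for cid, atoms in enumerate(classes, start=1):
        for a in atoms:
            class_of[a] = cid
    return EquivalencePartition(classes=classes, class_of=class_of)


def canonical_identifier(m: Molecule) -> CanonicalIdentifier:
    """Permutation-invariant identifier (canonical SMILES over connectivity,
    charge and H-count layers); the dedup key throughout the pipeline."""
    return CanonicalIdentifier(Chem.MolToSmiles(m.to_rdkit()))


def substructure_match(
    m: Molecule, query: Molecule, all_mappings: bool = True
) -> tuple[bool, list[dict[int, int]]]:
    """Subgraph-isomorphism on element + bond order; aromatic matches
    aromatic.  Mappings are query-atom -> molecule-atom, 1-based."""
    target = m.to_rdkit()
    q = query.to_rdkit()
    if all_mappings:
        raw = target.GetSubstructMatches(q, uniquify=False, maxMatches=100000)
    else:
        hit = target.GetSubstructMatch(q)
        raw = (hit,) if hit else ()
    mappings = [
        {qi + 1: ti + 1 for qi, ti in enumerate(match)} for match in raw
    ]
    return bool(mappings), mappings


def molecular_weight(m: Molecule) -> float:
    """Average molecular weight in amu, implicit hydrogens included."""
    return float(Descriptors.MolWt(m.to_rdkit()))
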