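"""Structure model, molfile I/O, formal checks, symmetry and identifiers."""

import numpy as np
import pytest

from c13referee.chem_core import (
    MolfileParseError,
    canonical_identifier,
    check_structure,
    equivalence_classes,
    from_smiles,
    molecular_weight,
    parse_molfile,
    parse_sdf,
    substructure_match,
    write_molfile,
    write_sdf,
)
from c13referee.fixtures import _CHROMONE_SMILES, named_molecule

from conftest import permute_molecule


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_parse_benzene_roundtrip(benzene):
    block = write_molfile(benzene)
    m = parse_molfile(block)
    assert len(m.atoms) == 6
    assert all(a.element == "C" for a in m.atoms)
    assert len(m.bonds) == 6
    assert all(b.aromatic for b in m.bonds)
    assert canonical_identifier(m) == canonical_identifier(benzene)


def test_sdf_three_records_in_order():
    mols = [from_smiles(s, n) for s, n in
            [("CCO", "ethanol"), ("c1ccccc1", "benzene"), ("CC(=O)C", "acetone")]]
    text = write_sdf(mols, [{"NAME": m.name} for m in mols])
    parsed = parse_sdf(text)
    assert [m.name for m in parsed] == ["ethanol", "benzene", "acetone"]
    assert [canonical_identifier(m).text for m in parsed] == [
        canonical_identifier(m).text for m in mols
    ]


def test_bond_to_nonexistent_atom_cites_line():
    decane = write_molfile(from_smiles("C" * 10))
    lines = decane.splitlines()
    # first bond line is line 15 (header 1-3, counts 4, atoms 5-14)
    lines[14] = "  1 99  1  0"
    with pytest.raises(MolfileParseError) as err:
        parse_molfile("\n".join(lines))
    assert "99" in str(err.value)
    assert err.value.line == 15


def test_v3000_rejected():
    text = "\n\n\n  0  0  0     0  0            999 V3000\nM  END\n"
    with pytest.raises(MolfileParseError, match="V3000"):
        parse_molfile(text)


def test_malformed_counts_line():
    with pytest.raises(MolfileParseError):
        parse_molfile("name\n\n\nxx yy\n")


@pytest.mark.parametrize(
    "smiles",
    ["CCO", "Cc1ccccc1", "O=C1C=COc2ccccc21", "CC(C)Cc1ccc(C)cc1", "C[N+](C)(C)C"],
)
def test_roundtrip_preserves_structure(smiles):
    m = from_smiles(smiles)
    again = parse_molfile(write_molfile(m))
    assert canonical_identifier(again) == canonical_identifier(m)


# ---------------------------------------------------------------------------
# formal checks
# ---------------------------------------------------------------------------


def test_pentavalent_carbon_is_valence_error():
    # methane block edited to bond the carbon to five explicit hydrogens
    block = """pentavalent
  c13referee

  6  5  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.0000    0.0000    0.0000 H   0  0
   -1.0000    0.0000    0.0000 H   0  0
    0.0000    1.0000    0.0000 H   0  0
    0.0000   -1.0000    0.0000 H   0  0
    1.0000    1.0000    0.0000 H   0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
M  END
"""
    m = parse_molfile(block)
    result = check_structure(m)
    assert not result.ok
    assert any(f.code == "valence" and 1 in f.atoms for f in result.errors())


def test_ethanol_is_clean():
    result = check_structure(from_smiles("CCO"))
    assert result.ok
    assert result.findings == []


def test_unspecified_stereocenter_is_warning_only():
    m = from_smiles("CC(O)CC")  # butan-2-ol, no wedge information
    result = check_structure(m)
    assert result.ok
    assert any(f.code == "stereocenter" for f in result.findings)


def test_net_charge_reported():
    m = from_smiles("C[N+](C)(C)C")
    result = check_structure(m)
    assert result.ok
    assert any(f.code == "net-charge" for f in result.findings)


# ---------------------------------------------------------------------------
# symmetry classes
# ---------------------------------------------------------------------------


def test_benzene_one_class(benzene):
    assert equivalence_classes(benzene).n_classes == 1


def test_toluene_five_classes(toluene):
    part = equivalence_classes(toluene)
    assert part.n_classes == 5
    assert sorted(len(c) for c in part.classes) == [1, 1, 1, 2, 2]


@pytest.mark.parametrize("smiles", ["Cc1ccccc1", "Oc1ccc(O)cc1", "CCCCCC",
                                    _CHROMONE_SMILES])
def test_classes_stable_under_permutation(smiles):
    m = from_smiles(smiles)
    reference = sorted(len(c) for c in equivalence_classes(m).classes)
    rng = np.random.default_rng(11)
    for _ in range(100):
        p = permute_molecule(m, rng)
        assert sorted(len(c) for c in equivalence_classes(p).classes) == reference


def test_classes_never_coarser_than_element_partition(std_db):
    for rec in std_db[::15]:
        part = equivalence_classes(rec.molecule)
        for atoms in part.classes:
            elements = {rec.molecule.atom(a).element for a in atoms}
            assert elements == {"C"}


# ---------------------------------------------------------------------------
# canonical identifier
# ---------------------------------------------------------------------------


def test_identifier_permutation_invariant():
    esculetin = named_molecule("esculetin")
    ref = canonical_identifier(esculetin).text
    rng = np.random.default_rng(5)
    for _ in range(50):
        assert canonical_identifier(permute_molecule(esculetin, rng)).text == ref


def test_esculetin_and_chromone_isomer_distinct():
    a = canonical_identifier(named_molecule("esculetin"))
    b = canonical_identifier(named_molecule("5,7-dihydroxy-2-hydroxymethylchromone"))
    assert a != b


def test_methane_vs_ethane_distinct():
    assert canonical_identifier(from_smiles("C")) != canonical_identifier(
        from_smiles("CC")
    )


def test_no_identifier_collisions_in_database(std_db):
    idents = [canonical_identifier(r.molecule).text for r in std_db]
    assert len(set(idents)) == len(idents)


# ---------------------------------------------------------------------------
# substructure matching and molecular weight
# ---------------------------------------------------------------------------


def test_chromone_query_matches_apigenin():
    chromone = from_smiles(_CHROMONE_SMILES)
    apigenin = from_smiles("O=C1C=C(Oc2cc(O)cc(O)c12)c1ccc(O)cc1")
    assert substructure_match(apigenin, chromone, all_mappings=False)[0]


def test_chromone_query_misses_steroid_skeleton():
    chromone = from_smiles(_CHROMONE_SMILES)
    steroid = from_smiles("C1CCC2(C)C(C1)CCC1C2CCC2(C)C1CCC2")
    assert not substructure_match(steroid, chromone, all_mappings=False)[0]


def test_benzene_automorphism_count(benzene):
    ok, mappings = substructure_match(benzene, benzene)
    assert ok
    assert len(mappings) == 12


@pytest.mark.parametrize(
    "smiles,expected",
    [("C", 16.04), ("c1ccccc1", 78.11), ("O", 18.02)],
)
def test_molecular_weight(smiles, expected):
    assert molecular_weight(from_smiles(smiles)) == pytest.approx(expected, abs=0.01)
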