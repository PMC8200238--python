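"""The synthetic shift model, fixture families and the error injector."""

import numpy as np
import pytest

from c13referee.chem_core import equivalence_classes, from_smiles
from c13referee.fixtures import (
    ErrorInjection,
    IncrementShiftModel,
    inject_errors,
    make_peaklist,
    make_reference_set,
)
from c13referee.hose import build_index, write_reference_sdf
from c13referee.similarity import find_identical_patterns
from c13referee.verification import verify


# ---------------------------------------------------------------------------
# model anchors
# ---------------------------------------------------------------------------


def test_alkane_chain_anchor_values(model):
    c14 = from_smiles("C" * 14)
    # terminal quartet ~14, the two chain-end triplets ~22/~32, interior ~29
    assert model.shift(c14, 1) == pytest.approx(14.0, abs=1.0)
    assert model.shift(c14, 2) == pytest.approx(22.9, abs=1.0)
    assert model.shift(c14, 3) == pytest.approx(32.0, abs=1.0)
    assert model.shift(c14, 7) == pytest.approx(29.5, abs=1.0)


def test_benzene_anchor(model, benzene):
    assert model.shift(benzene, 1) == pytest.approx(128.5)


def test_bromine_ipso_effect_is_six_ppm(model):
    brbz = from_smiles("Brc1ccccc1")
    ipso = next(
        i for i in brbz.carbons()
        if any(brbz.atom(n).element == "Br" for n in brbz.neighbors(i))
    )
    assert 128.5 - model.shift(brbz, ipso) == pytest.approx(6.0, abs=0.1)


def test_nitrile_ipso_effect_is_sixteen_ppm(model):
    cnbz = from_smiles("N#Cc1ccccc1")
    ipso = next(
        i for i in cnbz.carbons()
        if any(b.aromatic for b in cnbz.bonds_of(i))
        and any(not cnbz.bonds_of(i)[k].aromatic for k in range(len(cnbz.bonds_of(i))))
    )
    assert 128.5 - model.shift(cnbz, ipso) == pytest.approx(16.0, abs=0.1)


def test_symmetry_equivalent_carbons_share_one_shift(std_db):
    for rec in std_db[::10]:
        part = equivalence_classes(rec.molecule)
        for atoms in part.classes:
            values = {rec.shifts[a] for a in atoms}
            assert len(values) == 1


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------


def test_alkane_family_c6_to_c20():
    records = make_reference_set("alkanes", 15, seed=7)
    assert len(records) == 15
    assert records[0].name == "n-C6"
    assert records[-1].name == "n-C20"
    c14 = next(r for r in records if r.name == "n-C14")
    assert c14.shifts[1] == pytest.approx(13.7, abs=1.6)  # includes noise


def test_seed_repetition_is_byte_identical():
    a = write_reference_sdf(make_reference_set("benzenes", 20, seed=11))
    b = write_reference_sdf(make_reference_set("benzenes", 20, seed=11))
    assert a == b
    c = write_reference_sdf(make_reference_set("benzenes", 20, seed=12))
    assert a != c


def test_benzene_family_has_three_plus_brominated_members():
    records = make_reference_set("benzenes", 30, seed=7)
    brominated = [
        r for r in records
        if any(a.element == "Br" for a in r.molecule.atoms)
    ]
    assert len(brominated) >= 4  # bromobenzene plus >=3 companions


def test_every_family_size_respected(model):
    for family, size in (("alkanes", 5), ("benzenes", 12), ("chromones", 10),
                         ("fused", 8)):
        records = make_reference_set(family, size, seed=2, model=model)
        assert len(records) == size


def test_uncorrupted_entries_verify_all_green(std_db, std_index):
    # leave-in exact-match verification: the database contains the compound
    for rec in std_db[::6]:
        report = verify(
            rec.molecule, make_peaklist(rec), std_index, min_contributors=1
        )
        assert report.all_green, rec.name


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


def test_digit_drop_subtracts_exactly_one_hundred(std_db):
    droppable = next(
        i for i, r in enumerate(std_db)
        if any(100 <= v < 200 for v in r.shifts.values())
    )
    (entry,) = inject_errors(
        std_db, [ErrorInjection("digit-drop", seed=1, params={"record": droppable})]
    )
    assert entry.truth["original"] - entry.truth["corrupted"] == pytest.approx(100.0)
    corrupted_signal = entry.peaklist.signals[entry.truth["signal"]]
    assert corrupted_signal.shift == pytest.approx(entry.truth["corrupted"])


def test_duplicate_injection_found_by_pattern_scan(std_db):
    (entry,) = inject_errors(
        std_db,
        [ErrorInjection("duplicate-data", seed=2,
                        params={"record": 30, "source_record": 55})],
    )
    matches = find_identical_patterns(
        entry.peaklist, std_db, tolerance=0.0, query_structure=entry.molecule
    )
    flagged = [m.record_id for m in matches if m.same_data_different_structure]
    assert flagged == [55]


def test_swap_injection_reproduces_misassignment(std_db, std_index):
    alkane = next(i for i, r in enumerate(std_db) if r.name == "n-C12")
    (entry,) = inject_errors(
        std_db, [ErrorInjection("assignment-swap", seed=4,
                                params={"record": alkane})]
    )
    i, j = entry.truth["signals"]
    original = make_peaklist(std_db[alkane])
    assert entry.peaklist.signals[i].shift == original.signals[j].shift
    assert entry.peaklist.signals[j].shift == original.signals[i].shift


def test_sequence_shift_rotates_assignment_vector(std_db):
    (entry,) = inject_errors(
        std_db, [ErrorInjection("sequence-shift", seed=5, params={"record": 3})]
    )
    original = [s.shift for s in make_peaklist(std_db[3]).signals]
    rotated = [s.shift for s in entry.peaklist.signals]
    assert rotated == original[1:] + original[:1]


def test_wrong_structure_is_a_detectable_positional_isomer(std_db, model):
    from c13referee.chem_core import canonical_identifier
    from c13referee.fixtures import _spectrum_change

    target = next(i for i, r in enumerate(std_db) if r.name == "para-Me-OMe-benzene")
    (entry,) = inject_errors(
        std_db, [ErrorInjection("wrong-structure", seed=6,
                                params={"record": target})]
    )
    assert canonical_identifier(entry.molecule) != canonical_identifier(
        entry.record.molecule
    )
    assert _spectrum_change(model, entry.record.molecule, entry.molecule) >= 6.0
    # experimental data stay those of the true compound
    true_shifts = sorted(
        {v for v in entry.record.shifts.values()}
    )
    assert sorted(s.shift for s in entry.peaklist.signals) == pytest.approx(true_shifts)
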