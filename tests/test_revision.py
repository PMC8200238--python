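"""Structure generator: flagging, candidate enumeration and ranking."""

import numpy as np
import pytest

from c13referee.chem_core import canonical_identifier, equivalence_classes, from_smiles
from c13referee.fixtures import IncrementShiftModel, _positional_isomer, make_peaklist
from c13referee.hose import build_index, predict_shifts
from c13referee.revision import (
    flag_positions,
    generate_candidates,
    rank_candidates,
)
from c13referee.verification import PeakList, Signal, verify


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------


def _report_for(rec, index, **kw):
    return verify(rec.molecule, make_peaklist(rec), index, **kw)


def test_all_green_report_flags_nothing(std_db, std_index):
    report = _report_for(std_db[30], std_index, min_contributors=1)
    assert report.all_green
    assert flag_positions(report, molecule=std_db[30].molecule) == set()


def test_red_class_flags_all_symmetric_atoms(std_db, std_index):
    rec = std_db[30]
    p = make_peaklist(rec)
    # corrupt the signal of a 2-atom symmetry class by +15 ppm
    part = equivalence_classes(rec.molecule)
    target = next(i for i, s in enumerate(p.signals) if len(s.atoms) == 2)
    p.signals[target].shift += 15.0
    report = verify(rec.molecule, p, std_index, min_contributors=1)
    flagged = flag_positions(report, level="red", include_neighbors=False)
    assert set(p.signals[target].atoms) <= flagged


def test_localized_double_bond_deviation_flags_that_pair():
    # enone scaffold with both olefinic carbons reported ~20 ppm off
    m = from_smiles("O=C1CCC(O)C=C1", "toy-enone")
    model = IncrementShiftModel()
    shifts = model.spectrum(m)
    from c13referee.hose import ReferenceRecord

    index = build_index([ReferenceRecord(m, shifts, name="self")])
    part = equivalence_classes(m)
    olefinic = [
        i for i in m.carbons()
        if any(b.order == 2 and not b.aromatic
               and m.atom(b.other(i)).element == "C" for b in m.bonds_of(i))
    ]
    signals = []
    for atoms in part.classes:
        v = shifts[atoms[0]]
        if atoms[0] in olefinic:
            v += 20.0
        signals.append(Signal(v, atoms))
    report = verify(m, PeakList(signals=signals), index, min_contributors=1)
    flagged = flag_positions(report, level="red", include_neighbors=False)
    assert flagged == set(olefinic)


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------


def test_para_hydroxy_relocations_present():
    pcresol = from_smiles("Cc1ccc(O)cc1", "p-cresol")
    oh = next(i for i in range(1, pcresol.n_atoms + 1)
              if pcresol.atom(i).element == "O")
    site = pcresol.neighbors(oh)[0]
    candidates, truncated = generate_candidates(pcresol, {site, oh}, budget=500)
    assert not truncated
    ids = {c.identifier for c in candidates}
    assert canonical_identifier(from_smiles("Cc1ccccc1O")).text in ids  # ortho
    assert canonical_identifier(from_smiles("Cc1cccc(O)c1")).text in ids  # meta


def test_hydroxy_ketone_swap_reachable():
    inp = from_smiles("OC1CCC(=O)C=C1")
    alternative = from_smiles("O=C1CCC(O)C=C1")
    candidates, _ = generate_candidates(
        inp, set(range(1, inp.n_atoms + 1)), budget=500
    )
    ids = {c.identifier for c in candidates}
    assert canonical_identifier(alternative).text in ids


def test_candidates_have_unique_identifiers_and_pass_check():
    from c13referee.chem_core import check_structure

    m = from_smiles("COc1ccc(Br)cc1C")
    candidates, _ = generate_candidates(m, set(range(1, m.n_atoms + 1)), budget=300)
    ids = [c.identifier for c in candidates]
    assert len(set(ids)) == len(ids)
    for c in candidates:
        assert check_structure(c.molecule).ok


def test_empty_flagged_set_returns_input_only():
    m = from_smiles("Cc1ccccc1")
    candidates, truncated = generate_candidates(m, set(), budget=100)
    assert len(candidates) == 1
    assert candidates[0].is_input
    assert not truncated


def test_budget_truncation_flagged():
    m = from_smiles("COc1ccc(Br)cc1C")
    candidates, truncated = generate_candidates(m, set(range(1, m.n_atoms + 1)),
                                                budget=5)
    assert len(candidates) == 5
    assert truncated


def test_formula_preserved_by_default_moves():
    from c13referee.chem_core import molecular_weight

    m = from_smiles("Oc1ccc(C=O)cc1")
    ref = molecular_weight(m)
    candidates, _ = generate_candidates(m, set(range(1, m.n_atoms + 1)), budget=200)
    for c in candidates:
        assert molecular_weight(c.molecule) == pytest.approx(ref, abs=1e-6)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def test_true_structure_ranks_first_on_its_own_spectrum(std_db, std_index):
    rec = std_db[40]
    preds = predict_shifts(rec.molecule, std_index, min_contributors=1)
    p = PeakList(signals=[Signal(pr.shift) for pr in preds if pr.predicted])
    candidates, _ = generate_candidates(
        rec.molecule, set(range(1, rec.molecule.n_atoms + 1)), budget=100
    )
    ranked = rank_candidates(candidates, p, std_index, min_contributors=1)
    assert ranked.input_rank == 1
    assert ranked.candidates[0].score == pytest.approx(0.0, abs=1e-9)
    assert not ranked.revision_recommended


def test_scores_monotone_and_ranks_dense(std_db, std_index):
    rec = std_db[45]
    p = make_peaklist(rec)
    candidates, _ = generate_candidates(
        rec.molecule, set(range(1, rec.molecule.n_atoms + 1)), budget=60
    )
    ranked = rank_candidates(candidates, p, std_index)
    scores = [c.score for c in ranked.candidates]
    assert scores == sorted(scores)
    assert [c.rank for c in ranked.candidates] == list(range(1, len(scores) + 1))


def test_input_proposal_always_present_in_ranking(std_db, std_index):
    rec = std_db[50]
    p = make_peaklist(rec)
    candidates, _ = generate_candidates(
        rec.molecule, set(range(1, rec.molecule.n_atoms + 1)), budget=40
    )
    ranked = rank_candidates(candidates, p, std_index)
    assert any(c.is_input for c in ranked.candidates)
    assert ranked.input_rank >= 1


def test_wrong_proposal_recovered(std_db, std_index, model):
    rec = next(r for r in std_db if r.name == "para-Me-OMe-benzene")
    rid = std_db.index(rec)
    wrong, _ = _positional_isomer(rec.molecule, np.random.default_rng(3), model=model)
    spec = model.spectrum(rec.molecule,
                          rng=np.random.default_rng(9), noise_sigma=1.0)
    part = equivalence_classes(rec.molecule)
    p = PeakList(signals=[Signal(spec[a[0]]) for a in part.classes])
    report = verify(wrong, p, std_index, mode="auto", exclude_records={rid})
    flagged = flag_positions(report, level="yellow", molecule=wrong)
    candidates, trunc = generate_candidates(wrong, flagged, budget=1000)
    ranked = rank_candidates(candidates, p, std_index,
                             exclude_records={rid}, truncated=trunc)
    true_id = canonical_identifier(rec.molecule).text
    winner = ranked.candidates[0]
    assert winner.identifier == true_id
    assert ranked.revision_recommended
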