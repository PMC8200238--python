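"""Peak-list checks, assignment matching and the coincidence report."""

import itertools

import numpy as np
import pytest

from c13referee.chem_core import equivalence_classes, from_smiles
from c13referee.hose import ShiftPrediction, build_index
from c13referee.verification import (
    ClassificationThresholds,
    PeakList,
    Signal,
    assign_signals,
    check_peaklist,
    classify_deviation,
    read_peaklists,
    verify,
    write_peaklists,
)
from c13referee.fixtures import make_peaklist, make_reference_set


def _fake_predictions(shifts):
    return [
        ShiftPrediction(i + 1, (i + 1,), s, 3, 0.1, 4, "matched")
        for i, s in enumerate(shifts)
    ]


# ---------------------------------------------------------------------------
# peak-list file format
# ---------------------------------------------------------------------------


def test_peaklist_roundtrip():
    lists = [
        PeakList(
            signals=[
                Signal(14.1, (1,)),
                Signal(128.5, (2, 3), xgroup="a"),
                Signal(77.0),
            ],
            key="cmpd-1",
        ),
        PeakList(signals=[Signal(10.0)], key="cmpd-2"),
    ]
    again = read_peaklists(write_peaklists(lists))
    assert [p.key for p in again] == ["cmpd-1", "cmpd-2"]
    assert again[0].signals[1].atoms == (2, 3)
    assert again[0].signals[1].xgroup == "a"
    assert again[0].signals[2].atoms == ()
    assert again[0].shifts == pytest.approx([14.1, 128.5, 77.0])


# ---------------------------------------------------------------------------
# formal checks
# ---------------------------------------------------------------------------


def test_signal_count_mismatch_flagged(benzene):
    p = PeakList(signals=[Signal(128.5), Signal(127.9)])
    findings = check_peaklist(benzene, p)
    assert any(f.code == "signal-count" for f in findings)


def test_symmetry_violation_on_para_disubstituted_ring():
    # para-disubstituted ring: 2'/6' must resonate at one value
    m = from_smiles("Cc1ccc(O)cc1")
    part = equivalence_classes(m)
    pair = next(c for c in part.classes if len(c) == 2)
    p = PeakList(
        signals=[Signal(130.1, (pair[0],)), Signal(133.0, (pair[1],))]
    )
    findings = check_peaklist(m, p)
    assert any(f.code == "symmetry" for f in findings)


def test_consistent_assigned_list_is_clean(model):
    rec = make_reference_set("benzenes", 8, seed=2)[4]
    findings = check_peaklist(rec.molecule, make_peaklist(rec))
    assert findings == []


def test_non_carbon_assignment_is_error():
    m = from_smiles("CCO")
    p = PeakList(signals=[Signal(60.0, (3,)), Signal(18.0, (1,))])
    findings = check_peaklist(m, p)
    assert any(f.code == "assignment-atom" and f.severity == "error" for f in findings)


# ---------------------------------------------------------------------------
# assignment matcher
# ---------------------------------------------------------------------------


def test_unique_nearest_pairing():
    preds = _fake_predictions([14.1, 22.9, 32.1])
    p = PeakList(signals=[Signal(32.0), Signal(14.0), Signal(23.0)])
    assignment = assign_signals(preds, p, mode="auto")
    pairing = {cid: p.signals[sig].shift for cid, sig, _ in assignment.pairs}
    assert pairing == {1: 14.0, 2: 23.0, 3: 32.0}
    # |14.0-14.1| + |23.0-22.9| + |32.0-32.1|
    assert assignment.total_abs_delta(preds, p) == pytest.approx(0.3)


def test_exact_match_costs_zero():
    preds = _fake_predictions([14.1, 22.9, 32.1])
    p = PeakList(signals=[Signal(22.9), Signal(32.1), Signal(14.1)])
    assignment = assign_signals(preds, p, mode="auto")
    assert assignment.total_abs_delta(preds, p) == pytest.approx(0.0)


@pytest.mark.parametrize("trial", range(5))
def test_matcher_equals_bruteforce_on_random_instances(trial):
    rng = np.random.default_rng(100 + trial)
    for _ in range(40):
        n = int(rng.integers(2, 8))
        pred_shifts = rng.uniform(0, 200, n)
        exp = rng.permutation(pred_shifts) + rng.normal(0, 3, n)
        preds = _fake_predictions(list(pred_shifts))
        p = PeakList(signals=[Signal(float(v)) for v in exp])
        assignment = assign_signals(preds, p, mode="auto")
        observed = assignment.total_abs_delta(preds, p)
        best = min(
            sum(abs(a - b) for a, b in zip(pred_shifts, perm))
            for perm in itertools.permutations(exp)
        )
        assert observed == pytest.approx(best, abs=1e-9)


def test_exchangeable_group_optimized_within_group():
    preds = _fake_predictions([120.0, 150.0])
    # authors tagged the two signals as exchangeable, in the wrong order
    p = PeakList(
        signals=[Signal(149.8, (2,), xgroup="x"), Signal(120.3, (1,), xgroup="x")]
    )
    assignment = assign_signals(preds, p, mode="authors")
    pairing = {cid: p.signals[sig].shift for cid, sig, _ in assignment.pairs}
    assert pairing == {1: 120.3, 2: 149.8}
    provenance = {prov for _, _, prov in assignment.pairs}
    assert provenance == {"exchangeable"}


def test_surplus_signals_reported():
    preds = _fake_predictions([10.0, 20.0])
    p = PeakList(signals=[Signal(10.1), Signal(19.9), Signal(55.0)])
    assignment = assign_signals(preds, p, mode="auto")
    assert len(assignment.pairs) == 2
    assert assignment.unmatched_signals == [2]
    assert any(f.code == "unmatched-signals" for f in assignment.findings)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "delta,color",
    [
        (3.0, "green"),
        (-4.99, "green"),
        (5.0, "yellow"),
        (7.5, "yellow"),
        (10.0, "yellow"),
        (-10.0, "yellow"),
        (10.01, "red"),
        (100.0, "red"),
    ],
)
def test_color_boundaries(delta, color):
    assert classify_deviation(delta, ClassificationThresholds()) == color


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        ClassificationThresholds(green_below=12, red_above=10)


# ---------------------------------------------------------------------------
# verify
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_db(model):
    return make_reference_set("benzenes", 40, seed=2)


@pytest.fixture(scope="module")
def small_index(small_db):
    return build_index(small_db)


def test_correct_assignment_verifies_all_green(small_db, small_index):
    rec = small_db[10]
    report = verify(
        rec.molecule, make_peaklist(rec), small_index, min_contributors=1
    )
    assert report.status == "ok"
    assert report.all_green
    assert report.delta_mean < 1.5
    assert not report.gross_error


def test_swapped_assignment_caught_and_repaired(small_db, small_index):
    rec = small_db[10]
    p = make_peaklist(rec)
    # swap an aliphatic against an aromatic class (far apart in ppm)
    lo = min(range(len(p.signals)), key=lambda i: p.signals[i].shift)
    hi = max(range(len(p.signals)), key=lambda i: p.signals[i].shift)
    p.signals[lo].shift, p.signals[hi].shift = (
        p.signals[hi].shift, p.signals[lo].shift,
    )
    authors = verify(rec.molecule, p, small_index, min_contributors=1)
    non_green = [d for d in authors.deviations
                 if d.delta is not None and d.color != "green"]
    assert len(non_green) >= 2
    auto = verify(rec.molecule, p, small_index, min_contributors=1, mode="auto")
    assert auto.all_green


def test_scrambled_alkyl_chain_repaired_by_auto_assignment():
    records = make_reference_set("alkanes", 10, seed=2)
    index = build_index(records)
    rec = records[4]
    p = make_peaklist(rec)
    shifts = [s.shift for s in p.signals]
    for s, v in zip(p.signals, shifts[::-1]):  # terminal pattern scrambled
        s.shift = v
    auto = verify(rec.molecule, p, index, min_contributors=1, mode="auto")
    assert auto.all_green


def test_auto_assignment_never_worse_than_authors(small_db, small_index):
    rng = np.random.default_rng(17)
    for rec in small_db[::7]:
        p = make_peaklist(rec)
        shifts = [s.shift for s in p.signals]
        rng.shuffle(shifts)
        for s, v in zip(p.signals, shifts):
            s.shift = v
        authors = verify(rec.molecule, p, small_index, min_contributors=1)
        auto = verify(rec.molecule, p, small_index, min_contributors=1, mode="auto")
        a_total = sum(abs(d.delta) for d in authors.deviations if d.delta is not None)
        b_total = sum(abs(d.delta) for d in auto.deviations if d.delta is not None)
        assert b_total <= a_total + 1e-9


def test_all_unpredicted_reports_insufficient_data(toluene):
    report = verify(toluene, PeakList(signals=[Signal(21.0)]), build_index([]))
    assert report.status == "insufficient reference data"
    assert report.delta_mean is None


def test_structure_error_short_circuits(small_index):
    from c13referee.chem_core import parse_molfile

    block = """bad
  c13referee

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    0.0000    0.0000    0.0000 F   0  0
  1  2  3  0
M  END
"""
    m = parse_molfile(block)  # F with a triple bond: valence error
    report = verify(m, PeakList(signals=[Signal(50.0)]), small_index)
    assert report.status == "structure-error"
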