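"""Peak assignment, match classification and fit statistics."""

import warnings
from decimal import Decimal

import numpy as np
import pytest

import massladder as ml
from massladder.data import SSGII70


def test_read_peaklist_fixture(table1_peaks):
    assert len(table1_peaks) == 12
    assert table1_peaks[0].mz == Decimal("7930.24")


def test_read_peaklist_edge_cases(tmp_path):
    empty = tmp_path / "empty.txt"
    empty.write_text("# only a comment\n\n")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        assert ml.read_peaklist(empty) == []
    assert caught
    bad = tmp_path / "bad.txt"
    bad.write_text("1234.5\nnot-a-number\n")
    with pytest.raises(ValueError, match="line 2"):
        ml.read_peaklist(bad)
    two_col = tmp_path / "two.txt"
    two_col.write_text("1000.5, 42\n1000.5 7\n")
    peaks = ml.read_peaklist(two_col)
    assert [p.intensity for p in peaks] == [42.0, 7.0]
    out = tmp_path / "round.txt"
    ml.write_peaklist(peaks, out)
    assert [p.mz for p in ml.read_peaklist(out)] == [p.mz for p in peaks]


@pytest.mark.parametrize(
    "observed, match, expected",
    [
        ("7805.98", "7805.64", "integer"),
        ("7930.24", "7931.75", "next_integer"),
        ("7628.30", "7620.46", "loose"),
    ],
)
def test_classify_match_published_pairs(observed, match, expected):
    assert ml.classify_match(Decimal(observed), Decimal(match)) == expected


def test_classification_symmetry_on_grid():
    values = [Decimal(v) / 4 for v in range(4000, 4040)]
    for o in values:
        for m in values:
            assert ml.classify_match(o, m) == ml.classify_match(m, o)


def test_best_assignment_examples(ladder_full):
    a = ml.best_assignment(ml.Peak(Decimal("6109.35")), ladder_full)
    assert (a.cell.mer, a.cell.waters) == (54, 8)
    assert a.match == Decimal("6102.85")
    ramp = ml.best_assignment(ml.Peak(Decimal("1149")), ladder_full)
    assert (ramp.cell.mer, ramp.cell.waters) == (11, 6)
    assert ramp.cell.integer_part == 1153
    # a peak equal to a cell's reported mass hits that cell at deviation 0
    cell = ladder_full.cell(50, 5, True)
    hit = ml.best_assignment(ml.Peak(cell.printed), ladder_full)
    assert hit.cell is cell and hit.deviation == 0
    # out-of-window peak
    assert ml.best_assignment(ml.Peak(Decimal("20000")), ladder_full) is None


def test_low_mass_gate_flag(ladder_full):
    low = ml.best_assignment(ml.Peak(Decimal("699")), ladder_full)
    assert low.below_gate
    high = ml.best_assignment(ml.Peak(Decimal("6109.35")), ladder_full)
    assert not high.below_gate


def test_best_assignment_agrees_with_exhaustive_search(ladder_full):
    rng = np.random.default_rng(42)
    cells = ladder_full.canonical_cells()
    for mz in rng.uniform(700, 8200, size=200):
        peak = ml.Peak(Decimal(f"{mz:.4f}"))
        got = ml.best_assignment(peak, ladder_full)
        brute = min(cells, key=lambda c: (abs(peak.mz - c.mass), c.waters, -c.mer))
        if abs(peak.mz - brute.mass) > 10:
            assert got is None
        else:
            assert got.cell is brute


def test_fit_report_published_statistics(table1_peaks):
    cmp_ = ml.compare_truncation_models(table1_peaks, SSGII70)
    rep = cmp_.cterm
    r3 = rep.round3
    assert r3(rep.mean_deviation) == Decimal("2.655")
    assert r3(rep.mean_pct_error) == Decimal("0.035")
    assert rep.count_integer_or_next == 7
    assert r3(rep.sum_ratio_pct) == Decimal("100.008")
    assert r3(rep.chi_sq_quantity) == Decimal("0.024")
    assert rep.sum_observed == Decimal("91120.98")
    assert rep.sum_matched == Decimal("91113.76")


def test_fit_report_single_exact_pair(ladder_full):
    cell = ladder_full.cell(65, 2, True)
    a = ml.best_assignment(ml.Peak(cell.printed), ladder_full)
    rep = ml.fit_report([a])
    assert rep.mean_deviation == 0
    assert rep.mean_pct_error == 0
    assert rep.sum_ratio_pct == 100
    assert rep.chi_sq_quantity == 0


def test_fit_report_matches_brute_force_sums(ladder_full):
    rng = np.random.default_rng(7)
    peaks = [ml.Peak(Decimal(f"{x:.2f}")) for x in rng.uniform(6800, 8200, size=30)]
    assigns = [a for p in peaks if (a := ml.best_assignment(p, ladder_full))]
    rep = ml.fit_report(assigns)
    # independent summation oracle
    obs = sum(a.peak.mz for a in assigns)
    match = sum(a.match for a in assigns)
    assert rep.sum_observed == obs and rep.sum_matched == match
    assert rep.n * rep.mean_signed_difference == obs - match
    chi = sum((a.peak.mz - a.match) ** 2 / a.match for a in assigns)
    assert rep.chi_sq_quantity == chi
    with pytest.raises(ValueError):
        ml.fit_report([])


def test_compare_truncation_models_verdict(table1_peaks):
    cmp_ = ml.compare_truncation_models(table1_peaks, SSGII70)
    assert cmp_.cterm.count_integer_or_next == 7
    assert cmp_.nterm.count_integer_or_next == 3
    assert cmp_.verdict == "cterm"
    empty = ml.compare_truncation_models([], SSGII70)
    assert empty.verdict is None and empty.cterm is None and empty.nterm is None


def test_superheavyweight_homodimer(ladder_full):
    peaks = [ml.Peak(Decimal("4755.85")), ml.Peak(Decimal("9509.01"))]
    found = ml.superheavyweight_search(peaks, ladder_full)
    assert len(found) == 1
    shw = found[0]
    assert shw.peak.mz == Decimal("9509.01")
    assert shw.label == "homodimer" and shw.copies == 2
    assert (shw.cells[0].mer, shw.cells[0].waters) == (43, 7)


def test_superheavyweight_heterodimer(ladder_full):
    # the published case is "roughly the sum" (15 Da off), so a wider window
    peaks = [ml.Peak(Decimal("3791")), ml.Peak(Decimal("4607")), ml.Peak(Decimal("8383"))]
    found = ml.superheavyweight_search(peaks, ladder_full, window=20)
    assert len(found) == 1
    shw = found[0]
    assert shw.label == "heterodimer"
    assert sorted(c.mer for c in shw.cells) == [33, 40]


def test_superheavyweight_empty_when_no_heavy_peaks(ladder_full):
    peaks = [ml.Peak(Decimal("4755.85"))]
    assert ml.superheavyweight_search(peaks, ladder_full) == []
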