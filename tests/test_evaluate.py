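"""Tests for confusion tables, PPA/NPA, ROC cutoff analysis and kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stethosim import (
    ConfusionTable, cohen_kappa, cohort_summary, confusion,
    optimal_cutoff_interval, ppa_npa, roc,
)
from stethosim.errors import DegenerateReferenceError, InvalidParameterError


def brute_force_operating_points(scores: pd.Series, ref: pd.Series):
    """Independent oracle: evaluate *every* cutoff on a dense grid spanning
    below the minimum to above the maximum score and collect the distinct
    confusion tables in cutoff order."""
    vals = np.sort(np.unique(scores.to_numpy()))
    grid = [vals[0] - 1.0]
    for a, b in zip(vals[:-1], vals[1:]):
        grid += [a, (a + b) / 2]
    grid += [vals[-1], vals[-1] + 1.0]
    tables = []
    for c in grid:
        ct = confusion(scores > c, ref)
        if not tables or tables[-1][1] != ct:
            tables.append((c, ct))
    return tables


class TestConfusion:
    def test_perfect_agreement(self):
        ref = pd.Series([True] * 3 + [False] * 5,
                        index=[f"r{i}" for i in range(8)])
        ct = confusion(ref, ref)
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (3, 5, 0, 0)

    def test_all_negative_prediction(self):
        idx = [f"r{i}" for i in range(8)]
        ref = pd.Series([True] * 3 + [False] * 5, index=idx)
        pred = pd.Series(False, index=idx)
        ct = confusion(pred, ref)
        assert (ct.fn, ct.tn, ct.tp, ct.fp) == (3, 5, 0, 0)

    def test_disjoint_recording_sets_rejected(self):
        with pytest.raises(InvalidParameterError):
            confusion(pd.Series({"a": True}), pd.Series({"b": True}))


class TestPpaNpa:
    def test_formula_values(self):
        ppa, npa, tpr = ppa_npa(ConfusionTable(tp=19, fp=1, tn=99, fn=1))
        assert ppa == pytest.approx(0.95)
        assert npa == pytest.approx(0.99)
        assert tpr == ppa

    def test_zero_denominator_is_undefined_not_zero(self):
        ppa, npa, _ = ppa_npa(ConfusionTable(tp=0, fp=2, tn=5, fn=0))
        assert ppa is None
        assert npa == pytest.approx(5 / 7)

    def test_precision_style_tpr(self):
        _, _, tpr = ppa_npa(ConfusionTable(tp=5, fp=5, tn=1, fn=1),
                            tpr_definition="precision")
        assert tpr == pytest.approx(0.5)


class TestRoc:
    def three_score_fixture(self):
        scores = pd.Series({"a": 0.0, "b": 0.3, "c": 0.5})
        ref = pd.Series({"a": False, "b": True, "c": True})
        return scores, ref

    def test_three_score_example_against_brute_force(self):
        scores, ref = self.three_score_fixture()
        points = roc(scores, ref)
        oracle = brute_force_operating_points(scores, ref)
        assert [p.table for p in points] == [t for _, t in oracle]
        # any cutoff in [0.0, 0.3) separates perfectly
        at_zero = next(p for p in points if p.cutoff == 0.0)
        assert at_zero.ppa == 1.0 and at_zero.npa == 1.0

    def test_equal_scores_give_two_operating_points(self):
        scores = pd.Series(0.4, index=list("abcd"))
        ref = pd.Series([True, True, False, False], index=list("abcd"))
        points = roc(scores, ref)
        assert len(points) == 2
        # below the minimum: everything called positive
        assert points[0].table == ConfusionTable(tp=2, fp=2, tn=0, fn=0)
        # at the common score, strict ">" calls everything negative
        assert points[1].table == ConfusionTable(tp=0, fp=0, tn=2, fn=2)

    def test_perfect_separation_reaches_ideal_point(self):
        scores = pd.Series([0.9, 0.8, 0.1, 0.2], index=list("abcd"))
        ref = pd.Series([True, True, False, False], index=list("abcd"))
        assert any(p.ppa == 1.0 and p.npa == 1.0 for p in roc(scores, ref))

    def test_degenerate_reference_rejected(self):
        scores = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(DegenerateReferenceError):
            roc(scores, pd.Series([True, True], index=list("ab")))

    @given(st.integers(0, 10_000))
    def test_fast_path_equals_brute_force(self, seed):
        """ROC oracle equivalence on random score sets up to 100 recordings."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 100))
        idx = [f"r{i}" for i in range(n)]
        # quantized scores force ties, the interesting case
        scores = pd.Series(rng.integers(0, 6, n) / 5.0, index=idx)
        ref = pd.Series(rng.random(n) < 0.5, index=idx)
        if ref.all() or not ref.any():
            return
        points = roc(scores, ref)
        oracle = brute_force_operating_points(scores, ref)
        assert [p.table for p in points] == [t for _, t in oracle]
        # monotonicity: tp non-increasing, tn non-decreasing with cutoff
        tps = [p.table.tp for p in points]
        tns = [p.table.tn for p in points]
        assert tps == sorted(tps, reverse=True)
        assert tns == sorted(tns)


class TestOptimalCutoffInterval:
    def test_three_score_example_interval(self):
        scores = pd.Series({"a": 0.0, "b": 0.3, "c": 0.5})
        ref = pd.Series({"a": False, "b": True, "c": True})
        iv = optimal_cutoff_interval(roc(scores, ref))
        assert iv.cutoff_lo == pytest.approx(0.0)
        assert iv.cutoff_hi == pytest.approx(0.3)
        assert iv.ppa == 1.0 and iv.npa == 1.0

    def test_single_point_degenerates(self):
        from stethosim.evaluate import OperatingPoint
        p = OperatingPoint(0.2, ConfusionTable(1, 0, 1, 0), 1.0, 1.0, 1.0)
        iv = optimal_cutoff_interval([p])
        assert iv.cutoff_lo == iv.cutoff_hi == 0.2

    def test_tie_broken_toward_higher_npa(self):
        from stethosim.evaluate import OperatingPoint
        a = OperatingPoint(0.1, ConfusionTable(9, 4, 96, 1), 0.9, 0.96, 0.9)
        b = OperatingPoint(0.2, ConfusionTable(8, 1, 99, 2), 0.8, 0.99, 0.8)
        b = OperatingPoint(0.2, b.table, 0.87, 0.99, 0.87)
        a = OperatingPoint(0.1, a.table, 0.90, 0.96, 0.90)
        iv = optimal_cutoff_interval([a, b])
        assert iv.npa == 0.99

    def test_interval_cutoffs_produce_identical_tables(self):
        rng = np.random.default_rng(4)
        idx = [f"r{i}" for i in range(40)]
        scores = pd.Series(rng.integers(0, 8, 40) / 7.0, index=idx)
        ref = pd.Series(rng.random(40) < 0.4, index=idx)
        iv = optimal_cutoff_interval(roc(scores, ref))
        if iv.cutoff_hi > iv.cutoff_lo:
            eps = (iv.cutoff_hi - iv.cutoff_lo) / 10
            lo_ct = confusion(scores > iv.cutoff_lo + eps, ref)
            hi_ct = confusion(scores > iv.cutoff_hi - eps, ref)
            assert lo_ct == hi_ct == iv.table


class TestCohenKappa:
    def test_identical_nonconstant_vectors(self):
        tags = ["pos", "neg", "pos", "neg", "neg"]
        assert cohen_kappa(tags, tags) == 1.0

    def test_po_08_pe_05_gives_06(self):
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 40 + ["y"] * 10 + ["x"] * 10 + ["y"] * 40
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_balanced_2x2_table_hand_value(self):
        # agreement table (25,5 / 5,25): p_o = 50/60, p_e = 0.5 -> 2/3
        a = ["c"] * 30 + ["w"] * 30
        b = ["c"] * 25 + ["w"] * 5 + ["c"] * 5 + ["w"] * 25
        assert cohen_kappa(a, b) == pytest.approx(2 / 3)

    def test_constant_identical_raters_defined_as_one(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            cohen_kappa([1, 2], [1, 2, 3])


class TestCohortSummary:
    def _participants(self, ages, sexes=None, groups=None):
        n = len(ages)
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "group": groups or ["normal"] * n,
            "sex": sexes or ["M"] * n,
            "age_years": ages,
            "weight_kg": [20.0] * n,
        })

    def _manifest(self, n):
        return pd.DataFrame({"recording_id": [f"r{i}" for i in range(n)],
                             "excluded": [False] * n})

    def test_female_percent_rounds_to_table_style_integer(self):
        parts = self._participants([5.0] * 25,
                                   sexes=["F"] * 7 + ["M"] * 18)
        cs = cohort_summary(self._manifest(200), parts)
        assert cs.percent_female == 28

    def test_odd_and_even_medians(self):
        assert cohort_summary(self._manifest(3),
                              self._participants([1, 2, 3])).age_median == 2
        assert cohort_summary(self._manifest(4),
                              self._participants([1, 2, 3, 4])).age_median == 2.5
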