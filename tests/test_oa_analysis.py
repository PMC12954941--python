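import itertools
from fractions import Fraction

import numpy as np
import pytest

from hiddenproj.analysis import (
    cheng_guarantee,
    compare_designs,
    exact_rank,
    float_rank,
    is_full_rank_projection,
    max_strength,
    projection_coverage,
    run_reduction_pct,
    verify_strength,
)
from hiddenproj.design import make_design, model_matrix


class TestVerifyStrength:
    def test_oa12_strength_2_max_2(self, oa12):
        report = verify_strength(oa12, 2)
        assert report.holds
        assert report.max_t == 2  # 12 is not divisible by 8

    def test_full_factorial_strength_3(self, full8):
        report = verify_strength(full8, 3)
        assert report.holds and report.max_t == 3

    def test_resolution_iv_design_strength_3(self, regular16):
        assert verify_strength(regular16, 3).holds

    def test_resolution_vi_design_strength_5(self, regular32):
        report = verify_strength(regular32, 5)
        assert report.holds and report.max_t == 5

    def test_failure_produces_witness(self, oa12):
        report = verify_strength(oa12, 3)
        assert not report.holds
        assert report.witness is not None

    def test_witness_count_is_checkable(self):
        # a deliberately unbalanced 4x2 matrix: strength 2 fails
        d = make_design(np.array([[1, 1], [1, 1], [-1, -1], [-1, 1]]))
        report = verify_strength(d, 2)
        assert not report.holds
        cols, levels, count, expected = report.witness
        observed = sum(
            1
            for row in d.matrix
            if tuple(row[list(d.factors.index(c) for c in cols)]) == levels
        )
        assert observed == count != expected

    def test_t_out_of_range(self, oa12):
        with pytest.raises(ValueError):
            verify_strength(oa12, 0)
        with pytest.raises(ValueError):
            verify_strength(oa12, 7)


class TestRank:
    def test_exact_equals_float_on_model_matrices(self, oa12, regular16):
        for d in (oa12, regular16):
            for subset in itertools.combinations(d.factors, 4):
                M = model_matrix(d, list(subset))
                assert exact_rank(M) == float_rank(M)

    def test_rank_deficient_known_value(self, regular16):
        ok, rank = is_full_rank_projection(regular16, ["A", "B", "C", "E"])
        assert not ok
        assert rank == 8  # AB=CE, AC=BE, AE=BC: three duplicated columns of 11

    def test_aliased_projection_not_full_rank(self, aliased16):
        ok, _ = is_full_rank_projection(aliased16, ["A", "B", "E"])
        assert not ok

    def test_oa12_projection_full_rank(self, oa12):
        ok, rank = is_full_rank_projection(oa12, ["A", "B", "E"])
        assert ok and rank == 7

    def test_single_factor_always_full_rank(self, oa12, regular16, aliased16):
        for d in (oa12, regular16, aliased16):
            ok, rank = is_full_rank_projection(d, ["A"])
            assert ok and rank == 2

    def test_more_columns_than_runs_is_false_not_error(self):
        # 4 runs, ME+2FI over 4 factors needs 11 columns > 4
        d = make_design(
            np.array([[1, 1, 1, 1], [1, -1, 1, -1], [-1, 1, 1, -1], [-1, -1, -1, 1]])
        )
        ok, rank = is_full_rank_projection(d, list("ABCD"))
        assert not ok
        assert rank <= 4


class TestProjectionCoverage:
    def test_oa12_k3_full(self, oa12):
        report = projection_coverage(oa12, 3)
        assert report.total_subsets == 20
        assert report.coverage == 1
        assert report.coverage_pct == 100.0

    def test_oa12_k4_full(self, oa12):
        report = projection_coverage(oa12, 4)
        assert report.total_subsets == 15
        assert report.full_rank_count == 15

    def test_regular16_k4_80pct(self, regular16):
        report = projection_coverage(regular16, 4)
        assert report.full_rank_count == 12
        assert report.coverage == Fraction(4, 5)
        assert report.coverage_pct == 80.0
        assert set(report.deficient_subsets) == {
            ("A", "B", "C", "E"),
            ("A", "C", "D", "F"),
            ("B", "D", "E", "F"),
        }

    def test_explicit_subsets_marks_sampled(self, oa12):
        report = projection_coverage(oa12, 3, subsets=[("A", "B", "C")])
        assert not report.exhaustive
        assert report.total_subsets == 1

    def test_monotonicity_regular16(self, regular16):
        # 100% at k=3 implies 100% at lower k
        assert projection_coverage(regular16, 3).coverage == 1
        for k in (1, 2):
            assert projection_coverage(regular16, k).coverage == 1

    def test_k_out_of_range(self, oa12):
        with pytest.raises(ValueError):
            projection_coverage(oa12, 0)


class TestChengGuarantee:
    @pytest.mark.parametrize(
        "N,n,t,expected",
        [
            (12, 6, 2, 4),
            (16, 6, 2, None),   # 16 is a multiple of 8
            (24, 6, 3, 5),
            (420, 16, 2, 4),    # 420 mod 8 = 4
            (20, 6, 2, 4),
            (28, 6, 2, 4),
            (12, 3, 2, None),   # n < 4
            (32, 6, 3, None),   # 32 is a multiple of 16
        ],
    )
    def test_table(self, N, n, t, expected):
        assert cheng_guarantee(N, n, t) == expected

    def test_unsupported_strength(self):
        with pytest.raises(ValueError):
            cheng_guarantee(12, 6, 4)

    @pytest.mark.parametrize("fixture", ["oa12", "oa28"])
    def test_guarantee_consistency(self, fixture, request):
        d = request.getfixturevalue(fixture)
        t = max_strength(d)
        assert t >= 2
        g = cheng_guarantee(d.runs, d.n_factors, 2)
        assert g == 4
        assert projection_coverage(d, g).coverage == 1


class TestCompareDesigns:
    def test_table1_comparison(self, oa12, regular16):
        comp = compare_designs(
            [("regular16", regular16), ("oa12", oa12)], [3, 4], baseline="regular16"
        )
        reg, oa = comp.designs
        assert reg.coverage[3].coverage_pct == 100.0
        assert reg.coverage[4].coverage_pct == 80.0
        assert oa.coverage[3].coverage_pct == 100.0
        assert oa.coverage[4].coverage_pct == 100.0
        assert oa.reduction_vs_baseline_pct == 25
        assert reg.reduction_vs_baseline_pct == 0
        assert (reg.strength, oa.strength) == (3, 2)

    @pytest.mark.parametrize(
        "base,runs,expected", [(16, 12, 25), (512, 420, 18), (32, 28, 12), (100, 100, 0)]
    )
    def test_run_reduction(self, base, runs, expected):
        assert run_reduction_pct(base, runs) == expected

    def test_duplicate_names_rejected(self, oa12):
        with pytest.raises(ValueError):
            compare_designs([("d", oa12), ("d", oa12)], [3])

    def test_unknown_baseline_rejected(self, oa12):
        with pytest.raises(ValueError):
            compare_designs([("d", oa12)], [3], baseline="x")
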