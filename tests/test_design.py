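"""Tests for multilevel designs, D-optimal exchange and prep arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemcal.design import (
    CodedDesign,
    ConcentrationDesign,
    FactorRange,
    ModelSpec,
    build_model_matrix,
    code_to_concentration,
    d_optimal_select,
    design_diagnostics,
    enumerate_candidates,
    generate_brereton_design,
    solution_prep,
)
from chemcal.exceptions import (
    ConfigurationError,
    DomainError,
    InfeasibleDesignError,
    UnsupportedDesignError,
)
from chemcal.reference import CALIBRATION_SET, VALIDATION_SET, validation_design


class TestFactorRange:
    def test_step_and_levels(self):
        f = FactorRange("CIN", 4, 20, 5)
        assert f.step == 4
        assert f.midpoint == 12
        np.testing.assert_array_equal(f.levels, [4, 8, 12, 16, 20])

    def test_invalid_range(self):
        with pytest.raises(DomainError):
            FactorRange("x", 5, 5, 5)
        with pytest.raises(DomainError):
            FactorRange("x", 1, 2, 1)


class TestBreretonDesign:
    def test_25_runs_center_first(self, factors):
        coded, conc = generate_brereton_design(factors)
        assert conc.n_runs == 25
        # first calibration mixture of the reference table
        np.testing.assert_allclose(conc.matrix[0], [12.0, 9.0, 3.0])
        np.testing.assert_array_equal(coded.matrix[0], [0, 0, 0])

    def test_matches_reference_table(self, factors):
        _, conc = generate_brereton_design(factors)
        np.testing.assert_allclose(conc.matrix, CALIBRATION_SET)

    def test_level_balance(self, factors):
        coded, _ = generate_brereton_design(factors)
        for j in range(3):
            vals, counts = np.unique(coded.matrix[:, j], return_counts=True)
            np.testing.assert_array_equal(vals, [-2, -1, 0, 1, 2])
            assert (counts == 5).all()

    def test_orthogonal_columns_exact(self, factors):
        coded, _ = generate_brereton_design(factors)
        M = coded.matrix.astype(int)
        for i, j in itertools.combinations(range(3), 2):
            assert int(np.dot(M[:, i], M[:, j])) == 0

    def test_cyclic_shift_relation(self, factors):
        coded, _ = generate_brereton_design(factors)
        M = coded.matrix
        # run 1 fixed at centre; the generator advances by one run per column
        for j in range(2):
            np.testing.assert_array_equal(
                M[1:, j + 1], np.roll(M[1:, j], -1)
            )

    def test_three_level_variant(self):
        fs = [FactorRange("a", 0, 2, 3), FactorRange("b", 1, 3, 3)]
        coded, conc = generate_brereton_design(fs)
        assert conc.n_runs == 9
        assert int(np.dot(coded.matrix[:, 0], coded.matrix[:, 1])) == 0
        for j in range(2):
            _, counts = np.unique(coded.matrix[:, j], return_counts=True)
            assert (counts == 3).all()

    def test_even_levels_rejected(self):
        fs = [FactorRange("a", 0, 3, 4)]
        with pytest.raises(ConfigurationError):
            generate_brereton_design(fs)

    def test_mismatched_levels_rejected(self):
        fs = [FactorRange("a", 0, 2, 3), FactorRange("b", 0, 2, 5)]
        with pytest.raises(ConfigurationError):
            generate_brereton_design(fs)

    def test_too_many_factors_rejected(self):
        fs = [FactorRange(str(i), 0, 2, 3) for i in range(3)]
        with pytest.raises(UnsupportedDesignError):
            generate_brereton_design(fs)

    def test_decode_roundtrip(self, factors):
        coded, conc = generate_brereton_design(factors)
        np.testing.assert_array_equal(conc.to_coded().matrix, coded.matrix)


class TestCoding:
    def test_midpoint(self):
        f = [FactorRange("CIN", 4, 20, 5)]
        c = code_to_concentration(CodedDesign(np.array([[0.0]]), ["CIN"]), f)
        assert c.matrix[0, 0] == 12.0

    @pytest.mark.parametrize(
        "coded,lo,hi,expected",
        [(-2, 4, 20, 4.0), (2, 3, 15, 15.0), (1, 4, 20, 16.0)],
    )
    def test_extremes(self, coded, lo, hi, expected):
        f = [FactorRange("x", lo, hi, 5)]
        c = code_to_concentration(
            CodedDesign(np.array([[float(coded)]]), ["x"]), f
        )
        assert c.matrix[0, 0] == expected

    def test_out_of_range_rejected(self):
        f = [FactorRange("x", 4, 20, 5)]
        with pytest.raises(DomainError):
            code_to_concentration(CodedDesign(np.array([[3.0]]), ["x"]), f)


class TestModelMatrix:
    def test_term_counts(self):
        d = CodedDesign(np.zeros((4, 3)), ["a", "b", "c"])
        assert build_model_matrix(d, ModelSpec()).shape[1] == 10
        assert build_model_matrix(
            d, ModelSpec(interactions=False, quadratics=False)
        ).shape[1] == 4

    def test_single_run_row(self):
        d = CodedDesign(np.array([[2.0, 3.0, 5.0]]), ["a", "b", "c"])
        row = build_model_matrix(d, ModelSpec())[0]
        np.testing.assert_allclose(row, [1, 2, 3, 5, 6, 10, 15, 4, 9, 25])


class TestCandidates:
    def test_counts(self, factors):
        assert enumerate_candidates(factors).n_candidates == 125
        two = [FactorRange("a", 0, 1, 2), FactorRange("b", 0, 1, 2)]
        assert enumerate_candidates(two).n_candidates == 4

    def test_single_factor_values(self):
        g = enumerate_candidates([FactorRange("a", 0, 4, 5)])
        np.testing.assert_array_equal(g.matrix.ravel(), [-2, -1, 0, 1, 2])

    def test_rows_unique(self, factors):
        g = enumerate_candidates(factors)
        assert len(np.unique(g.matrix, axis=0)) == g.n_candidates


def _brute_force_best(candidates, n_select, spec):
    """Exhaustive determinant maximisation oracle."""
    X = build_model_matrix(candidates.matrix, spec)
    best = -np.inf
    for combo in itertools.combinations(range(X.shape[0]), n_select):
        d = np.linalg.det(X[list(combo)].T @ X[list(combo)])
        best = max(best, d)
    return best


class TestDOptimal:
    def test_full_grid_selection(self):
        fs = [FactorRange("a", 0, 1, 2), FactorRange("b", 0, 1, 2)]
        g = enumerate_candidates(fs)
        spec = ModelSpec(interactions=False, quadratics=False)
        res = d_optimal_select(g, 4, spec, n_starts=3, seed=0)
        assert sorted(res.indices) == [0, 1, 2, 3]
        X = build_model_matrix(g.matrix, spec)
        expected = np.log10(np.linalg.det(X.T @ X))
        assert res.log10_det == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_2level(self):
        fs = [FactorRange("a", 0, 1, 2), FactorRange("b", 0, 1, 2)]
        g = enumerate_candidates(fs)
        spec = ModelSpec(interactions=False, quadratics=False)
        res = d_optimal_select(g, 3, spec, n_starts=5, seed=0)
        best = _brute_force_best(g, 3, spec)
        assert 10**res.log10_det == pytest.approx(best, rel=1e-9)

    @pytest.mark.parametrize("n_select", [4, 5, 6])
    def test_matches_brute_force_small_grids(self, n_select):
        fs = [FactorRange("a", 0, 2, 3), FactorRange("b", 0, 2, 3)]
        g = enumerate_candidates(fs)  # 9 candidates
        spec = ModelSpec(quadratics=False)
        res = d_optimal_select(g, n_select, spec, n_starts=10, seed=1)
        best = _brute_force_best(g, n_select, spec)
        assert 10**res.log10_det == pytest.approx(best, rel=1e-8)

    def test_beats_random_subsets(self, factors):
        g = enumerate_candidates(factors)
        res = d_optimal_select(g, 13, ModelSpec(), n_starts=10, seed=3)
        X = build_model_matrix(g.matrix, ModelSpec())
        rng = np.random.default_rng(99)
        for _ in range(200):
            sel = rng.choice(125, 13, replace=False)
            sign, logdet = np.linalg.slogdet(X[sel].T @ X[sel])
            rand = logdet / np.log(10) if sign > 0 else -np.inf
            assert res.log10_det >= rand

    def test_monotone_within_start(self, factors):
        # final log-det is at least that of every random initial subset
        g = enumerate_candidates(factors)
        res = d_optimal_select(g, 13, ModelSpec(), n_starts=8, seed=5)
        assert all(
            res.log10_det >= s - 1e-9 for s in res.start_log10_dets
        )

    def test_reproducible(self, factors):
        g = enumerate_candidates(factors)
        a = d_optimal_select(g, 13, ModelSpec(), n_starts=5, seed=7)
        b = d_optimal_select(g, 13, ModelSpec(), n_starts=5, seed=7)
        np.testing.assert_array_equal(a.indices, b.indices)
        assert a.log10_det == b.log10_det

    def test_infeasible_size_rejected(self, factors):
        g = enumerate_candidates(factors)
        with pytest.raises(InfeasibleDesignError):
            d_optimal_select(g, 9, ModelSpec(), seed=0)

    def test_beats_reference_validation_logdet(self, factors):
        """The exchange search must match or beat the published 13-run set."""
        g = enumerate_candidates(factors)
        res = d_optimal_select(g, 13, ModelSpec(), n_starts=10, seed=2)
        ref = validation_design()
        X_ref = build_model_matrix(ref.to_coded(), ModelSpec())
        sign, logdet = np.linalg.slogdet(X_ref.T @ X_ref)
        assert res.log10_det >= logdet / np.log(10) - 1e-9


class TestDiagnostics:
    def test_calibration_zero_correlation(self, factors):
        _, conc = generate_brereton_design(factors)
        diag = design_diagnostics(conc)
        for v in diag["correlations"].values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_correlation_one(self):
        f = [FactorRange("a", 0, 4, 5), FactorRange("b", 0, 4, 5)]
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        diag = design_diagnostics(ConcentrationDesign(m, f))
        assert diag["correlations"][("a", "b")] == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        f = [FactorRange("a", 0, 4, 5), FactorRange("b", 0, 4, 5)]
        m = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        diag = design_diagnostics(ConcentrationDesign(m, f))
        assert diag["correlations"][("a", "b")] is None

    def test_reference_validation_coverage(self, factors):
        """Coverage of the published validation table (as printed: the
        extracted table spans 5-20, 3-14 and 1-5 ug/mL)."""
        diag = design_diagnostics(validation_design())
        assert diag["coverage"]["BNZ"] == pytest.approx(1.0)
        assert diag["coverage"]["CIN"] == pytest.approx(15 / 16)
        assert diag["coverage"]["DOM"] == pytest.approx(11 / 12)

    def test_generated_dopt_coverage_full(self, factors):
        g = enumerate_candidates(factors)
        res = d_optimal_select(g, 13, ModelSpec(), n_starts=10, seed=2)
        diag = design_diagnostics(res.design)
        for name in ("CIN", "DOM", "BNZ"):
            assert diag["coverage"][name] == pytest.approx(1.0)


class TestSolutionPrep:
    def test_stock_dilution(self):
        assert solution_prep(
            [("stock", 1250), ("dilute", 5, 250)]
        ) == pytest.approx(25.0)

    def test_identity_dilution(self):
        assert solution_prep(
            [("stock", 42), ("dilute", 10, 10)]
        ) == pytest.approx(42.0)

    def test_tablet_chain(self):
        assert solution_prep(
            [("mass", 20, 100), ("dilute", 0.5, 10)]
        ) == pytest.approx(10.0)
        assert solution_prep(
            [("mass", 15, 100), ("dilute", 0.5, 10)]
        ) == pytest.approx(7.5)

    def test_bad_volumes(self):
        with pytest.raises(DomainError):
            solution_prep([("stock", 10), ("dilute", -1, 10)])
        with pytest.raises(DomainError):
            solution_prep([("stock", 10), ("dilute", 11, 10)])

    @given(
        c=st.floats(0.01, 1e4),
        a=st.floats(0.01, 100),
        scale=st.floats(1.0, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_dilution_never_concentrates(self, c, a, scale):
        out = solution_prep([("stock", c), ("dilute", a, a * scale)])
        assert out <= c * (1 + 1e-12)
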