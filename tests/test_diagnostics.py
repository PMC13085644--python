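"""Tests for EJCR, cosine similarity, ambiguity bands and local rank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemcal.datasets import AbsorbanceMatrix, WavelengthGrid
from chemcal.diagnostics import (
    ambiguity_bands,
    cosine_similarity,
    ejcr,
    local_rank_map,
)
from chemcal.exceptions import DomainError
from chemcal.fom import PredictionSet
from chemcal.mcr import ConstraintSet, fit_mcr_als
from chemcal.spectra import NoiseModel, simulate_mixtures


class TestEjcr:
    def test_perfect_predictions_degenerate(self):
        E = np.linspace(1, 10, 8)
        res = ejcr(PredictionSet(E, E.copy()))
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.contains_ideal
        assert res.area == pytest.approx(0.0, abs=1e-20)

    def test_biased_model_excluded(self):
        E = np.linspace(1, 10, 20)
        pred = 1.5 * E + 2.0  # strongly biased, tiny noise
        rng = np.random.default_rng(0)
        res = ejcr(PredictionSet(E, pred + rng.normal(0, 0.01, 20)))
        assert not res.contains_ideal

    def test_coverage_95pct(self):
        """Monte-Carlo coverage of the F-based region for unbiased fits."""
        rng = np.random.default_rng(42)
        E = np.linspace(1, 10, 13)
        hits = 0
        reps = 10_000
        for _ in range(reps):
            pred = E + rng.normal(0, 0.5, 13)
            hits += ejcr(PredictionSet(E, pred)).contains_ideal
        assert abs(hits / reps - 0.95) <= 0.01

    def test_smaller_noise_smaller_area(self):
        rng = np.random.default_rng(3)
        E = np.linspace(1, 10, 13)
        small = ejcr(PredictionSet(E, E + rng.normal(0, 0.05, 13)))
        large = ejcr(PredictionSet(E, E + rng.normal(0, 0.8, 13)))
        assert small.area < large.area

    def test_boundary_on_ellipse(self):
        rng = np.random.default_rng(5)
        E = np.linspace(1, 10, 13)
        res = ejcr(PredictionSet(E, E + rng.normal(0, 0.3, 13)))
        beta = np.array([res.intercept, res.slope])
        for pt in res.boundary[::37]:
            q = (pt - beta) @ res.shape_matrix @ (pt - beta)
            assert q == pytest.approx(res.radius, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DomainError):
            ejcr(PredictionSet(np.arange(3.0), np.arange(3.0)))


class TestCosine:
    def test_self_similarity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            cosine_similarity([0, 0], [1, 1])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=10),
        st.floats(0.01, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_scale_invariance(self, vals, scale):
        a = np.asarray(vals)
        b = np.linspace(1, 2, len(vals))
        if np.linalg.norm(a) == 0:
            return
        c = cosine_similarity(a, b)
        assert -1 <= c <= 1
        assert cosine_similarity(a * scale, b) == pytest.approx(c, abs=1e-9)


@pytest.fixture(scope="module")
def two_component_toy():
    """k = 2 system with a selective region for the first component."""
    grid = WavelengthGrid(220, 259, 1)
    lam = grid.values
    s1 = np.exp(-((lam - 235) ** 2) / (2 * 5**2))
    s1[lam > 250] = 0.0
    s2 = np.exp(-((lam - 248) ** 2) / (2 * 6**2))
    S = np.vstack([s1, s2])
    rng = np.random.default_rng(0)
    C = rng.uniform(0.2, 1.0, (12, 2))
    D = AbsorbanceMatrix(C @ S, grid)
    model = fit_mcr_als(
        D, 2, init=S, constraints=ConstraintSet(), max_iter=200, rel_tol=0.0
    )
    return {"grid": grid, "model": model, "S": S}


class TestAmbiguity:
    def test_single_component_no_ambiguity(self, grid, library):
        from chemcal.datasets import ConcentrationTable

        conc = ConcentrationTable(np.linspace(1, 5, 6)[:, None], ["CIN"])
        sim = simulate_mixtures(conc, library[:1], NoiseModel(sd=0), grid)
        model = fit_mcr_als(
            sim.absorbance, 1, init=sim.pure_spectra, constraints=ConstraintSet()
        )
        res = ambiguity_bands(model, grid=grid)
        assert res.components[0].afs_pct == 0.0

    def test_optimizer_matches_grid_oracle(self, two_component_toy):
        t = two_component_toy
        opt = ambiguity_bands(
            t["model"], grid=t["grid"], method="optimize",
            n_starts=10, seed=3,
        )
        oracle = ambiguity_bands(t["model"], grid=t["grid"], method="grid")
        for c in range(2):
            assert opt.components[c].f_min == pytest.approx(
                oracle.components[c].f_min, abs=1e-3
            )
            assert opt.components[c].f_max == pytest.approx(
                oracle.components[c].f_max, abs=1e-3
            )

    def test_reference_constraint_never_widens(self, two_component_toy):
        t = two_component_toy
        free = ambiguity_bands(t["model"], grid=t["grid"], method="grid")
        refs = {0: (t["S"][0], 0.995), 1: (t["S"][1], 0.995)}
        tight = ambiguity_bands(
            t["model"], grid=t["grid"], method="grid",
            reference_constraints=refs,
        )
        for c in range(2):
            assert (
                tight.components[c].afs_pct
                <= free.components[c].afs_pct + 1e-9
            )

    def test_nested_constraints_nested_intervals(self, two_component_toy):
        t = two_component_toy
        loose = ambiguity_bands(
            t["model"], grid=t["grid"], method="grid",
            reference_constraints={0: (t["S"][0], 0.99)},
        )
        tight = ambiguity_bands(
            t["model"], grid=t["grid"], method="grid",
            reference_constraints={0: (t["S"][0], 0.999)},
        )
        for c in range(2):
            assert (
                tight.components[c].f_min
                >= loose.components[c].f_min - 1e-9
            )
            assert (
                tight.components[c].f_max
                <= loose.components[c].f_max + 1e-9
            )

    def test_identity_inside_band(self, two_component_toy):
        t = two_component_toy
        res = ambiguity_bands(t["model"], grid=t["grid"], method="grid")
        for c in res.components:
            assert c.f_min <= c.f_max
            assert c.afs_pct >= 0
            assert 0 <= c.selectivity_index <= 1


class TestLocalRank:
    def test_rank1_everywhere(self, grid):
        rng = np.random.default_rng(0)
        D = AbsorbanceMatrix(
            np.outer(rng.random(8), rng.uniform(0.5, 1, 81)), grid
        )
        res = local_rank_map(D, window_nm=10)
        assert (res["rank"] == 1).all()

    def test_selective_region_rank_drop(self, noiseless, grid):
        """DOM dominates alone above ~292 nm; the 240-260 region carries
        all three components."""
        res = local_rank_map(noiseless["sim"].absorbance, window_nm=9)
        mid = (res["center_nm"] >= 240) & (res["center_nm"] <= 260)
        assert res["rank"][mid].max() == 3
        edge = res["center_nm"] >= 294
        assert res["rank"][edge].min() <= 2

    def test_sample_order_invariant(self, noiseless):
        D = noiseless["sim"].absorbance
        rng = np.random.default_rng(1)
        perm = rng.permutation(D.n_samples)
        shuffled = AbsorbanceMatrix(D.values[perm], D.grid)
        a = local_rank_map(D, 11)
        b = local_rank_map(shuffled, 11)
        np.testing.assert_array_equal(a["rank"], b["rank"])

    def test_window_too_small_rejected(self, noiseless):
        with pytest.raises(DomainError):
            local_rank_map(noiseless["sim"].absorbance, window_nm=2)
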