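"""Preprocessing steps: SG filtering, rubber band, truncation, EMSC, recipes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycospec.errors import DesignError, RecipeError
from mycospec.preprocess import (
    apply_recipe,
    average_technical_replicates,
    emsc,
    fit_apply_recipe,
    make_recipe,
    PreprocessRecipe,
    rubberband_baseline,
    savgol,
    truncate_regions,
)

from conftest import make_meta, make_set


def _grid(n, spacing=2.0, start=None):
    start = start if start is not None else n * spacing
    return start - spacing * np.arange(n)


class TestSavgol:
    def test_quadratic_reproduced_order0(self):
        g = _grid(101)
        sset = make_set((0.01 * g**2 - g + 3)[None, :], grid=g)
        out = savgol(sset, 2, 15, 0)
        np.testing.assert_allclose(out.matrix, sset.matrix, atol=1e-10)

    def test_second_derivative_of_quadratic(self):
        g = _grid(101)
        sset = make_set((3.0 * g**2)[None, :], grid=g)
        out = savgol(sset, 2, 15, 2)
        interior = slice(8, -8)
        np.testing.assert_allclose(out.matrix[0][interior], 6.0, atol=1e-8)

    def test_matches_moving_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        g = _grid(60)
        y = rng.normal(size=60)
        out = savgol(make_set(y[None, :], grid=g), 2, 15, 0)
        # brute-force local quadratic fit at each interior point (ascending x)
        xa, ya = g[::-1], y[::-1]
        half = 7
        for k in range(half, 60 - half):
            xs = xa[k - half:k + half + 1] - xa[k]
            ys = ya[k - half:k + half + 1]
            coef = np.polynomial.polynomial.polyfit(xs, ys, 2)
            assert abs(out.matrix[0, ::-1][k] - coef[0]) < 1e-10

    def test_window_too_large(self):
        with pytest.raises(RecipeError, match="window"):
            savgol(make_set(np.zeros((1, 9))), 2, 15, 0)


class TestRubberband:
    def test_straight_line_zeroed(self):
        g = _grid(50)
        sset = make_set((2.0 * g + 5.0)[None, :], grid=g)
        out = rubberband_baseline(sset)
        np.testing.assert_allclose(out.matrix, 0.0, atol=1e-10)

    def test_convex_bowl_zeroed(self):
        g = _grid(50)
        sset = make_set(((g - 50.0) ** 2)[None, :], grid=g)
        out = rubberband_baseline(sset)
        np.testing.assert_allclose(out.matrix, 0.0, atol=1e-8)

    def test_lorentzian_on_slope_matches_chord(self):
        g = _grid(201)
        lor = 1.0 / (1.0 + ((g - 200.0) / 8.0) ** 2)
        base = 0.01 * g + 2.0
        out = rubberband_baseline(make_set((lor + base)[None, :], grid=g))
        # baseline of a peak on a line is the endpoint chord of (lor + line),
        # i.e. corrected = lor minus its own endpoint chord
        x = g[::-1]
        y = lor[::-1]
        chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        np.testing.assert_allclose(out.matrix[0][::-1], y - chord, atol=1e-10)
        assert abs(out.matrix[0, 0]) < 1e-12 and abs(out.matrix[0, -1]) < 1e-12

    def test_exhaustive_chord_oracle(self):
        # lower hull at x = min over all point-pair chords spanning x
        rng = np.random.default_rng(3)
        g = _grid(120)
        y = np.abs(rng.normal(size=120)).cumsum() * 0.1 + rng.normal(size=120)
        out = rubberband_baseline(make_set(y[None, :], grid=g))
        baseline = (y - out.matrix[0])[::-1]
        xa, ya = g[::-1], y[::-1]
        n = xa.size
        oracle = np.full(n, np.inf)
        for i in range(n):
            for j in range(i + 1, n):
                t = (xa[i:j + 1] - xa[i]) / (xa[j] - xa[i])
                chord = (1 - t) * ya[i] + t * ya[j]
                oracle[i:j + 1] = np.minimum(oracle[i:j + 1], chord)
        np.testing.assert_allclose(baseline, oracle, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        sset = make_set(rng.normal(size=(3, 80)).cumsum(axis=1))
        once = rubberband_baseline(sset)
        twice = rubberband_baseline(once)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-10)

    def test_too_few_points(self):
        with pytest.raises(RecipeError):
            rubberband_baseline(make_set(np.zeros((1, 2))))


class TestTruncate:
    def test_two_region_truncation_excludes_gap(self, raman_set):
        out = truncate_regions(raman_set, [[3200, 2400], [1900, 500]])
        gap = (out.grid < 2400) & (out.grid > 1900)
        assert not gap.any()
        assert out.grid.max() <= 3200 and out.grid.min() >= 500
        d = np.diff(out.grid)
        assert (d < 0).all()  # still descending

    def test_derivative_region(self, raman_set):
        out = truncate_regions(raman_set, [[1800, 900]])
        assert out.grid.max() <= 1800 and out.grid.min() >= 900

    def test_full_cover_identity(self):
        sset = make_set(np.arange(10.0)[None, :])
        out = truncate_regions(sset, [[0, 100]])
        np.testing.assert_array_equal(out.matrix, sset.matrix)

    def test_empty_result(self):
        with pytest.raises(RecipeError):
            truncate_regions(make_set(np.zeros((1, 5))), [[100, 200]])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(RecipeError):
            truncate_regions(make_set(np.zeros((1, 5))), [[1, 3], [2, 4]])


class TestEmsc:
    def _ref(self, n=200):
        g = _grid(n)
        m = np.exp(-0.5 * ((g - 150.0) / 20.0) ** 2) + 0.3
        return g, m

    def test_exact_model_recovery(self):
        g, m = self._ref()
        u = (g - (g.max() + g.min()) / 2) / ((g.max() - g.min()) / 2)
        s = 2.0 * m + 0.5 + 0.1 * u**2
        out = emsc(make_set(s[None, :], grid=g), reference=m, poly_degree=2)
        np.testing.assert_allclose(out.matrix[0], m, atol=1e-10)

    def test_identity(self):
        g, m = self._ref()
        out, model = emsc(make_set(m[None, :], grid=g), reference=m, poly_degree=3, return_model=True)
        np.testing.assert_allclose(out.matrix[0], m, atol=1e-10)
        assert abs(model["a"][0] - 1.0) < 1e-10
        np.testing.assert_allclose(model["poly_coefs"][0], 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        g, m = self._ref()
        S = rng.normal(size=(5, g.size)) + m
        out = emsc(make_set(S, grid=g), reference=m, poly_degree=3)
        u = (g - (g.max() + g.min()) / 2) / ((g.max() - g.min()) / 2)
        D = np.column_stack([m, np.ones_like(u), u, u**2, u**3])
        for i in range(5):
            coef = np.linalg.solve(D.T @ D, D.T @ S[i])
            expect = (S[i] - D[:, 1:] @ coef[1:]) / coef[0]
            np.testing.assert_allclose(out.matrix[i], expect, atol=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(kappa=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, kappa):
        g, m = self._ref(80)
        rng = np.random.default_rng(11)
        S = rng.normal(size=(3, 80)) * 0.1 + m
        a = emsc(make_set(S, grid=g), reference=m, poly_degree=3)
        b = emsc(make_set(kappa * S, grid=g), reference=m, poly_degree=3)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-10 * max(1, 1 / kappa))

    def test_singular_reference_rejected(self):
        g = _grid(50)
        u = (g - (g.max() + g.min()) / 2) / ((g.max() - g.min()) / 2)
        with pytest.raises(RecipeError, match="reference"):
            emsc(make_set(np.ones((2, 50)), grid=g), reference=1.0 + 0.5 * u, poly_degree=3)


class TestRecipes:
    def test_raman_nonderiv_grid(self, raman_set):
        out, _ = fit_apply_recipe(raman_set, make_recipe("raman_nonderiv"))
        gap = (out.grid < 2400) & (out.grid > 1900)
        assert not gap.any()
        assert out.grid.max() <= 3200 and out.grid.min() >= 500

    def test_ftir_deriv_grid(self, ftir_set):
        out, _ = fit_apply_recipe(ftir_set, make_recipe("ftir_deriv"))
        assert out.grid.max() <= 1800 and out.grid.min() >= 900

    def test_empty_recipe_is_identity(self, raman_set):
        sub = raman_set.select(np.arange(4))
        out = apply_recipe(sub, PreprocessRecipe(name="noop", steps=[]))
        np.testing.assert_array_equal(out.matrix, sub.matrix)

    def test_unknown_recipe_name(self):
        with pytest.raises(RecipeError):
            make_recipe("raman_cubic")

    def test_train_reference_reused_on_test(self, raman_set):
        train = raman_set.select(np.arange(0, 30))
        test = raman_set.select(np.arange(30, 60))
        _, ref = fit_apply_recipe(train, make_recipe("raman_deriv"))
        out1 = apply_recipe(test, make_recipe("raman_deriv"), emsc_reference=ref)
        out2 = apply_recipe(test, make_recipe("raman_deriv"), emsc_reference=ref)
        np.testing.assert_array_equal(out1.matrix, out2.matrix)
        # and it differs from the test set's own reference
        out3 = apply_recipe(test, make_recipe("raman_deriv"))
        assert np.abs(out1.matrix - out3.matrix).max() > 0


class TestReplicateAveraging:
    def test_identical_replicates(self):
        row = np.arange(5.0)
        sset = make_set(np.tile(row, (3, 1)))
        out = average_technical_replicates(sset)
        assert out.n_samples == 1
        np.testing.assert_array_equal(out.matrix[0], row)

    def test_arithmetic_mean(self):
        sset = make_set(np.array([[0.0], [1.0], [2.0]]), grid=[1.0])
        out = average_technical_replicates(sset)
        assert out.matrix[0, 0] == 1.0

    def test_full_block_collapses_to_72(self, raman_set):
        out = average_technical_replicates(raman_set)
        assert out.n_samples == 72
        assert out.chemistry is not None and len(out.chemistry) == 72

    def test_inconsistent_group_metadata_rejected(self):
        meta = make_meta(3)
        meta.loc[2, "laser_power_mw"] = 200.0
        with pytest.raises(DesignError, match="laser_power_mw"):
            average_technical_replicates(make_set(np.zeros((3, 4)), meta=meta))
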