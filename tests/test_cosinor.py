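import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antclock import (
    CosinorFit,
    CosinorParams,
    adjusted_r2,
    cosine_predict,
    cosinor_ftest,
    fit_ls,
    fit_mc,
    fit_pvalue,
    peak_zt,
)


def cosine_series(zts, mesor=0.0, amplitude=1.0, acrophase=18.0):
    return mesor + amplitude * np.cos(2 * np.pi * (np.asarray(zts) - acrophase) / 24)


class TestCosinePredict:
    def test_peak_trough_flat(self):
        p = CosinorParams(mesor=2.0, amplitude=1.5, acrophase=7.0)
        assert cosine_predict(p, 7.0) == pytest.approx(3.5)
        assert cosine_predict(p, 19.0) == pytest.approx(0.5)
        flat = CosinorParams(mesor=2.0, amplitude=0.0, acrophase=0.0)
        np.testing.assert_allclose(cosine_predict(flat, np.arange(0, 24)), 2.0)

    def test_acrophase_wraps_into_period(self):
        p = CosinorParams(mesor=0.0, amplitude=1.0, acrophase=30.0)
        assert p.acrophase == pytest.approx(6.0)


class TestFitLs:
    def test_exact_recovery_of_noiseless_cosine(self, zt_grid):
        y = cosine_series(zt_grid, 0.0, 1.0, 18.0)
        fit = fit_ls(zt_grid, y)
        assert fit.params.mesor == pytest.approx(0.0, abs=1e-9)
        assert fit.params.amplitude == pytest.approx(1.0, abs=1e-9)
        assert fit.params.acrophase == pytest.approx(18.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.amplitude_pt == pytest.approx(2 * fit.params.amplitude, abs=1e-9)

    def test_matches_normal_equations_oracle(self, zt_grid):
        rng = np.random.default_rng(5)
        y = cosine_series(zt_grid, 0.3, 0.8, 9.0) + rng.normal(0, 0.4, zt_grid.size)
        fit = fit_ls(zt_grid, y)
        # independent oracle: solve the normal equations directly
        w = 2 * np.pi * zt_grid / 24
        X = np.column_stack([np.ones_like(zt_grid), np.cos(w), np.sin(w)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params.mesor == pytest.approx(beta[0], abs=1e-8)
        assert fit.params.amplitude == pytest.approx(np.hypot(beta[1], beta[2]), abs=1e-8)
        phi = (24 / (2 * np.pi)) * math.atan2(beta[2], beta[1]) % 24
        assert fit.params.acrophase == pytest.approx(phi, abs=1e-8)

    def test_constant_series_flat_fit_with_warning(self, zt_grid):
        with pytest.warns(RuntimeWarning, match="constant"):
            fit = fit_ls(zt_grid, np.full(zt_grid.size, 3.0))
        assert fit.params.amplitude == 0.0
        assert fit.r2 == 0.0
        assert math.isnan(fit.peak_zt_grid)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_ls([2.0, 6.0, 10.0], [1.0, 2.0, 3.0])

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_ls([2.0, 26.0, 2.0, 26.0], [1.0, 2.0, 3.0, 4.0])

    def test_r2_adj_below_r2_for_imperfect_fits(self, zt_grid):
        rng = np.random.default_rng(9)
        y = cosine_series(zt_grid) + rng.normal(0, 0.5, zt_grid.size)
        fit = fit_ls(zt_grid, y)
        assert fit.r2_adj < fit.r2 < 1.0

    def test_average_parameter_recovery_under_noise(self, zt_grid):
        """With study geometry and noise sd 0.5, A and phi are recovered on average."""
        rng = np.random.default_rng(123)
        amp_err, phase_err = [], []
        for _ in range(200):
            y = cosine_series(zt_grid, 0.0, 1.0, 18.0) + rng.normal(0, 0.5, zt_grid.size)
            fit = fit_ls(zt_grid, y)
            amp_err.append(fit.params.amplitude - 1.0)
            d = (fit.params.acrophase - 18.0 + 12) % 24 - 12
            phase_err.append(d)
        assert abs(np.mean(amp_err)) <= 0.15
        assert abs(np.mean(phase_err)) <= 1.5


class TestFitMc:
    def test_seeded_determinism(self, zt_grid):
        y = cosine_series(zt_grid) + 0.1
        a = fit_mc(zt_grid, y, n_sims=5000, top_k=50, seed=7)
        b = fit_mc(zt_grid, y, n_sims=5000, top_k=50, seed=7)
        assert a == b

    def test_converges_to_ls_oracle_on_noiseless_cosine(self, zt_grid):
        y = cosine_series(zt_grid, 0.2, 1.0, 18.0)
        ls = fit_ls(zt_grid, y)
        mc = fit_mc(zt_grid, y, n_sims=100_000, top_k=400, seed=3)
        assert abs(mc.params.amplitude - ls.params.amplitude) <= 0.05
        assert abs(mc.r2 - ls.r2) <= 0.02

    def test_box_search_error_shrinks_with_n_sims(self, zt_grid):
        """Seed-averaged |R2_mc - R2_ls| decreases monotonically 1e3 -> 1e5."""
        y = cosine_series(zt_grid, 0.0, 1.0, 10.0)
        r2_ls = fit_ls(zt_grid, y).r2
        errs = []
        for n_sims in (1_000, 10_000, 100_000):
            gaps = [
                abs(fit_mc(zt_grid, y, n_sims=n_sims, top_k=100, seed=s, search="box").r2 - r2_ls)
                for s in range(10)
            ]
            errs.append(np.mean(gaps))
        assert errs[0] > errs[1] > errs[2]

    def test_n_sims_must_cover_top_k(self, zt_grid):
        with pytest.raises(ValueError, match="n_sims >= top_k"):
            fit_mc(zt_grid, cosine_series(zt_grid), n_sims=10, top_k=50)

    def test_records_search_metadata(self, zt_grid):
        fit = fit_mc(zt_grid, cosine_series(zt_grid), n_sims=2000, top_k=20, seed=5)
        assert (fit.method, fit.n_sims, fit.top_k, fit.seed) == ("mc", 2000, 20, 5)


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,expected",
        [(0.86, 0.79), (0.66, 0.49), (0.46, 0.19), (0.73, 0.60), (0.19, -0.22)],
    )
    def test_seven_timepoint_design(self, r2, expected):
        assert adjusted_r2(r2, n=7, k=2) == pytest.approx(expected, abs=0.01)

    def test_perfect_fit_stays_perfect(self):
        for n in (5, 7, 20):
            assert adjusted_r2(1.0, n=n, k=2) == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, n=3, k=2)

    def test_negative_when_r2_below_k_over_nm1(self):
        assert adjusted_r2(0.19, n=7, k=2) < 0


class TestFitPvalue:
    def test_perfect_cosine_attains_minimum_p(self):
        """A perfect fit is beaten by no permutation: p reaches 1/(n_perm+1).

        The grid is irregular so that no rotation/reflection of the cosine
        lands back on the sampled values (on an equispaced grid such symmetry
        permutations tie with the observed fit and lift the minimum).
        """
        zts = np.array([0.0, 3, 5, 10, 14, 17, 21])
        y = cosine_series(zts, acrophase=1.3)
        fit = fit_ls(zts, y)
        assert fit_pvalue(zts, y, fit.r2, n_perm=999, seed=3) == pytest.approx(1 / 1000)

    def test_perfect_cosine_on_study_grid_is_highly_significant(self, zt_grid):
        """Equispaced sampling leaves a few symmetry ties, but p stays tiny."""
        y = cosine_series(zt_grid)
        fit = fit_ls(zt_grid, y)
        assert fit_pvalue(zt_grid, y, fit.r2, n_perm=999, seed=1) <= 0.01

    def test_seeded_determinism(self, zt_grid):
        rng = np.random.default_rng(2)
        y = rng.normal(size=zt_grid.size)
        r2 = fit_ls(zt_grid, y).r2
        assert fit_pvalue(zt_grid, y, r2, 199, seed=42) == fit_pvalue(
            zt_grid, y, r2, 199, seed=42
        )

    def test_null_p_is_roughly_uniform(self, zt_grid):
        """Flat-noise series give p values centered near 0.5."""
        rng = np.random.default_rng(77)
        ps = []
        for i in range(500):
            y = rng.normal(0, 1, zt_grid.size)
            r2 = fit_ls(zt_grid, y).r2
            ps.append(fit_pvalue(zt_grid, y, r2, n_perm=99, seed=i))
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_parametric_alternative_agrees_on_strong_signal(self, zt_grid):
        rng = np.random.default_rng(4)
        y = cosine_series(zt_grid, 0, 2.0, 6.0) + rng.normal(0, 0.2, zt_grid.size)
        assert cosinor_ftest(zt_grid, y) < 0.05


class TestPeakZt:
    def test_on_grid_acrophase(self, zt_grid):
        fit = fit_ls(zt_grid, cosine_series(zt_grid, acrophase=18.0))
        assert peak_zt(fit, zt_grid) == (pytest.approx(18.0), 18.0)

    def test_off_grid_rounds_circularly(self, zt_grid):
        fit = fit_ls(zt_grid, cosine_series(zt_grid, acrophase=7.9))
        cont, grid = peak_zt(fit, zt_grid)
        assert cont == pytest.approx(7.9)
        assert grid == 6.0

    def test_tie_breaks_toward_earlier_zt(self, zt_grid):
        fit = fit_ls(zt_grid, cosine_series(zt_grid, acrophase=4.0))
        assert peak_zt(fit, zt_grid)[1] == 2.0

    def test_flat_fit_has_no_peak(self, zt_grid):
        with pytest.warns(RuntimeWarning):
            fit = fit_ls(zt_grid, np.zeros(zt_grid.size))
        cont, grid = peak_zt(fit, zt_grid)
        assert math.isnan(cont) and math.isnan(grid)

    def test_wraparound_grid_point_reduces_mod_24(self, zt_grid):
        fit = fit_ls(zt_grid, cosine_series(zt_grid, acrophase=1.0))
        assert peak_zt(fit, zt_grid)[1] == 2.0


@given(
    r2=st.floats(0, 0.999),
    n=st.integers(5, 30),
)
@settings(max_examples=50, deadline=None)
def test_adjusted_r2_never_exceeds_r2(r2, n):
    assert adjusted_r2(r2, n, 2) <= r2
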