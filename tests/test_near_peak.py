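import numpy as np
import pytest
from scipy.integrate import quad

import genodensity as gd
from genodensity.density import DensityCurve

from conftest import random_landscape


class TestKernel:
    def test_value_at_origin(self):
        assert gd.kernel_K(0.0) == pytest.approx(np.log(2))

    def test_area(self):
        area, _ = quad(gd.kernel_K, 0, np.inf)
        assert area == pytest.approx(np.pi**2 / 12, rel=1e-8)

    def test_exponential_decay(self):
        assert gd.kernel_K(20.0) == pytest.approx(np.exp(-20.0), rel=1e-8)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            gd.kernel_K(-1.0)


class TestAlphaFromGamma:
    @pytest.mark.parametrize(
        "gamma,alpha", [(0.0, 0.5), (-0.5, 1 / 3), (1.0, 2 / 3)]
    )
    def test_known_values(self, gamma, alpha):
        assert gd.alpha_from_gamma(gamma) == pytest.approx(alpha)

    def test_monotone_increasing(self):
        gammas = np.linspace(-0.9, 5, 30)
        alphas = [gd.alpha_from_gamma(g) for g in gammas]
        assert np.all(np.diff(alphas) > 0)
        assert all(0 < a < 1 for a in alphas)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            gd.alpha_from_gamma(-1.0)


class TestBRegular:
    def test_inversion(self):
        assert gd.B_regular(3 / np.pi**2) == pytest.approx(1.0)

    def test_against_saddle_fit_oracle(self):
        # binary landscape with uniform gaps on (0, 2]: p_gap(0) = 0.5.
        # Fit B with alpha fixed at 1/2 to the saddle density of a large
        # landscape; the closed form must match the fit.
        ls = gd.generate_binary_from_gaps(
            5000, {"kind": "power_law", "gamma": 0.0, "scale": 2.0}, seed=3
        )
        s = gd.summarize(ls)
        eps = gd.near_peak_grid(s)
        curve = gd.rho_saddle(ls, (s.Fmax - s.L * eps)[::-1])
        fit = gd.fit_near_peak(curve, fix_alpha=0.5)
        assert fit.B == pytest.approx(gd.B_regular(0.5), rel=0.05)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            gd.B_regular(0.0)


def _synthetic_curve(A, B, alpha, L=100, n=120):
    eps = np.geomspace(1e-5, 1e-2, n)
    log_rho = L * (A + B * eps**alpha)
    Fmax = 0.0
    F = Fmax - L * eps
    return DensityCurve(F[::-1], log_rho[::-1], eps[::-1], "peak",
                        {"L": L, "C": 2, "Fmax": Fmax, "Fmean": -L})


class TestFitNearPeak:
    def test_exact_recovery_noiseless(self):
        curve = _synthetic_curve(A=-0.1, B=2.0, alpha=0.4)
        fit = gd.fit_near_peak(curve)
        assert fit.A == pytest.approx(-0.1, abs=1e-6)
        assert fit.B == pytest.approx(2.0, abs=1e-6)
        assert fit.alpha == pytest.approx(0.4, abs=1e-6)

    def test_fix_alpha_linear_recovery(self):
        curve = _synthetic_curve(A=0.05, B=1.3, alpha=0.5)
        fit = gd.fit_near_peak(curve, fix_alpha=0.5)
        assert fit.A == pytest.approx(0.05, abs=1e-10)
        assert fit.B == pytest.approx(1.3, abs=1e-8)

    def test_too_few_points_raises(self):
        curve = _synthetic_curve(A=0.0, B=1.0, alpha=0.5, n=10)
        with pytest.raises(ValueError, match="20"):
            gd.fit_near_peak(curve)

    @pytest.mark.parametrize("gamma", [-0.5, 0.0, 1.0])
    def test_exponent_recovery_binary(self, gamma):
        ls = gd.generate_binary_from_gaps(
            2000, {"kind": "power_law", "gamma": gamma, "scale": 1.0}, seed=11
        )
        s = gd.summarize(ls)
        eps = gd.near_peak_grid(s)
        curve = gd.rho_saddle(ls, (s.Fmax - s.L * eps)[::-1])
        fit = gd.fit_near_peak(curve)
        assert fit.alpha == pytest.approx(gd.alpha_from_gamma(gamma), abs=0.05)

    def test_exponent_invariant_to_added_deep_characters(self):
        # appending large-deficit characters (C=4) must not move alpha
        base = gd.generate_binary_from_gaps(
            2000, {"kind": "power_law", "gamma": 0.0, "scale": 1.0}, seed=21
        )
        deep = np.full((2000, 2), -30.0)
        wide = gd.AdditiveLandscape(
            0.0, np.hstack([base.theta, deep]), ("0", "1", "2", "3")
        )
        fits = []
        for ls in (base, wide):
            s = gd.summarize(ls)
            # same absolute deficit window for both alphabets: the wide
            # landscape's Fmean sits far lower, so the default window moves
            eps = gd.near_peak_grid(s, eps_min=2.5e-4, eps_max=0.025)
            curve = gd.rho_saddle(ls, (s.Fmax - s.L * eps)[::-1])
            fits.append(gd.fit_near_peak(curve).alpha)
        assert abs(fits[0] - fits[1]) < 0.03

    def test_hamming_alpha_approaches_one(self):
        # fixed gaps: log rho ~ eps(1 - ln eps), whose local exponent
        # (-ln eps)/(1 - ln eps) runs 0.75-0.88 over the default window and
        # tends to 1 as eps -> 0; well above any power-law gap value
        ls = gd.generate_binary_from_gaps(500, {"kind": "fixed", "delta0": 1.0})
        s = gd.summarize(ls)
        eps = gd.near_peak_grid(s)
        curve = gd.rho_saddle(ls, (s.Fmax - s.L * eps)[::-1])
        fit = gd.fit_near_peak(curve)
        assert 0.72 < fit.alpha <= 1.0


class TestRhoPeak:
    def test_unique_optimum_limit(self, toy):
        s = gd.summarize(toy)
        fit = gd.PeakFit(A=0.0, B=1.0, alpha=0.5, fit_region=(1e-6, 1e-2),
                         residual_rms=0.0)
        F = np.array([s.Fmax - 1e-12])
        c = gd.rho_peak(fit, s, F)
        assert c.log_rho[0] == pytest.approx(0.0, abs=1e-4)

    def test_tie_count_from_A(self):
        theta = np.array([[0.0, 0.0], [0.0, -1.0]])
        ls = gd.AdditiveLandscape(0.0, theta, ("a", "b"))
        s = gd.summarize(ls)
        fit = gd.PeakFit(A=np.log(s.n_ties) / s.L, B=1.0, alpha=0.5,
                         fit_region=(1e-6, 1e-2), residual_rms=0.0)
        c = gd.rho_peak(fit, s, np.array([s.Fmax - 1e-14]))
        assert np.exp(c.log_rho[0]) == pytest.approx(s.n_ties, rel=1e-5)

    def test_monotone_in_eps(self, toy):
        s = gd.summarize(toy)
        fit = gd.PeakFit(A=0.0, B=2.0, alpha=0.6, fit_region=(1e-6, 1e-2),
                         residual_rms=0.0)
        c = gd.rho_peak(fit, s, np.linspace(0.5, 2.9, 50))
        assert np.all(np.diff(c.log_rho) < 0)  # increasing in eps = decreasing in F

    def test_rejects_f_at_or_above_fmax(self, toy):
        s = gd.summarize(toy)
        fit = gd.PeakFit(A=0.0, B=1.0, alpha=0.5, fit_region=(1e-6, 1e-2),
                         residual_rms=0.0)
        with pytest.raises(ValueError):
            gd.rho_peak(fit, s, np.array([3.0]))


def _pipeline(ls):
    s = gd.summarize(ls)
    eps = gd.near_peak_grid(s)
    fit = gd.fit_near_peak(gd.rho_saddle(ls, (s.Fmax - s.L * eps)[::-1]))
    margin = 1e-4 * (s.Fmax - s.Fmean)
    grid = np.linspace(s.Fmean + margin, s.Fmax - margin, 512)
    peak = gd.rho_peak(fit, s, grid)
    bulk = gd.rho_bulk(ls, grid)
    saddle = gd.rho_saddle(ls, grid)
    return s, fit, peak, bulk, saddle


class TestCrossover:
    def test_simulated_gaussian_landscapes_in_printed_range(self):
        rs = []
        for C in (4, 20):
            per_seed = [
                gd.crossover(*_pipeline(gd.generate_iid(100, C, seed=seed))[2:]).r
                for seed in (1, 2, 3)
            ]
            rs.append(np.mean(per_seed))
        assert all(0.26 - 0.03 <= r <= 0.34 + 0.03 for r in rs)

    def test_r_independent_of_L(self):
        # the crossover equation is L-free only to leading order; the
        # saddle prefactor adds an O(log L / L) shift, so the invariance is
        # checked between lengths where that correction is already small
        rs = {}
        for L in (100, 200):
            vals = [
                gd.crossover(*_pipeline(gd.generate_iid(L, 4, seed=seed))[2:]).r
                for seed in range(1, 9)
            ]
            rs[L] = np.mean(vals)
        assert abs(rs[100] - rs[200]) < 0.03

    def test_gauge_invariance_under_theta0_shift(self):
        ls = gd.generate_iid(100, 4, seed=9)
        shifted = gd.AdditiveLandscape(ls.theta0 + 7.0, ls.theta, ls.alphabet)
        res0 = gd.crossover(*_pipeline(ls)[2:])
        res1 = gd.crossover(*_pipeline(shifted)[2:])
        s0 = gd.summarize(ls)
        s1 = gd.summarize(shifted)
        assert s1.Fmax - res1.F_cross == pytest.approx(
            s0.Fmax - res0.F_cross, abs=1e-6
        )
        assert res1.r == pytest.approx(res0.r, abs=1e-6)

    def test_peak_beats_bulk_above_crossover(self):
        s, fit, peak, bulk, saddle = _pipeline(gd.generate_iid(100, 4, seed=2))
        res = gd.crossover(peak, bulk, saddle)
        above = peak.F > res.F_cross + 0.02 * (s.Fmax - s.Fmean)
        err_peak = np.abs(peak.log_rho - saddle.log_rho)[above]
        err_bulk = np.abs(bulk.log_rho - saddle.log_rho)[above]
        assert np.all(err_peak <= err_bulk)

    def test_no_crossover_raises(self, toy):
        grid = np.linspace(1.6, 2.9, 30)
        bulk = gd.rho_bulk(toy, grid)
        saddle = gd.rho_saddle(toy, grid)
        with pytest.raises(ValueError, match="crossover"):
            gd.crossover(bulk, bulk, saddle)


class TestSandwichBound:
    def test_binary_restriction_brackets_full_deficit(self):
        # E_bin <= E <= (C-1) E_bin across random landscapes and beta grids
        rng = np.random.default_rng(30)
        betas = np.linspace(0.0, 20.0, 20)
        for _ in range(100):
            C = int(rng.choice([3, 4, 20]))
            ls = random_landscape(rng, L=int(rng.integers(3, 10)), C=C)
            theta = ls.theta
            order = np.argsort(theta, axis=1)
            top2 = np.take_along_axis(theta, order[:, -2:], axis=1)
            binary = gd.AdditiveLandscape(0.0, top2, ("r", "m"))
            for beta in betas:
                E = gd.deficit_contribution(ls, beta)
                Ebin = gd.deficit_contribution(binary, beta)
                assert Ebin <= E + 1e-12
                assert E <= (C - 1) * Ebin + 1e-12


class TestGapExponent:
    def test_uniform_gaps(self):
        rng = np.random.default_rng(40)
        est = gd.estimate_gap_exponent(rng.uniform(0, 1, 10_000))
        assert est.gamma == pytest.approx(0.0, abs=0.1)
        assert not est.fixed_gap

    def test_enriched_small_gaps(self):
        rng = np.random.default_rng(41)
        gaps = rng.random(10_000) ** 2  # density ~ Delta^(-1/2)
        est = gd.estimate_gap_exponent(gaps)
        assert est.gamma == pytest.approx(-0.5, abs=0.1)

    def test_fixed_gap_regime_flagged(self):
        est = gd.estimate_gap_exponent(np.ones(100))
        assert est.fixed_gap

    def test_too_few_gaps(self):
        with pytest.raises(ValueError, match="50"):
            gd.estimate_gap_exponent(np.ones(10) * 0.5)
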