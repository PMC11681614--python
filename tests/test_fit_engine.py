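"""Regime partitioning, apparent/replot/global fits, product inhibition."""

import numpy as np
import pytest

from ssadhkin import (InhibitoryRegimeParams, OrderedBiBiParams,
                      PartialSubstrateInhibitionParams, RateDataset,
                      RateObservation, eval_inhibitory_regime,
                      eval_ordered_bibi, eval_partial_substrate_inhibition,
                      fit_apparent, global_fit, partition_regimes,
                      product_inhibition_analysis, replot_secondary,
                      select_model, uncertainty)
from ssadhkin._fitting import fit_least_squares
from ssadhkin.synthetic import (DESIGN_14C, DesignSpec, NoiseModel,
                                gen_product_inhibition, gen_rate_grid)
from conftest import make_dataset


class TestPartition:
    def test_paper_ranges(self):
        obs = [RateObservation(ssa_um=s, nad_um=100, rate=1.0)
               for s in (1, 5, 10, 12, 50, 200)]
        parts = partition_regimes(RateDataset(obs))
        assert sorted(parts["subinhibitory"].ssa) == [1, 5, 10]
        assert sorted(parts["inhibitory"].ssa) == [12, 50, 200]

    def test_gap_excluded(self):
        obs = [RateObservation(ssa_um=11, nad_um=100, rate=1.0)]
        with pytest.warns(UserWarning, match="subset is empty"):
            parts = partition_regimes(RateDataset(obs))
        assert len(parts["subinhibitory"]) == 0
        assert len(parts["inhibitory"]) == 0

    def test_empty_subset_warns(self):
        obs = [RateObservation(ssa_um=s, nad_um=100, rate=1.0)
               for s in (1, 2, 5)]
        with pytest.warns(UserWarning, match="inhibitory subset is empty"):
            parts = partition_regimes(RateDataset(obs))
        assert len(parts["inhibitory"]) == 0


class TestApparentFits:
    def test_zero_noise_mm_exact(self):
        d = make_dataset(lambda a, s: 100 * a / (30 + a),
                         ssa_grid=[5.0], nad_grid=[5, 15, 30, 60, 120, 500])
        fits = fit_apparent(d, fixed="ssa", model="eq1")
        p = fits[5.0]
        assert p.vmax == pytest.approx(100, rel=1e-8)
        assert p.km == pytest.approx(30, rel=1e-8)

    def test_apparent_matches_algebraic_reduction_of_partial_law(self):
        """At fixed subinhibitory SSA, the NAD+ saturation curve of the
        partial-inhibition law is exactly Michaelis–Menten with
        appVmax = Vmax*B(1+b*B/Kis)/(K_B+B(1+B/Kis)) and
        appKm = (K_iA*K_B+K_A*B)/(K_B+B(1+B/Kis))."""
        p = PartialSubstrateInhibitionParams(vmax=26, k_a=31, k_b=1.2,
                                             k_ia=31, k_is=13, b=0.06)
        b = 5.0
        d = make_dataset(lambda a, s: eval_partial_substrate_inhibition(a, s, p),
                         ssa_grid=[b], nad_grid=[5, 10, 25, 50, 100, 250, 500])
        fits = fit_apparent(d, fixed="ssa", model="eq1")
        denom = p.k_b + b * (1 + b / p.k_is)
        app_vmax = p.vmax * b * (1 + p.b * b / p.k_is) / denom
        app_km = (p.k_ia * p.k_b + p.k_a * b) / denom
        assert fits[b].vmax == pytest.approx(app_vmax, rel=1e-6)
        assert fits[b].km == pytest.approx(app_km, rel=1e-6)

    def test_substrate_inhibition_apparent(self):
        d = make_dataset(
            lambda a, s: 100 * s / (2 + s * (1 + s / 15)),
            ssa_grid=[1, 2, 5, 10, 25, 50, 100], nad_grid=[500.0])
        fits = fit_apparent(d, fixed="nad", model="eq2")
        p = fits[500.0]
        assert p.vmax == pytest.approx(100, rel=1e-6)
        assert p.km == pytest.approx(2, rel=1e-5)
        assert p.ki == pytest.approx(15, rel=1e-5)

    def test_noisy_apparent_vmax_within_10pc(self):
        rng = np.random.default_rng(8)
        conc = np.array([5, 15, 30, 60, 120, 250, 500.0])
        clean = 100 * conc / (30 + conc)
        noisy = clean * (1 + 0.05 * rng.standard_normal(conc.size))
        obs = [RateObservation(ssa_um=5.0, nad_um=a, rate=r)
               for a, r in zip(conc, noisy)]
        fits = fit_apparent(RateDataset(obs), fixed="ssa", model="eq1")
        assert fits[5.0].vmax == pytest.approx(100, rel=0.10)

    def test_insufficient_points_skipped(self):
        d = make_dataset(lambda a, s: 100 * a / (30 + a),
                         ssa_grid=[5.0], nad_grid=[10, 50, 100])
        with pytest.warns(UserWarning, match="fewer than 4"):
            fits = fit_apparent(d, fixed="ssa", model="eq1")
        assert fits == {}


class TestReplotSecondary:
    def test_zero_noise_bibi_exact(self, bibi_params):
        d = make_dataset(lambda a, s: eval_ordered_bibi(a, s, bibi_params),
                         ssa_grid=[0.5, 1, 2, 5, 10],
                         nad_grid=[2, 5, 10, 25, 50])
        apparent = fit_apparent(d, fixed="ssa", model="eq1")
        est, flags = replot_secondary(apparent)
        assert est.vmax == pytest.approx(100, rel=1e-6)
        assert est.k_a == pytest.approx(10, rel=1e-6)
        assert est.k_b == pytest.approx(1, rel=1e-6)
        assert est.k_ia == pytest.approx(5, rel=1e-6)
        assert flags["reliable"]

    def test_agrees_with_global_fit_zero_noise(self, bibi_params):
        d = make_dataset(lambda a, s: eval_ordered_bibi(a, s, bibi_params),
                         ssa_grid=[0.5, 1, 2, 5, 10],
                         nad_grid=[2, 5, 10, 25, 50])
        apparent = fit_apparent(d, fixed="ssa", model="eq1")
        est, _ = replot_secondary(apparent)
        gfit = global_fit(d, model="eq3")
        for name in ("vmax", "k_a", "k_b", "k_ia"):
            assert getattr(est, name) == pytest.approx(
                getattr(gfit.params, name), rel=0.01)

    def test_noisy_vmax_within_20pc(self, bibi_params):
        rng = np.random.default_rng(17)
        obs = []
        for s in (0.5, 1, 2, 5, 10):
            for a in (2, 5, 10, 25, 50):
                clean = eval_ordered_bibi(a, s, bibi_params)
                obs.append(RateObservation(
                    ssa_um=s, nad_um=a,
                    rate=float(clean * (1 + 0.05 * rng.standard_normal()))))
        apparent = fit_apparent(RateDataset(obs), fixed="ssa", model="eq1")
        est, _ = replot_secondary(apparent)
        assert est.vmax == pytest.approx(100, rel=0.20)

    def test_two_levels_rejected(self, bibi_params):
        from ssadhkin import MMParams
        apparent = {1.0: MMParams(10, 5), 2.0: MMParams(20, 5)}
        with pytest.raises(ValueError):
            replot_secondary(apparent)


class TestGlobalFit:
    def test_eq5_zero_noise_exact(self):
        truth = PartialSubstrateInhibitionParams(
            vmax=26, k_a=31, k_b=1.2, k_ia=31, k_is=13, b=0.06)
        d = gen_rate_grid(truth, DESIGN_14C)
        fit = global_fit(d, model="eq5")
        for name, want in vars(truth).items():
            assert getattr(fit.params, name) == pytest.approx(want, rel=1e-6)
        assert fit.converged

    def test_eq4_zero_noise_exact(self):
        truth = InhibitoryRegimeParams(vmax=165, k_a=32, k_is=5, k_ix=84,
                                       k_ii=7)
        d = make_dataset(lambda a, s: eval_inhibitory_regime(a, s, truth),
                         ssa_grid=[12, 25, 50, 100, 200],
                         nad_grid=[10, 25, 50, 100, 250, 500])
        fit = global_fit(d, model="eq4")
        for name, want in vars(truth).items():
            assert getattr(fit.params, name) == pytest.approx(want, rel=1e-5)

    def test_random_zero_noise_recovery_all_models(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            truth = PartialSubstrateInhibitionParams(
                vmax=10.0 ** rng.uniform(1, 2.3),
                k_a=10.0 ** rng.uniform(0.8, 2),
                k_b=10.0 ** rng.uniform(-0.3, 0.7),
                k_ia=10.0 ** rng.uniform(0.8, 2),
                k_is=10.0 ** rng.uniform(0.7, 1.5),
                b=rng.uniform(0.02, 0.3))
            d = gen_rate_grid(truth, DESIGN_14C)
            fit = global_fit(d, model="eq5", n_starts=6)
            for name, want in vars(truth).items():
                assert getattr(fit.params, name) == pytest.approx(
                    want, rel=1e-4), name

    def test_regime_mismatch_rejected(self):
        truth = PartialSubstrateInhibitionParams(
            vmax=26, k_a=31, k_b=1.2, k_ia=31, k_is=13, b=0.06)
        d = gen_rate_grid(truth, DESIGN_14C)  # contains SSA up to 500
        with pytest.raises(ValueError, match="regime mismatch"):
            global_fit(d, model="eq3")

    def test_ordering_and_unit_scale_invariance(self):
        truth = PartialSubstrateInhibitionParams(
            vmax=26, k_a=31, k_b=1.2, k_ia=31, k_is=13, b=0.06)
        d = gen_rate_grid(truth, DESIGN_14C, NoiseModel(cv=0.05, seed=6))
        fit1 = global_fit(d, model="eq5")
        shuffled = RateDataset(list(reversed(d.observations)))
        fit2 = global_fit(shuffled, model="eq5")
        assert fit1.params.vmax == pytest.approx(fit2.params.vmax, rel=1e-6)
        # express the same rates as uM/s with the design enzyme conc
        scaled_obs = [RateObservation(
            ssa_um=o.ssa_um, nad_um=o.nad_um, rate=o.rate * o.enzyme_um,
            rate_units="um_per_s", enzyme_um=o.enzyme_um)
            for o in d.observations]
        fit3 = global_fit(RateDataset(scaled_obs), model="eq5")
        assert fit3.params.vmax == pytest.approx(fit1.params.vmax, rel=1e-6)
        assert fit3.params.k_b == pytest.approx(fit1.params.k_b, rel=1e-6)

    def test_aic_detects_substrate_inhibition(self):
        """On data carrying real substrate inhibition, both AIC and BIC
        prefer the partial-inhibition law over the plain bi-bi law."""
        truth5 = PartialSubstrateInhibitionParams(
            vmax=26, k_a=31, k_b=1.2, k_ia=31, k_is=13, b=0.06)
        d5 = gen_rate_grid(truth5, DESIGN_14C, NoiseModel(cv=0.05, seed=30))
        best, fits = select_model(d5, ("eq3", "eq5"), criterion="bic")
        assert best == "eq5"
        assert fits["eq5"].aic < fits["eq3"].aic


class TestProductInhibition:
    def test_competitive_zero_noise(self, bibi_params):
        d = gen_product_inhibition(bibi_params, ki_nadh_um=30.0)
        res = product_inhibition_analysis(d)
        assert res.pattern == "competitive"
        assert res.ki_um == pytest.approx(30.0, rel=1e-8)
        assert abs(res.convergence_point[0]) < 1e-10

    def test_uncompetitive_counterexample(self, bibi_params):
        # intercept-only effect: v = v0/(1 + I/Ki) at each level -> parallel
        # double-reciprocal lines shifted vertically
        nad = np.array([10, 25, 50, 100, 250, 500.0])
        obs, levels = [], []
        for i_conc in (17, 55, 110, 220.0):
            factor = 1 + i_conc / 60.0
            for a in nad:
                v = eval_ordered_bibi(a, 10.0, bibi_params)
                # uncompetitive: both slope and intercept cannot converge
                # on the y-axis; scale v so 1/v gains a constant offset
                obs.append(RateObservation(ssa_um=10.0, nad_um=float(a),
                                           rate=float(1 / (1 / v + 0.002 * factor))))
                levels.append(i_conc)
        d = RateDataset(obs, nadh_um=np.array(levels))
        res = product_inhibition_analysis(d)
        assert res.pattern != "competitive"

    def test_noisy_ki_within_25pc(self, bibi_params):
        d = gen_product_inhibition(bibi_params, ki_nadh_um=30.0,
                                   noise=NoiseModel(cv=0.05, seed=44))
        res = product_inhibition_analysis(d)
        assert res.ki_um == pytest.approx(30.0, rel=0.25)

    def test_no_inhibition_ambiguous(self, bibi_params):
        d = gen_product_inhibition(bibi_params, ki_nadh_um=1e12)
        res = product_inhibition_analysis(d)
        assert res.pattern == "ambiguous"

    def test_needs_levels(self, bibi_params):
        d = gen_product_inhibition(bibi_params, ki_nadh_um=30.0,
                                   nadh_um_list=(17.0, 55.0))
        with pytest.raises(ValueError):
            product_inhibition_analysis(d)


class TestUncertainty:
    def test_covariance_matches_analytic_ols(self):
        """Jacobian-based SE equals the closed-form OLS slope/intercept SE."""
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 30)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.5, x.size)

        fit = fit_least_squares(lambda th: th[0] + th[1] * x - y,
                                [0.0, 1.0], ["intercept", "slope"])
        n = x.size
        resid = y - (fit.params["intercept"] + fit.params["slope"] * x)
        s2 = resid @ resid / (n - 2)
        sxx = np.sum((x - x.mean()) ** 2)
        se_slope = np.sqrt(s2 / sxx)
        se_inter = np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
        assert fit.stderr["slope"] == pytest.approx(se_slope, rel=1e-8)
        assert fit.stderr["intercept"] == pytest.approx(se_inter, rel=1e-8)

    def test_bootstrap_collapses_at_zero_noise(self):
        truth = PartialSubstrateInhibitionParams(
            vmax=26, k_a=31, k_b=1.2, k_ia=31, k_is=13, b=0.06)
        d = gen_rate_grid(truth, DESIGN_14C)
        fit = global_fit(d, model="eq5")
        se = uncertainty(fit, method="bootstrap", n_boot=20, seed=1)
        assert all(v < 1e-6 for v in se.values())

    def test_bootstrap_and_covariance_agree_within_factor_2(self):
        truth = PartialSubstrateInhibitionParams(
            vmax=26, k_a=31, k_b=1.2, k_ia=31, k_is=13, b=0.06)
        d = gen_rate_grid(truth, DESIGN_14C, NoiseModel(cv=0.05, seed=12))
        fit = global_fit(d, model="eq5")
        cov = uncertainty(fit, method="covariance")
        boot = uncertainty(fit, method="bootstrap", n_boot=150, seed=2)
        for name in ("vmax", "k_a", "k_b", "b"):
            ratio = boot[name] / cov[name]
            assert 0.5 < ratio < 2.0, name
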