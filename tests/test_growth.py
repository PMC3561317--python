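"""Turbidostat cycle segmentation, exponential fits, Platt light response."""

import numpy as np
import pytest

from photophys import growth as gr
from photophys import synthdata as sd


class TestSegmentation:
    def test_monotone_trace_is_one_cycle(self):
        t = np.linspace(0, 10, 50)
        tr = gr.TurbidostatTrace(t, 0.3 * np.exp(0.05 * t))
        cycles = gr.segment_cycles(tr)
        assert len(cycles) == 1
        assert (cycles[0].start_index, cycles[0].end_index) == (0, 49)

    def test_simulated_dilutions_all_detected(self):
        tr = sd.sim_turbidostat(1.8, n_cycles=12, noise_sd=0.0)
        cycles = gr.segment_cycles(tr)
        assert len(cycles) == 12

    def test_post_to_pre_dilution_ratio(self):
        tr = sd.sim_turbidostat(2.0, n_cycles=8, noise_sd=0.0)
        cycles = gr.segment_cycles(tr)
        for prev, nxt in zip(cycles[:-1], cycles[1:]):
            ratio = tr.od680[nxt.start_index] / tr.od680[prev.end_index]
            assert ratio == pytest.approx(0.9, abs=0.01)

    def test_threshold_validation(self):
        tr = sd.sim_turbidostat(1.8, noise_sd=0.0)
        with pytest.raises(ValueError):
            gr.segment_cycles(tr, drop_threshold=0.5)

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            gr.TurbidostatTrace([0, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError, match="od680"):
            gr.TurbidostatTrace([0, 1, 2], [1, -1, 1])


class TestCycleFit:
    def test_constant_od_gives_zero(self):
        mu, r2 = gr.fit_cycle_mu(np.linspace(0, 2, 10), np.full(10, 0.4))
        assert mu == 0.0

    def test_noiseless_exponential_recovered_exactly(self):
        t = np.linspace(0, 1.4, 12)
        od = 0.36 * np.exp(1.5 / 24 * t)
        mu, r2 = gr.fit_cycle_mu(t, od)
        assert mu == pytest.approx(1.5, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            gr.fit_cycle_mu([0, 1, 2, 3], [1, 2, 0, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gr.fit_cycle_mu([0, 1, 2], [1, 2, 3])


class TestMeanGrowthRate:
    def test_identical_cycles(self):
        cycles = [gr.DilutionCycle(0, 5, mu=2.0) for _ in range(10)]
        mu, sdv = gr.mean_growth_rate(cycles)
        assert (mu, sdv) == (2.0, 0.0)

    def test_uses_last_n(self):
        cycles = [gr.DilutionCycle(0, 5, mu=float(k)) for k in range(15)]
        mu, _ = gr.mean_growth_rate(cycles, n_last=10)
        assert mu == np.mean(range(5, 15))

    def test_n_last_larger_than_available(self):
        cycles = [gr.DilutionCycle(0, 5, mu=1.0) for _ in range(3)]
        mu, _ = gr.mean_growth_rate(cycles, n_last=10)
        assert mu == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gr.mean_growth_rate([])


class TestTurbidostatSteadyState:
    def test_cycle_period_links_to_growth_rate(self):
        # mu * T_cycle = ln(1/(1-f)) for the simulated steady state
        for mu in (0.8, 1.8, 2.3):
            tr = sd.sim_turbidostat(mu, n_cycles=10, noise_sd=0.01, seed=5)
            cycles = gr.analyze_trace(tr)
            t_cycle = np.mean([c.duration for c in cycles[1:-1]])
            assert mu / 24 * t_cycle == pytest.approx(np.log(1 / 0.9), rel=0.08)


class TestPlatt:
    TRUTH = (3.5, 0.05, 0.004)

    def test_zero_noise_recovers_parameters(self):
        i = np.array([30, 80, 160, 240, 380] * 3, float)
        fit = gr.fit_platt(i, gr.platt_mu(i, *self.TRUTH))
        assert fit.mu_s == pytest.approx(3.5, rel=1e-4)
        assert fit.alpha == pytest.approx(0.05, rel=1e-4)
        assert fit.beta == pytest.approx(0.004, rel=1e-4)

    def test_mu_max_equals_numeric_maximum(self):
        grid = np.linspace(0.01, 2000, 400001)
        numeric = gr.platt_mu(grid, *self.TRUTH).max()
        assert gr.platt_mu_max(*self.TRUTH) == pytest.approx(numeric, rel=1e-6)

    def test_beta_zero_limit(self):
        assert gr.platt_mu_max(3.5, 0.05, 0.0) == 3.5
        assert gr.platt_i_opt(3.5, 0.05, 0.0) == np.inf
        i = np.array([20, 60, 150, 300, 500], float)
        fit = gr.fit_platt(i, gr.platt_mu(i, 3.5, 0.05, 0.0), fit_beta=False)
        assert fit.mu_max == pytest.approx(fit.mu_s)

    def test_curve_maximum_at_i_opt(self):
        i_opt = gr.platt_i_opt(*self.TRUTH)
        mm = gr.platt_mu_max(*self.TRUTH)
        assert gr.platt_mu(i_opt, *self.TRUTH) == pytest.approx(mm, rel=1e-12)

    def test_fitted_mu_max_can_exceed_observed(self):
        # sparse sampling away from the optimum: the fitted peak exceeds
        # every measured point
        i = np.array([30, 80, 160, 240, 380] * 3, float)
        rng = np.random.default_rng(3)
        mu = gr.platt_mu(i, 3.4, 0.031, 0.008) + rng.normal(0, 0.05, i.size)
        fit = gr.fit_platt(i, mu)
        assert fit.mu_max > 0.95 * mu.max()
        assert fit.ci95["mu_max"] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            gr.fit_platt([100, 100, 100, 100], [1, 1.1, 0.9, 1.0])
        with pytest.raises(ValueError, match="degenerate|identical"):
            gr.fit_platt([10, 50, 100, 200], [1.0, 1.0, 1.0, 1.0])

    def test_sklearn_estimator_interface(self):
        est = gr.PlattLightResponse()
        assert est.get_params() == {"fit_beta": True}
        i = np.array([30, 80, 160, 240, 380], float)
        est.fit(i.reshape(-1, 1), gr.platt_mu(i, *self.TRUTH))
        pred = est.predict([160.0])
        assert pred[0] == pytest.approx(gr.platt_mu(160, *self.TRUTH), rel=1e-3)
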