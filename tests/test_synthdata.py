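"""Generator determinism, noiseless model identities, truth recovery."""

import numpy as np
import pytest

from photophys import carbonate as cb
from photophys import fire as fr
from photophys import growth as gr
from photophys import photoinact as pi
from photophys import synthdata as sd


class TestDeterminism:
    def test_turbidostat_identical_bytes(self):
        a = sd.sim_turbidostat(1.8, seed=42)
        b = sd.sim_turbidostat(1.8, seed=42)
        assert a.od680.tobytes() == b.od680.tobytes()

    def test_study_identical_files(self, tmp_path):
        design = sd.StudyDesign(light_levels=(30.0,), replicates=1, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.write_dataset(sd.sim_study(design), d1)
        sd.write_dataset(sd.sim_study(design), d2)
        for f in d1.iterdir():
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_streams_independent(self):
        # the induction stream does not perturb the turbidostat stream
        a = sd.sim_turbidostat(1.8, seed=5)
        sd.sim_induction(noise_sd=0.01, seed=5)
        b = sd.sim_turbidostat(1.8, seed=5)
        assert np.array_equal(a.od680, b.od680)


class TestNoiselessIdentities:
    def test_turbidostat_cycle_duration_closed_form(self):
        mu = 1.8
        tr = sd.sim_turbidostat(mu, noise_sd=0.0, n_cycles=6)
        cycles = gr.segment_cycles(tr)
        expected = np.log(1 / 0.9) / (mu / 24)
        for c in cycles[1:-1]:
            assert c.duration == pytest.approx(expected, abs=2 / 60)

    def test_induction_matches_model_exactly(self):
        cur = sd.sim_induction(f0=280, fm=700, sigma=300, p=0.0, noise_sd=0.0)
        expect = 280 + 420 * (1 - np.exp(-300 * cur.dose))
        assert np.allclose(cur.fluorescence, expect, rtol=1e-12)

    def test_lightshift_active_fraction_closed_form(self):
        s = sd.sim_lightshift(sigma_i=8e-5, k_rep=0, npq_amp=0, noise_sd=0.0)
        dose90 = pi.photon_dose(450, 90 * 60)
        assert s.fvfm[s.time == 90][0] / 0.65 == pytest.approx(
            np.exp(-8e-5 * dose90), rel=1e-12
        )

    def test_lightshift_repair_equilibrium(self):
        k_rep = 5e-3  # fast repair: Fv/Fm nearly flat at the steady state
        s = sd.sim_lightshift(sigma_i=8e-5, k_rep=k_rep, lincomycin=False,
                              noise_sd=0.0)
        k_pi = 8e-5 * pi.photon_flux(450)
        a_eq = k_rep / (k_rep + k_pi)
        tre = s.phase == "treatment"
        assert s.fvfm[tre][-1] / 0.65 == pytest.approx(a_eq, rel=0.01)

    def test_carbonate_self_consistency(self):
        inputs = sd.sim_carbonate(390.0, ta_base=2300.0, n=1)
        st = cb.solve_sample(inputs[0])
        assert st.pco2 == pytest.approx(390.0, rel=1e-3)
        assert st.ta == pytest.approx(2300.0, rel=1e-4)

    def test_carbonate_elevated_doubles_free_co2(self):
        amb = cb.solve_sample(sd.sim_carbonate(390.0, n=1)[0])
        ele = cb.solve_sample(sd.sim_carbonate(750.0, n=1)[0])
        assert ele.co2 / amb.co2 == pytest.approx(750 / 390, rel=0.01)


class TestUmbrellaRecovery:
    """Pipeline(sim_study(truth)) recovers truth at default noise."""

    def test_each_stage_recovers_truth(self, small_bundle):
        tru = small_bundle["truth"]
        # growth
        for cid, sub in small_bundle["trace"].groupby("culture_id"):
            tr = gr.TurbidostatTrace(sub.time_h.to_numpy(), sub.od680.to_numpy())
            mu, _ = gr.mean_growth_rate(gr.analyze_trace(tr))
            assert mu == pytest.approx(tru[cid]["mu"], rel=0.08)
        # sigma_PSII (dark state)
        fdf = small_bundle["fire"]
        for cid, sub in fdf[fdf.state == "dark"].groupby("culture_id"):
            cur = fr.InductionCurve(sub.time_us.to_numpy(),
                                    sub.fluorescence.to_numpy(),
                                    float(sub.flux_photons_a2_s.iloc[0]))
            y = fr.fit_induction(cur)
            assert y.sigma_psii == pytest.approx(tru[cid]["sigma_psii"], rel=0.06)
        # sigma_i (lincomycin flask)
        ls = small_bundle["lightshift"]
        for cid, sub in ls[ls.lincomycin == 1].groupby("culture_id"):
            s = pi.LightShiftSeries(
                sub.time_min.to_numpy(), sub.fvfm.to_numpy(),
                sub.phase.to_numpy(), True,
                growth_irradiance=float(sub.light.iloc[0]),
            )
            corr, _ = pi.npq_correct(s)
            fit = pi.fit_sigma_i(corr)
            assert fit.sigma_i == pytest.approx(tru[cid]["sigma_i"], rel=0.15)

    def test_truth_manifest_complete(self, small_bundle):
        needed = {"mu", "sigma_psii", "sigma_i", "qp", "chl_pg_cell",
                  "mda_attomol_cell", "cn_molar", "group", "light"}
        for cid, entry in small_bundle["truth"].items():
            assert needed <= set(entry)

    def test_study_shaped_ranges(self):
        # spans of the built-in light responses match the observed study
        # ranges they emulate
        lights = np.array([30.0, 80, 160, 240, 380])
        sig = [sd.sigma_psii_truth(l) for l in lights]
        assert max(sig) == pytest.approx(322, abs=1) and min(sig) == pytest.approx(210, abs=1)
        mus = gr.platt_mu(lights, *sd.PLATT_TRUTH[390])
        si = [sd.sigma_i_truth(390, m) for m in mus]
        assert 7.0e-5 < min(si) < 7.5e-5 and 9.0e-5 < max(si) < 9.6e-5
        qps = [sd.qp_truth(l) for l in lights]
        assert max(qps) == pytest.approx(0.89, abs=0.01)
        assert min(qps) == pytest.approx(0.63, abs=0.01)


class TestValidation:
    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            sd.sim_turbidostat(-1.0)
        with pytest.raises(ValueError):
            sd.sim_induction(f0=700, fm=280)
        with pytest.raises(ValueError):
            sd.sim_lightshift(sigma_i=-1e-5)
        with pytest.raises(ValueError):
            sd.sim_carbonate(-100.0)
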