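"""Carbonate system: constants, speciation, alkalinity, pH inversion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from photophys import carbonate as cb


class TestConstants:
    def test_k0_matches_weiss_closed_form(self):
        # independent evaluation of the Weiss (1974) solubility polynomial
        tk = 291.15
        lnk0 = (
            -60.2409
            + 93.4517 * 100 / tk
            + 23.3585 * np.log(tk / 100)
            + 35 * (0.023517 - 0.023656 * tk / 100 + 0.0047036 * (tk / 100) ** 2)
        )
        c = cb.equilibrium_constants(18, 35)
        assert c.k0 == pytest.approx(np.exp(lnk0), rel=1e-12)
        assert c.k0 == pytest.approx(0.0343, rel=0.01)

    @pytest.mark.parametrize("t,s", [(0.5, 5), (10, 30), (18, 35), (30, 40)])
    @pytest.mark.parametrize("form", ["dm87", "mehrbach"])
    def test_dissociation_ordering(self, t, s, form):
        c = cb.equilibrium_constants(t, s, form)
        assert c.k1 > c.k2 > 0
        assert all(x > 0 for x in (c.k0, c.kb, c.kw, c.kp2, c.kp3, c.ksi, c.bt))

    def test_borate_proportional_to_salinity(self):
        c30 = cb.equilibrium_constants(18, 30)
        c40 = cb.equilibrium_constants(18, 40)
        assert c40.bt / c30.bt == pytest.approx(40 / 30, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs,field",
        [(dict(temperature=-5, salinity=35), "temperature"),
         (dict(temperature=18, salinity=60), "salinity")],
    )
    def test_out_of_range_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            cb.equilibrium_constants(**kwargs)


class TestSpeciation:
    def test_zero_carbon(self, constants18):
        st_ = cb.speciate(8.0, 0.0, constants18)
        assert st_.co2 == st_.hco3 == st_.co3 == st_.pco2 == 0.0

    def test_negative_dic_rejected(self, constants18):
        with pytest.raises(ValueError, match="dic"):
            cb.speciate(8.0, -1.0, constants18)

    @given(ph=st.floats(6.0, 10.0))
    def test_fractions_sum_to_one(self, ph):
        c = cb.equilibrium_constants(18, 35)
        st_ = cb.speciate(ph, 2000.0, c)
        assert (st_.co2 + st_.hco3 + st_.co3) == pytest.approx(2000.0, rel=1e-12)

    def test_pco2_is_co2_over_k0(self, constants18):
        st_ = cb.speciate(8.14, 1976, constants18)
        assert st_.pco2 == pytest.approx(st_.co2 / constants18.k0, rel=1e-12)

    def test_monotonicity_in_ph(self, constants18):
        phs = np.linspace(7.0, 8.6, 30)
        states = [cb.speciate(p, 2000.0, constants18) for p in phs]
        pco2 = np.array([s.pco2 for s in states])
        co3 = np.array([s.co3 for s in states])
        assert np.all(np.diff(pco2) < 0)
        assert np.all(np.diff(co3) > 0)


class TestAlkalinity:
    def test_reference_row_terms(self, constants18):
        # carbonate alkalinity of the low-light ambient sample leaves
        # ~120 µmol/kg for borate/OH-/nutrient terms
        st_ = cb.speciate(8.14, 1976, constants18, phosphate=21, silicate=52.5)
        ta = cb.total_alkalinity(st_, constants18)
        carb_alk = st_.hco3 + 2 * st_.co3
        assert ta > carb_alk
        assert 60 < ta - carb_alk < 180

    def test_nutrient_free_reduces_to_carb_borate(self, constants18):
        st_ = cb.speciate(8.1, 2000, constants18)
        ta = cb.total_alkalinity(st_, constants18)
        c = constants18
        h = 10**-8.1
        balk = c.bt * 1e6 * c.kb / (c.kb + h)
        # remaining terms (OH-, free H+) are a few µmol/kg at this pH
        assert ta == pytest.approx(st_.hco3 + 2 * st_.co3 + balk, abs=8.0)

    def test_unspeciated_state_rejected(self, constants18):
        st_ = cb.speciate(8.1, 2000, constants18)
        st_.hco3 = None
        with pytest.raises(ValueError, match="speciated|ConstantSet"):
            cb.total_alkalinity(st_, constants18)


class TestPhInversion:
    @pytest.mark.parametrize("ph", [7.0, 7.5, 8.14, 8.6])
    @pytest.mark.parametrize("dic", [1500, 1976, 2500])
    def test_round_trip(self, constants18, ph, dic):
        st_ = cb.speciate(ph, dic, constants18, phosphate=21, silicate=52.5)
        ta = cb.total_alkalinity(st_, constants18)
        back = cb.ph_from_ta_dic(ta, dic, constants18, phosphate=21, silicate=52.5)
        assert back == pytest.approx(ph, abs=1e-3)

    def test_ta_monotone_in_ph(self, constants18):
        ph1 = cb.ph_from_ta_dic(2200, 2000, constants18)
        ph2 = cb.ph_from_ta_dic(2300, 2000, constants18)
        assert ph2 > ph1

    def test_infeasible_pair_reports_bracket(self, constants18):
        with pytest.raises(RuntimeError, match="bracket"):
            cb.ph_from_ta_dic(50.0, 2000.0, constants18)


class TestTreatmentSummary:
    def test_identical_groups_zero_change(self, study_df):
        import pandas as pd

        df = cb.process_dataframe(study_df)
        df["group"] = df["target_pco2"]
        # mirror every sample into the other group: means become identical
        sym = pd.concat([df, df.assign(group=df.group.map({390: 750, 750: 390}))])
        out = cb.treatment_summary(sym)
        assert np.allclose(out["change"].to_numpy(), 0.0, atol=1e-10)

    def test_empty_group_rejected(self, study_df):
        df = cb.process_dataframe(study_df)
        df["group"] = 390
        with pytest.raises(ValueError, match="750"):
            cb.treatment_summary(df)

    def test_reported_contrasts_from_reference_columns(self, study_df):
        # unweighted column means of the reference table
        ref = study_df.rename(columns=lambda c: c.replace("ref_", ""))
        ref["group"] = ref["target_pco2"]
        out = cb.treatment_summary(ref)
        assert out.loc["hco3_umol_kg", "change"] == pytest.approx(13.5, abs=0.5)
        assert out.loc["co2_umol_kg", "change"] == pytest.approx(116.3, abs=0.5)


def test_process_dataframe_appends_outputs(study_df):
    out = cb.process_dataframe(study_df)
    for col in ["ta_umol_kg", "pco2_ppm", "co2_umol_kg", "hco3_umol_kg", "co3_umol_kg"]:
        assert col in out.columns and out[col].notna().all()
    # species conservation row-wise
    total = out.co2_umol_kg + out.hco3_umol_kg + out.co3_umol_kg
    assert np.allclose(total, out.dic_umol_kg, rtol=1e-9)
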