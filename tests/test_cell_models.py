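"""Membrane-model tests: remodeling factors, oracle agreement, fixed points."""

import numpy as np
import pytest

from atriafib import cell_models as cm
from conftest import random_myocyte_states
import reference_currents as ref


class TestAfRemodeling:
    @pytest.mark.parametrize("region,current,factor", [
        ("left_atrium", "I_to", 0.25),
        ("left_atrium", "I_Kur", 0.55),
        ("left_atrium", "I_Ks", 2.0),
        ("left_atrium", "I_CaL", 0.35),
        ("right_atrium", "I_to", 0.55),
        ("right_atrium", "I_Kur", 0.40),
        ("right_atrium", "I_Ks", 2.5),
        ("right_atrium", "I_K1", 2.0),
    ])
    def test_scaling_factors(self, region, current, factor):
        out = cm.apply_af_remodeling(cm.BASELINE_CONDUCTANCES, region)
        assert out[current] == pytest.approx(
            cm.BASELINE_CONDUCTANCES[current] * factor)

    def test_untouched_currents_pass_through(self):
        out = cm.apply_af_remodeling(cm.BASELINE_CONDUCTANCES, "left_atrium")
        for name in ("I_Na", "I_Kr", "I_bCa", "I_bNa"):
            assert out[name] == cm.BASELINE_CONDUCTANCES[name]

    def test_region_none_is_identity(self):
        out = cm.apply_af_remodeling(cm.BASELINE_CONDUCTANCES, "none")
        assert out == cm.BASELINE_CONDUCTANCES

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            cm.apply_af_remodeling(cm.BASELINE_CONDUCTANCES, "ventricle")
        with pytest.raises(ValueError):
            cm.RemodelingProfile.for_region("ventricle")


class TestMyocyteRhs:
    def test_total_current_matches_independent_transcription(self, rng,
                                                             la_profile):
        """100 randomized clamped states agree with the second transcription
        of every current equation to 1e-8 relative tolerance."""
        scales = {"to": la_profile.scale_Ito, "kur": la_profile.scale_IKur,
                  "ks": la_profile.scale_IKs, "k1": la_profile.scale_IK1,
                  "cal": la_profile.scale_ICaL}
        for y in random_myocyte_states(rng, 100):
            _, iion = cm.cardiomyocyte_rhs(y, la_profile)
            expected = ref.myocyte_total_current(
                y, scales, la_profile.ach_concentration)
            assert iion == pytest.approx(expected, rel=1e-8)

    def test_individual_currents_match_oracle(self, rng, ra_profile):
        y = random_myocyte_states(rng, 1)[0]
        cur = cm.cardiomyocyte_currents(y, ra_profile)
        v, na_i, k_i, ca_i = y[0], y[16], y[17], y[18]
        assert cur["I_Na"] == pytest.approx(
            ref.i_na(v, y[1], y[2], y[3], na_i), rel=1e-10)
        assert cur["I_K1"] == pytest.approx(
            ref.i_k1(v, k_i, scale=2.0), rel=1e-10)
        assert cur["I_NaCa"] == pytest.approx(
            ref.i_na_ca(v, na_i, ca_i), rel=1e-10)
        assert cur["I_KACh"] == pytest.approx(
            ref.i_k_ach(v, ra_profile.ach_concentration, k_i), rel=1e-10)

    def test_stimulus_linearity(self, la_profile):
        """A -28 pA/pF pulse raises dVm/dt by exactly +28 mV/ms."""
        y = cm.CRN_INITIAL_STATE.copy()
        dy0, _ = cm.cardiomyocyte_rhs(y, la_profile, ist=0.0)
        dy1, _ = cm.cardiomyocyte_rhs(y, la_profile, ist=-28.0)
        assert dy1[0] - dy0[0] == pytest.approx(28.0, abs=1e-12)
        assert np.allclose(dy1[1:], dy0[1:])

    def test_nonfinite_state_rejected(self, la_profile):
        y = cm.CRN_INITIAL_STATE.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            cm.cardiomyocyte_rhs(y, la_profile)

    def test_quiescent_baseline_is_fixed_point(self):
        """The settled unstimulated cell has |dVm/dt| < 1e-4 mV/ms."""
        base = cm.RemodelingProfile()
        y = cm.CRN_INITIAL_STATE.copy()
        cm._settle_myocyte(y, base.gscale, 0.0, 0.01, 100000, 1e-7, 100)
        dy, _ = cm.cardiomyocyte_rhs(y, base)
        assert abs(dy[0]) < 1e-4

    def test_zero_ach_removes_ikach(self, rng):
        prof_on = cm.RemodelingProfile.for_region("left_atrium", 0.01)
        prof_off = cm.RemodelingProfile.for_region("left_atrium", 0.0)
        y = random_myocyte_states(rng, 1)[0]
        on = cm.cardiomyocyte_currents(y, prof_on)
        off = cm.cardiomyocyte_currents(y, prof_off)
        assert off["I_KACh"] == 0.0
        assert on["I_KACh"] != 0.0
        _, iion_on = cm.cardiomyocyte_rhs(y, prof_on)
        _, iion_off = cm.cardiomyocyte_rhs(y, prof_off)
        assert iion_on - iion_off == pytest.approx(on["I_KACh"], rel=1e-12)


class TestFibroticRhs:
    def test_current_sum_matches_independent_transcription(self, rng):
        params = cm.CELL_PARAMS["fibroblast"]
        for _ in range(100):
            y = np.array([rng.uniform(-90, 20), rng.uniform(0, 1),
                          rng.uniform(0, 1)])
            dy, icfi = cm.fibrotic_rhs(y, params)
            expected = ref.fibroblast_total_current(y[0], y[1], y[2])
            assert icfi / params.capacitance == pytest.approx(expected,
                                                              rel=1e-8)
            assert dy[0] == pytest.approx(-expected, rel=1e-8)

    def test_cardiomyocyte_kind_rejected(self):
        with pytest.raises(ValueError):
            cm.fibrotic_rhs(cm.FIB_INITIAL_STATE,
                            cm.CELL_PARAMS["cardiomyocyte"])

    def test_fibroblast_and_fibrocyte_share_membrane(self):
        """Table-1 rows differ only in tissue conductivity, so the membrane
        dynamics (and absolute current: same 6.3 pF) are identical."""
        y = np.array([-20.0, 0.3, 0.8])
        dy_fb, i_fb = cm.fibrotic_rhs(y, cm.CELL_PARAMS["fibroblast"])
        dy_fc, i_fc = cm.fibrotic_rhs(y, cm.CELL_PARAMS["fibrocyte"])
        assert np.array_equal(dy_fb, dy_fc)
        assert i_fb == i_fc

    def test_myofibroblast_same_dynamics_scaled_current(self):
        y = np.array([-20.0, 0.3, 0.8])
        dy_fb, i_fb = cm.fibrotic_rhs(y, cm.CELL_PARAMS["fibroblast"])
        dy_mf, i_mf = cm.fibrotic_rhs(y, cm.CELL_PARAMS["myofibroblast"])
        assert np.array_equal(dy_fb, dy_mf)
        assert i_mf / i_fb == pytest.approx(50.4 / 6.3)


class TestRestingPotentials:
    def test_baseline_courtemanche_rests_near_published_value(self):
        res = cm.find_resting_potential("cardiomyocyte",
                                        cm.RemodelingProfile())
        assert res.converged
        assert res.vm == pytest.approx(-81.2, abs=1.0)

    def test_fibrotic_cells_rest_near_minus_49_6(self):
        res = cm.find_resting_potential("fibroblast")
        assert res.converged
        assert res.vm == pytest.approx(-49.6, abs=1.0)

    def test_all_fibrotic_kinds_share_resting_potential(self):
        vms = [cm.find_resting_potential(k).vm
               for k in ("fibroblast", "myofibroblast", "fibrocyte")]
        assert vms[0] == vms[1] == vms[2]

    def test_remodeled_myocyte_settles_and_initial_condition_is_published(self):
        """The published initial Vm is -81.18 mV; the AF-remodeled cell then
        drifts to its own (more negative) steady state under doubled I_K1.
        Both readings of the stated resting potential are exercised."""
        assert cm.CRN_INITIAL_STATE[0] == pytest.approx(-81.18)
        res = cm.find_resting_potential(
            "cardiomyocyte", cm.RemodelingProfile.for_region("left_atrium"))
        assert res.converged
        assert -90.0 < res.vm < cm.CRN_INITIAL_STATE[0]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            cm.find_resting_potential("neuron")


class TestPacing:
    def test_gates_stay_in_unit_interval_during_pacing(self, la_profile):
        y = cm.CRN_INITIAL_STATE.copy()
        for _ in range(60):
            cm._integrate_myocyte(y, la_profile.gscale,
                                  la_profile.ach_concentration, 0.01,
                                  1000, 400.0, 0.0, 2.0, 28.0, 1000)
            assert np.all(y[1:16] >= 0.0) and np.all(y[1:16] <= 1.0)
            assert np.all(y[16:] > 0.0)

    def test_pacing_reaches_periodic_orbit(self, la_profile):
        """Beat-to-beat APD90 difference < 1 ms after 10 beats at CL 1000."""
        from atriafib.biomarkers import apd90
        t, v, _ = cm.pace_single_cell(la_profile, n_beats=12,
                                      cycle_length=1000.0, record_every=10)
        apds = []
        for b in (10, 11):
            sel = (t >= b * 1000.0) & (t < b * 1000.0 + 900.0)
            apds.append(apd90((t[sel], v[sel])))
        assert abs(apds[1] - apds[0]) < 1.0


def test_parameter_serialization_mirrors_cell_table():
    doc = cm.serialize_parameters()
    assert doc["cells"]["fibrocyte"]["tissue_conductivity"] == 0.024
    assert doc["cells"]["myofibroblast"]["capacitance"] == 50.4
    assert set(doc["af_remodeling_factors"]) == {"left_atrium",
                                                 "right_atrium", "none"}
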