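"""Monodomain solver tests: fixed points, conservation, convergence, symmetry."""

import numpy as np
import pytest

from atriafib import cell_models as cm
from atriafib.biomarkers import activation_time, conduction_velocity
from atriafib.monodomain import (SolverConfig, StabilityViolation,
                                 check_stability, default_profiles,
                                 fem_coupling_weights, simulate, step)
from atriafib.protocols import StimulusProtocol
from atriafib.synthetic_tissue import (FibrosisConfig, TissueGrid,
                                       generate_fibrosis, make_sheet)


def settled_state(profile, tol=1e-7):
    y = cm.CRN_INITIAL_STATE.copy()
    cm._settle_myocyte(y, profile.gscale, profile.ach_concentration,
                       0.01, 3_000_000, tol, 100)
    return y


@pytest.fixture(scope="module")
def settled_baseline():
    return settled_state(cm.RemodelingProfile())


class TestFixedPointsAndConservation:
    def test_resting_tissue_stays_at_rest(self, settled_baseline):
        """Uniform resting tissue without stimulus: |dVm| < 1e-6 mV/step."""
        grid = make_sheet(12, 10)
        profiles = {"left_atrium": cm.RemodelingProfile(),
                    "right_atrium": cm.RemodelingProfile()}
        res = step(grid, SolverConfig(snapshot_interval=0,
                                      probes=[(5, 5)]),
                   profiles, n_steps=200, myo_init=settled_baseline)
        per_step = np.abs(np.diff(res.probe_vm[:, 0]))
        assert per_step.max() < 1e-6
        assert np.abs(res.v - settled_baseline[0]).max() < 1e-3

    def test_diffusion_conserves_deviation_integral(self):
        """No-flux diffusion of a +10 mV interior perturbation conserves the
        lumped-mass-weighted deviation integral to 1e-10 per step."""
        grid = make_sheet(15, 13)
        v0 = np.full((13, 15), -80.0)
        v0[6, 7] += 10.0
        cfg = SolverConfig(snapshot_interval=0)
        res = step(grid, cfg, n_steps=50, initial_v=v0, diffusion_only=True)
        mass = np.ones((13, 15))
        mass[0, :] = mass[-1, :] = 0.5
        mass[:, 0] *= 0.5
        mass[:, -1] *= 0.5
        total0 = (mass * (v0 + 80.0)).sum()
        total1 = (mass * (res.v + 80.0)).sum()
        assert total1 == pytest.approx(total0, abs=50 * 1e-10 * abs(total0))

    def test_interior_spread_conserves_plain_sum_initially(self):
        """Away from the boundary all node masses are equal, so the plain
        sum of the deviation is conserved too (consistent-mass leakage to
        the boundary decays exponentially with distance)."""
        grid = make_sheet(41, 41)
        v0 = np.full((41, 41), -80.0)
        v0[20, 20] += 10.0
        res = step(grid, SolverConfig(snapshot_interval=0), n_steps=1,
                   initial_v=v0, diffusion_only=True)
        assert (res.v + 80.0).sum() == pytest.approx(10.0, abs=1e-10)


class TestStability:
    def test_stated_parameters_are_stable(self):
        rep = check_stability(make_sheet(20, 20), SolverConfig())
        assert rep["ok"]

    def test_hundredfold_dt_names_binding_node(self):
        grid = make_sheet(20, 20)
        grid = generate_fibrosis(grid, FibrosisConfig(
            kinds=("fibrocyte",), density=0.1, seed=0))
        rep = check_stability(grid, SolverConfig(dt=1.0,
                                                 coupling_mode="replace"))
        assert not rep["ok"]
        j, i = rep["binding_node"]
        assert 0 <= j < 20 and 0 <= i < 20
        assert rep["binding_kind"] == "fibrocyte"
        with pytest.raises(StabilityViolation):
            simulate(grid, None, 1.0, SolverConfig(dt=1.0,
                                                   coupling_mode="replace"))

    def test_zero_conductivity_rejected_at_validation(self):
        grid = make_sheet(10, 10)
        grid.element_conductivity[3, 3] = 0.0
        with pytest.raises(ValueError):
            check_stability(grid, SolverConfig())


@pytest.fixture(scope="module")
def strip_run(profiles, prepaced):
    grid = make_sheet(70, 7, region_layout="left_atrium")
    probes = [(3, c) for c in range(15, 60, 5)]
    cfg = SolverConfig(snapshot_interval=0, probes=probes)
    prot = StimulusProtocol(s1_site=("edge", "left"), s1_times=(0.0,))
    res = simulate(grid, prot, 120.0, cfg, profiles, myo_init=prepaced)
    return grid, probes, res


class TestPlaneWave:
    def test_isochrones_are_linear_in_x(self, strip_run):
        """Plane-wave activation times grow linearly with distance."""
        grid, probes, res = strip_run
        acts = [activation_time(res.probe_trace(p))
                for p in range(len(probes))]
        x = np.array([c for _, c in probes], dtype=float) * grid.spacing
        acts = np.array(acts, dtype=float)
        slope, intercept = np.polyfit(x, acts, 1)
        pred = slope * x + intercept
        ss_res = ((acts - pred) ** 2).sum()
        ss_tot = ((acts - acts.mean()) ** 2).sum()
        assert 1.0 - ss_res / ss_tot > 0.999

    def test_baseline_cv_near_62(self, strip_run):
        grid, probes, res = strip_run
        cv = conduction_velocity(res.probe_trace(3), res.probe_trace(5),
                                 10 * grid.spacing)
        assert cv == pytest.approx(62.0, rel=0.05)

    def test_no_protocol_everything_stays_near_rest(self, profiles,
                                                    settled_baseline):
        grid = make_sheet(30, 6)
        base_profiles = {"left_atrium": cm.RemodelingProfile(),
                         "right_atrium": cm.RemodelingProfile()}
        res = simulate(grid, None, 100.0,
                       SolverConfig(snapshot_interval=0),
                       base_profiles, myo_init=settled_baseline)
        assert np.abs(res.v - settled_baseline[0]).max() < 0.1


class TestSymmetryAndMonotonicity:
    def test_mirrored_grid_mirrors_activation_map(self, profiles, prepaced):
        grid = make_sheet(30, 12)
        grid = generate_fibrosis(grid, FibrosisConfig(
            kinds=("fibroblast",), density=0.15, seed=9))
        mirrored = grid.copy()
        mirrored.node_kind = grid.node_kind[::-1].copy()
        mirrored.element_conductivity = grid.element_conductivity[::-1].copy()
        prot = StimulusProtocol(s1_site=("edge", "left"), s1_times=(0.0,))
        cfg = SolverConfig(snapshot_interval=1.0)
        a = simulate(grid, prot, 60.0, cfg, profiles, myo_init=prepaced)
        b = simulate(mirrored, prot, 60.0, cfg, profiles, myo_init=prepaced)

        def act_map(res):
            above = res.snapshots > -20.0
            never = ~above.any(axis=0)
            first = above.argmax(axis=0).astype(float)
            first[never] = np.nan
            return first

        ma, mb = act_map(a), act_map(b)
        assert np.array_equal(ma, mb[::-1], equal_nan=True)

    def test_cv_increases_with_conductivity(self, profiles, prepaced):
        cvs = []
        for factor in (0.6, 1.0, 1.6):
            grid = make_sheet(60, 5)
            grid.element_conductivity *= factor
            cfg = SolverConfig(snapshot_interval=0,
                               probes=[(2, 25), (2, 35)])
            prot = StimulusProtocol(s1_site=("edge", "left"),
                                    s1_times=(0.0,))
            res = simulate(grid, prot, 130.0, cfg, profiles,
                           myo_init=prepaced)
            cvs.append(conduction_velocity(res.probe_trace(0),
                                           res.probe_trace(1),
                                           10 * grid.spacing))
        assert cvs[0] < cvs[1] < cvs[2]


class TestHeterogeneityContract:
    def test_replace_mode_runs_fibrotic_membrane_at_node(self, profiles):
        """In replace mode a fibrotic node follows the MacCannell update."""
        grid = make_sheet(5, 5)
        grid.node_kind[:, :] = cm.KIND_CODE["fibroblast"]
        # every node fibrotic and uniform V: reaction stays uniform and the
        # diffusion stage is exactly zero
        v0 = np.full((5, 5), cm.FIB_INITIAL_STATE[0])
        # the low-capacitance membrane tightens the stability bound in
        # replace mode, hence the smaller step
        cfg = SolverConfig(dt=0.004, snapshot_interval=0,
                           coupling_mode="replace")
        res = step(grid, cfg, profiles, n_steps=1, initial_v=v0)
        y = cm.FIB_INITIAL_STATE.copy()
        cm._fib_step(y, 0.0, cfg.dt)
        assert res.v[2, 2] == pytest.approx(y[0], abs=1e-9)
        assert res.fib_state[2 * 5 + 2, 1] == pytest.approx(y[1], rel=1e-9)

    def test_paired_mode_adds_gap_current_to_myocyte(self, profiles):
        """In paired mode the fibrotic node's myocyte feels exactly the gap
        current G_gap (Vm - Vf) / Cm on top of its own membrane current."""
        grid = make_sheet(5, 5)
        grid.node_kind[2, 2] = cm.KIND_CODE["fibroblast"]
        v0 = np.full((5, 5), cm.CRN_INITIAL_STATE[0])
        cfg = SolverConfig(snapshot_interval=0)
        res = step(grid, cfg, profiles, n_steps=1, initial_v=v0)
        # same step without fibrosis
        grid0 = make_sheet(5, 5)
        res0 = step(grid0, cfg, profiles, n_steps=1, initial_v=v0)
        vm, vf = cm.CRN_INITIAL_STATE[0], cm.FIB_INITIAL_STATE[0]
        igap = cfg.gap_junction_ns * (vm - vf) / cm.CM_MYO
        dv_expected = res0.v[2, 2] - cfg.dt * igap
        # the diffusion stage then relaxes a dt*igap-sized deviation by
        # at most dt * (coupling rate) of itself
        assert res.v[2, 2] == pytest.approx(dv_expected, abs=2e-3)
        assert abs(res.v[2, 2] - res0.v[2, 2]) > 5e-3


class TestConvergence:
    def test_cv_self_convergence_under_refinement(self, profiles, prepaced):
        """Halving dx and dt changes the measured CV by < 3%."""
        # the stimulated strip keeps its physical width on the fine grid
        coarse = make_sheet(70, 3)
        prot_c = StimulusProtocol(s1_site=("rect", (0, 3, 0, 3)),
                                  s1_times=(0.0,))
        cfg_c = SolverConfig(snapshot_interval=0, probes=[(1, 30), (1, 40)])
        res_c = simulate(coarse, prot_c, 100.0, cfg_c, profiles,
                         myo_init=prepaced)
        cv_c = conduction_velocity(res_c.probe_trace(0), res_c.probe_trace(1),
                                   10 * coarse.spacing)

        fine = make_sheet(139, 3, spacing=coarse.spacing / 2)
        prot_f = StimulusProtocol(s1_site=("rect", (0, 3, 0, 6)),
                                  s1_times=(0.0,))
        cfg_f = SolverConfig(dt=0.005, snapshot_interval=0,
                             probes=[(1, 60), (1, 80)])
        res_f = simulate(fine, prot_f, 100.0, cfg_f, profiles,
                         myo_init=prepaced)
        cv_f = conduction_velocity(res_f.probe_trace(0), res_f.probe_trace(1),
                                   20 * fine.spacing)
        assert abs(cv_f - cv_c) / cv_c < 0.03

    def test_tissue_kernel_tracks_exact_integrator(self, profiles):
        """A uniformly stimulated sheet (diffusion inert) reproduces the
        exact-rate single-cell trajectory to < 0.01 mV, validating the
        voltage lookup tables."""
        grid = make_sheet(3, 3)
        prot = StimulusProtocol(s1_site=("rect", (0, 3, 0, 3)),
                                s1_times=(0.0,))
        cfg = SolverConfig(snapshot_interval=0, probes=[(1, 1)])
        res = simulate(grid, prot, 350.0, cfg, profiles,
                       myo_init=cm.CRN_INITIAL_STATE)
        t, v, _ = cm.pace_single_cell(profiles["left_atrium"], n_beats=1,
                                      cycle_length=350.0, record_every=1)
        assert np.abs(res.probe_vm[:, 0] - v).max() < 0.01

    def test_repolarized_profile_matches_fine_grid(self, profiles, prepaced):
        """After full activation the coarse and refined cable agree to
        < 0.5 mV pointwise."""
        coarse = make_sheet(40, 3)
        prot_c = StimulusProtocol(s1_site=("rect", (0, 3, 0, 3)),
                                  s1_times=(0.0,))
        cfg_c = SolverConfig(snapshot_interval=10.0)
        res_c = simulate(coarse, prot_c, 60.0, cfg_c, profiles,
                         myo_init=prepaced)
        fine = make_sheet(79, 3, spacing=coarse.spacing / 2)
        prot_f = StimulusProtocol(s1_site=("rect", (0, 3, 0, 6)),
                                  s1_times=(0.0,))
        cfg_f = SolverConfig(dt=0.001, snapshot_interval=10.0)
        res_f = simulate(fine, prot_f, 60.0, cfg_f, profiles,
                         myo_init=prepaced)
        v_c = res_c.snapshots[-1][1, :]
        v_f = res_f.snapshots[-1][1, ::2]
        assert np.abs(v_c - v_f).max() < 0.5
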