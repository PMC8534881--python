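"""Monodomain reaction-diffusion solver on a 2D tissue sheet.

The transmembrane potential obeys  chi * (Cm dV/dt + Iion) = div(D grad V)
with element-wise conductivity D, no-flux boundaries, and a membrane model
per node kind (AF-remodeled CRN cardiomyocyte or MacCannell fibrotic cell).
Operator splitting per time step: a reaction update of every node with its
own membrane model (Rush-Larsen gates, forward Euler otherwise), then an
explicit finite-difference diffusion update.

Units: Vm in mV, time in ms, conductivity in S/cm, lengths in cm.  The
surface-to-volume ratio ``chi`` closes the unit system; it is calibrated once
so the homogeneous no-fibrosis sheet conducts a plane wave at 62 cm/s with
the 0.26 S/cm myocardial conductivity, and is recorded in every run manifest.
The nominal membrane capacitances (100 pF cardiomyocyte, Table-1 values for
fibrotic cells) enter the diffusion term as the ratio 100 pF / C_node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import cell_models as cmod
from .cell_models import (CELL_PARAMS, CRN_INITIAL_STATE, FIB_INITIAL_STATE,
                          KIND_NAME, LUT_DV, LUT_VMIN, RemodelingProfile,
                          build_voltage_tables)
from .synthetic_tissue import REGION_CODE, TissueGrid

#: calibrated surface-to-volume ratio (1/cm, with 1 uF/cm^2 specific
#: capacitance): fixed once so that the no-fibrosis sheet with 0.26 S/cm,
#: dx = 300 um and dt = 0.01 ms conducts a plane wave at 62 cm/s.
DEFAULT_CHI = 1.762e5

#: capacitance ratio 100 pF / C_kind, indexed by kind code
CAP_FACTOR = np.array([1.0,
                       100.0 / CELL_PARAMS["fibroblast"].capacitance,
                       100.0 / CELL_PARAMS["myofibroblast"].capacitance,
                       100.0 / CELL_PARAMS["fibrocyte"].capacitance])


@dataclass
class SolverConfig:
    """Numerical parameters of the monodomain integration."""

    dt: float = 0.01                      # ms
    surface_to_volume: float = DEFAULT_CHI   # 1/cm
    specific_capacitance: float = 1.0     # uF/cm^2
    snapshot_interval: float = 1.0        # ms; <= 0 disables snapshots
    probes: list = field(default_factory=list)   # [(row, col), ...]
    check_every: int = 200                # steps between finiteness checks
    #: "paired": each fibrotic node is a cardiomyocyte gap-junction-coupled
    #: to a fibrotic cell (heterocellular coupling); "replace": the fibrotic
    #: membrane substitutes the cardiomyocyte's at the node
    coupling_mode: str = "paired"
    gap_junction_ns: float = 3.0          # nS, myocyte-fibrotic cell coupling

    def diffusivity_scale(self) -> float:
        """Converts S/cm to the effective diffusivity in cm^2/ms."""
        return 1e3 / (self.surface_to_volume * self.specific_capacitance)


def default_profiles(ach: float = cmod.DEFAULT_ACH) -> dict:
    return {"left_atrium": RemodelingProfile.for_region("left_atrium", ach),
            "right_atrium": RemodelingProfile.for_region("right_atrium", ach)}


@dataclass
class SimulationState:
    """Full solver state plus recorded probe traces and snapshots."""

    t: float
    v: np.ndarray                  # (ny, nx) membrane potential, mV
    myo_state: np.ndarray          # (n_nodes, 20) gates + concentrations
    fib_state: np.ndarray          # (n_nodes, 3) fibrotic Vf and K+ gates
    probe_times: np.ndarray
    probe_vm: np.ndarray           # (n_rec, n_probes)
    snapshot_times: np.ndarray
    snapshots: np.ndarray          # (n_frames, ny, nx) float32
    status: str                    # "ok" | "non_finite" | "no_propagation"
    fail_node: tuple | None = None
    manifest: dict = field(default_factory=dict)

    def probe_trace(self, p: int):
        return self.probe_times, self.probe_vm[:, p]


class StabilityViolation(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Assembly helpers
# ---------------------------------------------------------------------------

def fem_coupling_weights(grid: TissueGrid, config: SolverConfig,
                         sigma=None):
    """Assembled bilinear-FEM diffusion couplings on the quadrilateral mesh.

    Element-wise conductivities enter through the standard bilinear
    quadrilateral stiffness matrix (edge neighbors at sigma/6 per adjacent
    element, diagonal neighbors at sigma/3), with a lumped mass matrix; this
    matches the finite-element discretization of the reference experiments
    and, unlike a 5-point stencil, conducts across element diagonals.
    Returns (wx, wy, wa, wb, inv_mass): couplings in 1/ms (already scaled by
    1/dx^2) for horizontal, vertical, down-right and down-left neighbor
    pairs, plus the per-node lumped-mass factor.
    """
    sig = grid.element_conductivity if sigma is None else sigma
    ny, nx = grid.ny, grid.nx
    scale = config.diffusivity_scale() / grid.spacing ** 2
    wx = np.zeros((ny, nx - 1))
    wx[:-1, :] += sig / 6.0
    wx[1:, :] += sig / 6.0
    wy = np.zeros((ny - 1, nx))
    wy[:, :-1] += sig / 6.0
    wy[:, 1:] += sig / 6.0
    wa = sig / 3.0          # (j, i) <-> (j+1, i+1)
    wb = sig / 3.0          # (j, i+1) <-> (j+1, i)
    # lumped mass: fraction of adjacent elements (interior 4, edge 2, corner 1)
    n_adj = np.zeros((ny, nx))
    n_adj[:-1, :-1] += 1.0
    n_adj[:-1, 1:] += 1.0
    n_adj[1:, :-1] += 1.0
    n_adj[1:, 1:] += 1.0
    inv_mass = 4.0 / n_adj
    return wx * scale, wy * scale, wa * scale, wb * scale, inv_mass


def node_membrane_arrays(grid: TissueGrid, profiles: dict):
    """Per-node conductance scalings and I_KACh amplitude factors."""
    n = grid.n_nodes
    gscale = np.ones((n, 5))
    achfac = np.zeros(n)
    region = grid.node_region.ravel()
    for rname, rcode in REGION_CODE.items():
        if rname == "excluded":
            prof = profiles.get("excluded",
                               profiles.get("right_atrium",
                                            RemodelingProfile()))
        else:
            prof = profiles.get(rname, RemodelingProfile())
        sel = region == rcode
        gscale[sel] = prof.gscale
        ach = prof.ach_concentration
        achfac[sel] = (10.0 / (1.0 + 9.13652 / ach ** 0.477811)) if ach > 0 else 0.0
    return gscale, achfac


def initial_node_states(grid: TissueGrid, myo_init=None, fib_init=None,
                        coupling_mode: str = "paired"):
    """Per-node initial V / gate / concentration arrays.

    ``myo_init`` may be a single 21-vector or a dict region-name -> 21-vector
    (e.g. regionally pre-paced states); fibrotic compartments start from
    ``fib_init`` (default: the fibroblast resting state).  In paired mode the
    continuum V at fibrotic nodes is the myocyte's; in replace mode it is the
    fibrotic cell's.
    """
    n = grid.n_nodes
    v = np.empty(n)
    myo = np.empty((n, 20))
    fib = np.tile(FIB_INITIAL_STATE, (n, 1))    # columns: Vf, r, s
    kind = grid.node_kind.ravel()
    region = grid.node_region.ravel()

    if myo_init is None:
        myo_init = CRN_INITIAL_STATE
    if isinstance(myo_init, dict):
        v[:] = 0.0
        for rname, vec in myo_init.items():
            sel = region == REGION_CODE[rname]
            v[sel] = vec[0]
            myo[sel] = vec[1:]
        # excluded nodes fall back to the published resting state
        done = np.zeros(n, dtype=bool)
        for rname in myo_init:
            done |= region == REGION_CODE[rname]
        if not done.all():
            v[~done] = CRN_INITIAL_STATE[0]
            myo[~done] = CRN_INITIAL_STATE[1:]
    else:
        vec = np.asarray(myo_init, dtype=float)
        v[:] = vec[0]
        myo[:] = vec[1:]

    if fib_init is None:
        fib_init = FIB_INITIAL_STATE
    fib_mask = kind != 0
    fib[fib_mask] = fib_init
    if coupling_mode == "replace":
        v[fib_mask] = fib_init[0]
    return v.reshape(grid.ny, grid.nx), myo, fib


def _layers_of(tissue):
    """Normalize a TissueGrid or TissueSlab to a list of layers."""
    return list(tissue.layers) if hasattr(tissue, "layers") else [tissue]


def _node_centered_sigma(sig2d, ny, nx):
    """Average of the in-plane elements adjacent to each node."""
    s = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx))
    for dj, di in ((0, 0), (0, 1), (1, 0), (1, 1)):
        s[dj:ny - 1 + dj, di:nx - 1 + di] += sig2d
        cnt[dj:ny - 1 + dj, di:nx - 1 + di] += 1.0
    return s / cnt


def slab_layer_sigmas(tissue):
    """Per-layer in-plane element conductivities of a slab, from hexahedra.

    With the hexahedral rule assigned, a layer's quadrilateral conduction
    plane takes the mean of the element layers above and below it (boundary
    layers see a single element layer); vertical links between layers l and
    l+1 take the node-centered conductivity of element layer l.
    """
    layers = _layers_of(tissue)
    hexsig = getattr(tissue, "hex_conductivity", None)
    if hexsig is None:
        return ([g.element_conductivity for g in layers],
                None)
    nl = len(layers)
    plane = []
    for l in range(nl):
        if l == 0:
            plane.append(hexsig[0])
        elif l == nl - 1:
            plane.append(hexsig[-1])
        else:
            plane.append(0.5 * (hexsig[l - 1] + hexsig[l]))
    return plane, hexsig


def vertical_coupling_weights(tissue, config: SolverConfig):
    """(nl-1, ny, nx) couplings between stacked slab nodes, in 1/ms."""
    layers = _layers_of(tissue)
    ny, nx = layers[0].ny, layers[0].nx
    scale = config.diffusivity_scale() / layers[0].spacing ** 2
    plane, hexsig = slab_layer_sigmas(tissue)
    if hexsig is not None:
        return np.array([_node_centered_sigma(hexsig[l], ny, nx) * scale
                         for l in range(len(layers) - 1)])
    node_sigma = [_node_centered_sigma(p, ny, nx) for p in plane]
    return np.array([0.5 * (node_sigma[l] + node_sigma[l + 1]) * scale
                     for l in range(len(layers) - 1)])


def check_stability(tissue, config: SolverConfig):
    """Explicit-diffusion stability bound dt <= dx^2 C chi / (2 d Dmax).

    Evaluated per node with the actual assembled couplings and the node's
    capacitance ratio; returns a report dict with ``ok``, the binding node
    and the maximal admissible dt.  Accepts a sheet or a slab.
    """
    layers = _layers_of(tissue)
    for g in layers:
        g.validate()
    if config.dt <= 0:
        raise ValueError("dt must be positive")
    nl = len(layers)
    ny, nx = layers[0].ny, layers[0].nx
    rate = np.zeros((nl, ny, nx))
    plane_sig, _ = slab_layer_sigmas(tissue)
    for l, g in enumerate(layers):
        wx, wy, wa, wb, inv_mass = fem_coupling_weights(g, config,
                                                        plane_sig[l])
        r = np.zeros((ny, nx))
        r[:, :-1] += wx
        r[:, 1:] += wx
        r[:-1, :] += wy
        r[1:, :] += wy
        r[:-1, :-1] += wa
        r[1:, 1:] += wa
        r[:-1, 1:] += wb
        r[1:, :-1] += wb
        # consistent-mass inverse amplifies the stiffest mode up to 3x
        # relative to the lumped bound
        rate[l] = 3.0 * r * inv_mass
    if nl > 1:
        wv = vertical_coupling_weights(tissue, config)
        rate[:-1] += wv
        rate[1:] += wv
    kind_stack = np.stack([g.node_kind for g in layers])
    if config.coupling_mode == "replace":
        rate *= CAP_FACTOR[kind_stack]
    worst = np.unravel_index(np.argmax(rate), rate.shape)
    dt_max = 1.0 / rate[worst]
    node = (int(worst[1]), int(worst[2])) if nl == 1 else \
        (int(worst[0]), int(worst[1]), int(worst[2]))
    return {
        "ok": bool(config.dt <= dt_max),
        "dt": config.dt,
        "dt_max": float(dt_max),
        "binding_node": node,
        "binding_kind": KIND_NAME[int(kind_stack[worst])],
    }


# ---------------------------------------------------------------------------
# The time-stepping kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _lut(table, col, x0, inv_dv, v):
    x = (v - x0) * inv_dv
    if x < 0.0:
        x = 0.0
    hi = table.shape[1] - 1.001
    if x > hi:
        x = hi
    i = int(x)
    w = x - i
    return table[col, i] * (1.0 - w) + table[col, i + 1] * w


@njit(cache=False)
def _myocyte_lut_step(y, vm, gs, achn, i_extra, dt, table, inv_dv, x0,
                      et_fca, et_u):
    """One reaction step of a myocyte membrane; returns the updated Vm.

    ``i_extra`` collects stimulus and gap-junction current densities (pA/pF,
    outward positive) so dVm/dt = -(Iion + i_extra).
    """
    na_i = y[15]
    k_i = y[16]
    ca_i = y[17]
    ca_up = y[18]
    ca_rel = y[19]
    e_na = cmod.RTF * math.log(cmod.NA_O / na_i)
    e_k = cmod.RTF * math.log(cmod.K_O / k_i)
    e_ca = 0.5 * cmod.RTF * math.log(cmod.CA_O / ca_i)

    k1den = _lut(table, 24, x0, inv_dv, vm)
    gkurv = _lut(table, 25, x0, inv_dv, vm)
    krfac = _lut(table, 26, x0, inv_dv, vm)
    fnak = _lut(table, 27, x0, inv_dv, vm)
    e1 = _lut(table, 28, x0, inv_dv, vm)
    e2 = _lut(table, 29, x0, inv_dv, vm)
    kachg = _lut(table, 30, x0, inv_dv, vm)

    i_na = cmod.G_NA * y[0] ** 3 * y[1] * y[2] * (vm - e_na)
    i_k1 = gs[3] * cmod.G_K1 * (vm - e_k) * k1den
    i_to = gs[0] * cmod.G_TO * y[3] ** 3 * y[4] * (vm - e_k)
    i_kur = gs[1] * gkurv * y[5] ** 3 * y[6] * (vm - e_k)
    i_kr = cmod.G_KR * y[7] * (vm - e_k) * krfac
    i_ks = gs[2] * cmod.G_KS * y[8] * y[8] * (vm - e_k)
    i_cal = gs[4] * cmod.G_CAL * y[9] * y[10] * y[11] * (vm - 65.0)
    i_pca = cmod.I_PCA_MAX * ca_i / (0.0005 + ca_i)
    i_nak = (cmod.I_NAK_MAX * fnak
             * (1.0 / (1.0 + (cmod.KM_NA_I / na_i) ** 1.5))
             * (cmod.K_O / (cmod.K_O + cmod.KM_K_O)))
    i_naca = (cmod.I_NACA_MAX
              * (e1 * na_i ** 3 * cmod.CA_O - e2 * cmod.NA_O ** 3 * ca_i)
              / ((cmod.KM_NA ** 3 + cmod.NA_O ** 3)
                 * (cmod.KM_CA + cmod.CA_O) * (1.0 + cmod.K_SAT * e2)))
    i_bna = cmod.G_B_NA * (vm - e_na)
    i_bca = cmod.G_B_CA * (vm - e_ca)
    i_kach = achn * kachg * (vm - e_k)
    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca + i_kach)

    # voltage-dependent gates via tables
    for g in range(12):
        inf = _lut(table, g, x0, inv_dv, vm)
        et = _lut(table, 12 + g, x0, inv_dv, vm)
        idx = g if g < 11 else 14    # w sits at slot 14
        y[idx] = inf + (y[idx] - inf) * et

    fca_inf = 1.0 / (1.0 + ca_i / 0.00035)
    y[11] = fca_inf + (y[11] - fca_inf) * et_fca

    i_rel = cmod.K_REL * y[12] * y[12] * y[13] * y[14] * (ca_rel - ca_i)
    fn = 1e3 * (1e-15 * cmod.V_REL * i_rel
                - (1e-15 / (2.0 * cmod.FARADAY))
                * (0.5 * i_cal * cmod.CM_MYO - 0.2 * i_naca * cmod.CM_MYO))
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    y[12] = u_inf + (y[12] - u_inf) * et_u
    y[13] = v_inf + (y[13] - v_inf) * math.exp(-dt / tau_v)

    i_up = cmod.I_UP_MAX / (1.0 + cmod.K_UP / ca_i)
    i_up_leak = cmod.I_UP_MAX * ca_up / cmod.CA_UP_MAX
    i_tr = (ca_up - ca_rel) / cmod.TAU_TR

    y[15] += dt * (-3.0 * i_nak - (3.0 * i_naca + i_bna + i_na)) \
        * cmod.CM_MYO / (cmod.V_I * cmod.FARADAY)
    y[16] += dt * (2.0 * i_nak - (i_k1 + i_to + i_kur + i_kr + i_ks
                                  + i_kach)) * cmod.CM_MYO / (cmod.V_I * cmod.FARADAY)
    b1 = ((2.0 * i_naca - (i_pca + i_cal + i_bca))
          * cmod.CM_MYO / (2.0 * cmod.V_I * cmod.FARADAY)
          + (cmod.V_UP * (i_up_leak - i_up) + i_rel * cmod.V_REL) / cmod.V_I)
    b2 = (1.0 + cmod.TRPN_MAX * cmod.KM_TRPN / (ca_i + cmod.KM_TRPN) ** 2
          + cmod.CMDN_MAX * cmod.KM_CMDN / (ca_i + cmod.KM_CMDN) ** 2)
    y[17] += dt * b1 / b2
    y[18] += dt * (i_up - i_up_leak - i_tr * cmod.V_REL / cmod.V_UP)
    y[19] += dt * (i_tr - i_rel) \
        / (1.0 + cmod.CSQN_MAX * cmod.KM_CSQN / (ca_rel + cmod.KM_CSQN) ** 2)

    return vm + dt * (-(i_ion + i_extra))


@njit(cache=False)
def _fibroblast_membrane_step(fibrow, vf, i_extra, dt):
    """One reaction step of the MacCannell membrane; returns the updated Vf."""
    r = fibrow[1]
    s = fibrow[2]
    e_k = cmod.RTF * math.log(cmod.K_O / cmod.K_I_FIB)
    e_na = cmod.RTF * math.log(cmod.NA_O / cmod.NA_I_FIB)
    vk = vf - e_k
    i_kv = cmod.G_KV_FIB * r * s * vk
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (vk - 200.0)))
    b_k1 = ((3.0 * math.exp(0.0002 * (vk + 100.0)) + math.exp(0.1 * (vk - 10.0)))
            / (1.0 + math.exp(-0.5 * vk)))
    i_k1 = cmod.G_K1_FIB * (a_k1 / (a_k1 + b_k1)) * vk
    i_nak = (cmod.I_NAK_MAX_FIB * (cmod.K_O / (cmod.K_O + cmod.KM_K_FIB))
             * (cmod.NA_I_FIB ** 1.5
                / (cmod.NA_I_FIB ** 1.5 + cmod.KM_NA_FIB ** 1.5))
             * (vf - cmod.V_REV_NAK_FIB) / (vf - cmod.B_NAK_FIB))
    i_bna = cmod.G_B_NA_FIB * (vf - e_na)
    i_tot = i_kv + i_k1 + i_nak + i_bna
    r_inf = 1.0 / (1.0 + math.exp(-(vf + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * math.exp(-((vf + 20.0) / 25.9) ** 2)
    s_inf = 1.0 / (1.0 + math.exp((vf + 23.0) / 7.0))
    tau_s = 1574.0 + 5268.0 * math.exp(-((vf + 23.0) / 22.7) ** 2)
    fibrow[1] = r_inf + (r - r_inf) * math.exp(-dt / tau_r)
    fibrow[2] = s_inf + (s - s_inf) * math.exp(-dt / tau_s)
    return vf + dt * (-(i_tot + i_extra))


@njit(cache=False)
def _mass_solve_x(lap, work_c, work_d):
    """In-place solve of the normalized 1D FEM mass system along x rows.

    Interior rows are (1/6, 2/3, 1/6), boundary rows (1/3, 1/6): the
    consistent bilinear mass matrix factorizes over the tensor grid, so the
    2D solve is one Thomas pass along x and one along y.
    """
    n = lap.shape[1]
    for j in range(lap.shape[0]):
        # forward sweep
        b0 = 1.0 / 3.0
        work_c[0] = (1.0 / 6.0) / b0
        work_d[0] = lap[j, 0] / b0
        for i in range(1, n):
            diag = 2.0 / 3.0 if i < n - 1 else 1.0 / 3.0
            m = diag - (1.0 / 6.0) * work_c[i - 1]
            work_c[i] = (1.0 / 6.0) / m
            work_d[i] = (lap[j, i] - (1.0 / 6.0) * work_d[i - 1]) / m
        lap[j, n - 1] = work_d[n - 1]
        for i in range(n - 2, -1, -1):
            lap[j, i] = work_d[i] - work_c[i] * lap[j, i + 1]


@njit(cache=False)
def _mass_solve_y(lap, work_c, work_d):
    """Same as _mass_solve_x, along the y columns."""
    n = lap.shape[0]
    for i in range(lap.shape[1]):
        b0 = 1.0 / 3.0
        work_c[0] = (1.0 / 6.0) / b0
        work_d[0] = lap[0, i] / b0
        for j in range(1, n):
            diag = 2.0 / 3.0 if j < n - 1 else 1.0 / 3.0
            m = diag - (1.0 / 6.0) * work_c[j - 1]
            work_c[j] = (1.0 / 6.0) / m
            work_d[j] = (lap[j, i] - (1.0 / 6.0) * work_d[j - 1]) / m
        lap[n - 1, i] = work_d[n - 1]
        for j in range(n - 2, -1, -1):
            lap[j, i] = work_d[j] - work_c[j] * lap[j + 1, i]


@njit(cache=False)
def _run_kernel(v, myo, fib, kind, gscale, achfac, capfac, gap_cm, gap_cf,
                wx, wy, wa, wb, wv, inv_mass, table, dt, n_steps,
                ev_on, ev_off, ev_amp, ev_site, site_idx, site_ptr,
                probe_l, probe_j, probe_i, probe_out,
                snap_every, snaps, check_every, diffusion_only, paired):
    nl, ny, nx = v.shape
    n = nl * ny * nx
    inv_dv = 1.0 / LUT_DV
    x0 = LUT_VMIN
    et_fca = math.exp(-dt / cmod.TAU_F_CA)
    et_u = math.exp(-dt / cmod.TAU_U)
    ist = np.zeros(n)
    lap = np.empty((nl, ny, nx))
    nwork = ny if ny > nx else nx
    work_c = np.empty(nwork)
    work_d = np.empty(nwork)
    n_ev = ev_on.shape[0]
    snap_count = 0

    for step in range(n_steps):
        t = step * dt
        # stimulus bookkeeping (few events, small site sets)
        for e in range(n_ev):
            if ev_on[e] <= t < ev_off[e]:
                s = ev_site[e]
                for kk in range(site_ptr[s], site_ptr[s + 1]):
                    ist[site_idx[kk]] = ev_amp[e]

        if not diffusion_only:
            for l in range(nl):
                for j in range(ny):
                    for i in range(nx):
                        node = (l * ny + j) * nx + i
                        vm = v[l, j, i]
                        stim = -ist[node]     # depolarizing pulse
                        if kind[node] == 0:
                            v[l, j, i] = _myocyte_lut_step(
                                myo[node], vm, gscale[node], achfac[node],
                                stim, dt, table, inv_dv, x0, et_fca, et_u)
                        elif paired:
                            # heterocellular pair: myocyte in the continuum
                            # plus a gap-junction-coupled fibrotic compartment
                            vf = fib[node, 0]
                            igap = gap_cm * (vm - vf)
                            v[l, j, i] = _myocyte_lut_step(
                                myo[node], vm, gscale[node], achfac[node],
                                stim + igap, dt, table, inv_dv, x0,
                                et_fca, et_u)
                            fib[node, 0] = _fibroblast_membrane_step(
                                fib[node], vf, -gap_cf[node] * (vm - vf), dt)
                        else:
                            # fibrotic membrane replaces the myocyte here
                            v[l, j, i] = _fibroblast_membrane_step(
                                fib[node], vm, stim, dt)

        # diffusion: in-plane 9-point FEM stencil per layer plus vertical
        # coupling between stacked nodes; natural no-flux boundaries
        for l in range(nl):
            for j in range(ny):
                for i in range(nx):
                    acc = 0.0
                    if i > 0:
                        acc += wx[l, j, i - 1] * (v[l, j, i - 1] - v[l, j, i])
                    if i < nx - 1:
                        acc += wx[l, j, i] * (v[l, j, i + 1] - v[l, j, i])
                    if j > 0:
                        acc += wy[l, j - 1, i] * (v[l, j - 1, i] - v[l, j, i])
                    if j < ny - 1:
                        acc += wy[l, j, i] * (v[l, j + 1, i] - v[l, j, i])
                    if j > 0 and i > 0:
                        acc += wa[l, j - 1, i - 1] * (v[l, j - 1, i - 1] - v[l, j, i])
                    if j < ny - 1 and i < nx - 1:
                        acc += wa[l, j, i] * (v[l, j + 1, i + 1] - v[l, j, i])
                    if j > 0 and i < nx - 1:
                        acc += wb[l, j - 1, i] * (v[l, j - 1, i + 1] - v[l, j, i])
                    if j < ny - 1 and i > 0:
                        acc += wb[l, j, i - 1] * (v[l, j + 1, i - 1] - v[l, j, i])
                    lap[l, j, i] = acc
        # consistent-mass solve of the in-plane stiffness contribution
        for l in range(nl):
            _mass_solve_x(lap[l], work_c, work_d)
            _mass_solve_y(lap[l], work_c, work_d)
        # vertical coupling between layers (lumped in z)
        for l in range(nl):
            for j in range(ny):
                for i in range(nx):
                    if l > 0:
                        lap[l, j, i] += wv[l - 1, j, i] * (v[l - 1, j, i] - v[l, j, i])
                    if l < nl - 1:
                        lap[l, j, i] += wv[l, j, i] * (v[l + 1, j, i] - v[l, j, i])
        for l in range(nl):
            for j in range(ny):
                for i in range(nx):
                    node = (l * ny + j) * nx + i
                    v[l, j, i] += dt * capfac[node] * lap[l, j, i]
                    if diffusion_only and ist[node] != 0.0:
                        v[l, j, i] += dt * ist[node]

        # reset stimulus entries
        for e in range(n_ev):
            if ev_on[e] <= t < ev_off[e]:
                s = ev_site[e]
                for kk in range(site_ptr[s], site_ptr[s + 1]):
                    ist[site_idx[kk]] = 0.0

        # recordings
        for p in range(probe_j.shape[0]):
            probe_out[step + 1, p] = v[probe_l[p], probe_j[p], probe_i[p]]
        if snap_every > 0 and (step + 1) % snap_every == 0:
            for l in range(nl):
                for j in range(ny):
                    for i in range(nx):
                        snaps[snap_count, l, j, i] = v[l, j, i]
            snap_count += 1

        if (step + 1) % check_every == 0:
            for l in range(nl):
                for j in range(ny):
                    for i in range(nx):
                        if not math.isfinite(v[l, j, i]):
                            return 1, j, i, (step + 1) * dt
    return 0, -1, -1, n_steps * dt


# ---------------------------------------------------------------------------
# Public driver
# ---------------------------------------------------------------------------

def _pack_protocol(protocol, grid, nl, n2):
    """Flatten a StimulusProtocol into kernel event/site arrays.

    Site node sets resolve on the 2D sheet and are replicated through the
    slab thickness (a stimulus excites the full wall).
    """
    if protocol is None:
        z = np.zeros(0)
        return z, z, z, np.zeros(0, np.int64), np.zeros(0, np.int64), \
            np.zeros(1, np.int64)
    events = protocol.events()
    sites = protocol.site_node_indices(grid)
    sites = [np.concatenate([l * n2 + s for l in range(nl)]) for s in sites]
    ev_on = np.array([e[0] for e in events])
    ev_off = np.array([e[1] for e in events])
    ev_amp = np.array([e[2] for e in events])
    ev_site = np.array([e[3] for e in events], dtype=np.int64)
    site_idx = np.concatenate(sites) if sites else np.zeros(0, np.int64)
    ptr = np.zeros(len(sites) + 1, dtype=np.int64)
    for i, s in enumerate(sites):
        ptr[i + 1] = ptr[i] + len(s)
    return ev_on, ev_off, ev_amp, ev_site, site_idx.astype(np.int64), ptr


def simulate(tissue, protocol, duration: float,
             config: SolverConfig | None = None, profiles: dict | None = None,
             myo_init=None, fib_init=None,
             diffusion_only: bool = False,
             initial_v: np.ndarray | None = None) -> SimulationState:
    """Advance the monodomain system to ``duration`` (ms).

    ``tissue`` is a TissueGrid sheet or a TissueSlab.  Stimuli are injected
    per ``protocol`` (None for an unstimulated run); probe Vm is recorded
    every time step and full-field snapshots every
    ``config.snapshot_interval``.  Deterministic given tissue + config.
    """
    if config is None:
        config = SolverConfig()
    if profiles is None:
        profiles = default_profiles()
    layers = _layers_of(tissue)
    nl = len(layers)
    base = layers[0]
    ny, nx = base.ny, base.nx
    n2 = ny * nx
    rep = check_stability(tissue, config)
    if not rep["ok"]:
        raise StabilityViolation(
            f"dt={rep['dt']} exceeds the stability bound {rep['dt_max']:.3g} ms "
            f"(binding node {rep['binding_node']}, {rep['binding_kind']})")

    paired = config.coupling_mode == "paired"
    v_l, myo_l, fib_l, gs_l, ach_l = [], [], [], [], []
    for g in layers:
        vg, myog, fibg = initial_node_states(g, myo_init, fib_init,
                                             config.coupling_mode)
        v_l.append(vg)
        myo_l.append(myog)
        fib_l.append(fibg)
        gs, ach = node_membrane_arrays(g, profiles)
        gs_l.append(gs)
        ach_l.append(ach)
    v = np.stack(v_l)
    myo = np.concatenate(myo_l)
    fib = np.concatenate(fib_l)
    gscale = np.concatenate(gs_l)
    achfac = np.concatenate(ach_l)
    if initial_v is not None:
        v = np.array(initial_v, dtype=float).reshape(nl, ny, nx)
    kind = np.concatenate([g.node_kind.ravel() for g in layers]).astype(np.int8)
    capfac = np.ones(kind.size) if paired else CAP_FACTOR[kind]
    gap_cm = config.gap_junction_ns / cmod.CM_MYO
    fib_caps = np.array([CELL_PARAMS[KIND_NAME[k]].capacitance
                         for k in range(4)])
    gap_cf = np.where(kind > 0, config.gap_junction_ns / fib_caps[kind], 0.0)
    plane_sig, _ = slab_layer_sigmas(tissue)
    w_l = [fem_coupling_weights(g, config, plane_sig[l])
           for l, g in enumerate(layers)]
    wx = np.stack([w[0] for w in w_l])
    wy = np.stack([w[1] for w in w_l])
    wa = np.stack([w[2] for w in w_l])
    wb = np.stack([w[3] for w in w_l])
    inv_mass = np.stack([w[4] for w in w_l])
    wv = (vertical_coupling_weights(tissue, config) if nl > 1
          else np.zeros((0, ny, nx)))
    table = build_voltage_tables(config.dt)

    n_steps = int(round(duration / config.dt))
    probes = [(p if len(p) == 3 else (0,) + tuple(p))
              for p in (config.probes or [])]
    probe_l = np.array([p[0] for p in probes], dtype=np.int64)
    probe_j = np.array([p[1] for p in probes], dtype=np.int64)
    probe_i = np.array([p[2] for p in probes], dtype=np.int64)
    probe_out = np.zeros((n_steps + 1, len(probes)))
    for p in range(len(probes)):
        probe_out[0, p] = v[probe_l[p], probe_j[p], probe_i[p]]

    if config.snapshot_interval and config.snapshot_interval > 0:
        snap_every = max(1, int(round(config.snapshot_interval / config.dt)))
        n_frames = n_steps // snap_every
    else:
        snap_every, n_frames = 0, 0
    snaps = np.zeros((n_frames, nl, ny, nx), dtype=np.float32)

    ev = _pack_protocol(protocol, base, nl, n2)
    status, fj, fi, t_end = _run_kernel(
        v, myo, fib, kind, gscale, achfac, capfac, gap_cm, gap_cf,
        wx, wy, wa, wb, wv, inv_mass, table, config.dt, n_steps,
        ev[0], ev[1], ev[2], ev[3], ev[4], ev[5],
        probe_l, probe_j, probe_i, probe_out, snap_every, snaps,
        config.check_every, diffusion_only, paired)

    snap_times = (np.arange(1, n_frames + 1) * snap_every * config.dt
                  if n_frames else np.zeros(0))
    manifest = {
        "dt": config.dt,
        "surface_to_volume": config.surface_to_volume,
        "specific_capacitance": config.specific_capacitance,
        "coupling_mode": config.coupling_mode,
        "gap_junction_ns": config.gap_junction_ns,
        "duration": duration,
        "n_nodes": nl * n2,
        "n_layers": nl,
        "fibrosis": dict(tissue.fibrosis_manifest),
        "profiles": {r: {"gscale": list(p.gscale),
                         "ach": p.ach_concentration}
                     for r, p in profiles.items()},
    }
    state = SimulationState(
        t=t_end, v=v[0] if nl == 1 else v, myo_state=myo, fib_state=fib,
        probe_times=np.arange(n_steps + 1) * config.dt, probe_vm=probe_out,
        snapshot_times=snap_times,
        snapshots=snaps[:, 0] if nl == 1 else snaps,
        status="ok" if status == 0 else "non_finite",
        fail_node=None if status == 0 else (fj, fi),
        manifest=manifest)
    if status != 0:
        raise RuntimeError(
            f"non-finite potential at node {(fj, fi)} at t = {t_end} ms")
    return state


def step(grid: TissueGrid, config: SolverConfig | None = None,
         profiles: dict | None = None, n_steps: int = 1,
         initial_v: np.ndarray | None = None, myo_init=None,
         diffusion_only: bool = False) -> SimulationState:
    """Advance a protocol-free system by ``n_steps`` single steps (testing aid)."""
    if config is None:
        config = SolverConfig()
    duration = n_steps * config.dt
    return simulate(grid, None, duration, config, profiles,
                    myo_init=myo_init, diffusion_only=diffusion_only,
                    initial_v=initial_v)


def prepaced_initial_states(profiles: dict, n_beats: int = 2,
                            cycle_length: float = 1000.0,
                            dt: float = 0.01) -> dict:
    """Region-wise myocyte states after the pre-pacing equilibration beats."""
    out = {}
    for rname, prof in profiles.items():
        if rname == "excluded":
            continue
        _, _, y = cmod.pace_single_cell(prof, n_beats=n_beats,
                                        cycle_length=cycle_length, dt=dt)
        out[rname] = y
    return out


def calibrate_surface_to_volume(target_cv: float = 62.0,
                                config: SolverConfig | None = None,
                                n_iter: int = 12,
                                chi_bounds=(2e4, 2e6)) -> float:
    """Bisection on chi so a homogeneous strip conducts at ``target_cv`` cm/s.

    This reproduces the calibration that fixed ``DEFAULT_CHI``; it is not run
    automatically.
    """
    from .biomarkers import conduction_velocity
    from .protocols import StimulusProtocol
    from .synthetic_tissue import make_sheet

    base = config or SolverConfig()
    lo, hi = chi_bounds

    def cv_for(chi):
        cfg = SolverConfig(dt=base.dt, surface_to_volume=chi,
                           specific_capacitance=base.specific_capacitance,
                           snapshot_interval=0,
                           probes=[(3, 30), (3, 40)])
        grid = make_sheet(70, 7, region_layout="left_atrium")
        prot = StimulusProtocol(s1_site=("edge", "left"), s1_times=(0.0,))
        profiles = default_profiles()
        init = prepaced_initial_states(profiles)
        res = simulate(grid, prot, 120.0, cfg, profiles, myo_init=init)
        a = res.probe_trace(0)
        b = res.probe_trace(1)
        return conduction_velocity(a, b, 10 * grid.spacing)

    # CV decreases as chi grows (larger chi = smaller effective diffusivity)
    for _ in range(n_iter):
        mid = math.sqrt(lo * hi)
        if cv_for(mid) > target_cv:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)
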