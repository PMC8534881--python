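"""Membrane kinetics of the AF-remodeled human atrial cardiomyocyte and fibrotic cells.

The cardiomyocyte is the Courtemanche–Ramirez–Nattel (CRN) human atrial model
augmented with the acetylcholine-activated inward-rectifier current ``I_KACh``
and multiplicative conductance scalings that represent persistent-AF electrical
remodeling (different in the left and right atrium).  Fibroblasts,
myofibroblasts and fibrocytes share the MacCannell active-fibroblast membrane
model; they differ only in membrane capacitance and tissue conductivity.

State layout (cardiomyocyte, 21 doubles)::

    0  Vm (mV)
    1..15  gates: m h j oa oi ua ui xr xs d f fca u v w
    16..20 concentrations (mM): Na_i K_i Ca_i Ca_up Ca_rel

State layout (fibrotic cell, 3 doubles)::

    0  Vcfi (mV)
    1  r  (time-dependent K+ activation)
    2  s  (time-dependent K+ inactivation)

All membrane currents are current densities in pA/pF, so dV/dt = -(Iion + Ist)
in mV/ms regardless of the absolute capacitance of the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Physical constants and cell parameters
# ---------------------------------------------------------------------------

R_GAS = 8.3143        # J / (mol K)
TEMP = 310.0          # K
FARADAY = 96.4867     # C / mmol
RTF = R_GAS * TEMP / FARADAY   # ~26.71 mV

CM_MYO = 100.0        # pF, cardiomyocyte membrane capacitance

# bath concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 1.8

# cell volumes (um^3)
V_CELL = 20100.0
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

# maximal conductances (nS/pF) and transport rates of the baseline CRN model
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375
I_NAK_MAX = 0.59933874    # pA/pF
I_NACA_MAX = 1600.0       # pA/pF
I_PCA_MAX = 0.275         # pA/pF
I_UP_MAX = 0.005          # mM/ms
K_Q10 = 3.0
GAMMA = 0.35
KM_NA_I = 10.0
KM_K_O = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
K_REL = 30.0
K_UP = 0.00092
CA_UP_MAX = 15.0
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8
TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0

#: published initial (resting) state of the baseline CRN model
CRN_INITIAL_STATE = np.array([
    -81.18,       # Vm
    2.908e-3,     # m
    9.649e-1,     # h
    9.775e-1,     # j
    3.043e-2,     # oa
    9.992e-1,     # oi
    4.966e-3,     # ua
    9.986e-1,     # ui
    3.296e-5,     # xr
    1.869e-2,     # xs
    1.367e-4,     # d
    9.996e-1,     # f
    7.755e-1,     # fca
    0.0,          # u   (2.35e-112 in the source publication)
    1.0,          # v
    9.992e-1,     # w
    1.117e1,      # Na_i
    1.39e2,       # K_i
    1.013e-4,     # Ca_i
    1.488,        # Ca_up
    1.488,        # Ca_rel
])

N_STATE_MYO = 21
N_STATE_FIB = 3

GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f",
              "fca", "u", "v", "w")
CONC_NAMES = ("na_i", "k_i", "ca_i", "ca_up", "ca_rel")

# names of the scalable maximal conductances, in the order used throughout
SCALED_CURRENTS = ("I_to", "I_Kur", "I_Ks", "I_K1", "I_CaL")

#: AF electrical-remodeling conductance factors per atrium.
#: LA: I_to -75%, I_Kur -45%, I_Ks +100%, I_K1 +100%, I_CaL -65%
#: RA: I_to -45%, I_Kur -60%, I_Ks +150%, I_K1 +100%, I_CaL -65%
AF_REMODELING_FACTORS = {
    "left_atrium": {"I_to": 0.25, "I_Kur": 0.55, "I_Ks": 2.0,
                    "I_K1": 2.0, "I_CaL": 0.35},
    "right_atrium": {"I_to": 0.55, "I_Kur": 0.40, "I_Ks": 2.5,
                     "I_K1": 2.0, "I_CaL": 0.35},
    "none": {name: 1.0 for name in SCALED_CURRENTS},
}

#: default acetylcholine concentration (uM) for I_KACh.  Chosen once so that
#: the LA-remodeled tissue sheet repolarizes with APD90 near the no-fibrosis
#: working point used throughout the package; exposed in every config.
DEFAULT_ACH = 0.00075

# I_Kur's maximal conductance is voltage dependent (0.005 + 0.05 / (1 +
# exp(-(V - 15) / 13))); its table entry is the dimensionless multiplier.
BASELINE_CONDUCTANCES = {
    "I_Na": G_NA, "I_K1": G_K1, "I_to": G_TO, "I_Kur": 1.0, "I_Kr": G_KR,
    "I_Ks": G_KS, "I_CaL": G_CAL, "I_bCa": G_B_CA, "I_bNa": G_B_NA,
}

CELL_KINDS = ("cardiomyocyte", "fibroblast", "myofibroblast", "fibrocyte")

# integer codes used on tissue grids
KIND_CODE = {"cardiomyocyte": 0, "fibroblast": 1, "myofibroblast": 2,
             "fibrocyte": 3}
KIND_NAME = {v: k for k, v in KIND_CODE.items()}


@dataclass(frozen=True)
class CellParams:
    """Membrane capacitance (pF) and tissue conductivity (S/cm) per cell kind."""

    kind: str
    capacitance: float
    tissue_conductivity: float


CELL_PARAMS = {
    "cardiomyocyte": CellParams("cardiomyocyte", 100.0, 0.26),
    "fibroblast": CellParams("fibroblast", 6.3, 0.078),
    "myofibroblast": CellParams("myofibroblast", 50.4, 0.078),
    "fibrocyte": CellParams("fibrocyte", 6.3, 0.024),
}


@dataclass
class RemodelingProfile:
    """Regional AF remodeling: conductance scale factors plus [ACh] for I_KACh."""

    region: str = "none"
    scale_Ito: float = 1.0
    scale_IKur: float = 1.0
    scale_IKs: float = 1.0
    scale_IK1: float = 1.0
    scale_ICaL: float = 1.0
    ach_concentration: float = 0.0

    @classmethod
    def for_region(cls, region: str,
                   ach_concentration: float = DEFAULT_ACH) -> "RemodelingProfile":
        if region not in AF_REMODELING_FACTORS:
            raise ValueError(f"unknown region tag: {region!r}")
        f = AF_REMODELING_FACTORS[region]
        return cls(region=region, scale_Ito=f["I_to"], scale_IKur=f["I_Kur"],
                   scale_IKs=f["I_Ks"], scale_IK1=f["I_K1"],
                   scale_ICaL=f["I_CaL"], ach_concentration=ach_concentration)

    @property
    def gscale(self) -> np.ndarray:
        """Scale factors as an array in SCALED_CURRENTS order."""
        return np.array([self.scale_Ito, self.scale_IKur, self.scale_IKs,
                         self.scale_IK1, self.scale_ICaL])


def apply_af_remodeling(base_conductances: dict, region: str) -> dict:
    """Return the maximal conductances after the persistent-AF scalings.

    ``region`` is ``left_atrium``, ``right_atrium`` or ``none``; conductances
    not listed in the remodeling table pass through unchanged.
    """
    if region not in AF_REMODELING_FACTORS:
        raise ValueError(f"unknown region tag: {region!r}")
    factors = AF_REMODELING_FACTORS[region]
    return {name: g * factors.get(name, 1.0)
            for name, g in base_conductances.items()}


@dataclass
class IonicState:
    """Cardiomyocyte membrane state: potential, gates and concentrations."""

    vm: float = CRN_INITIAL_STATE[0]
    gates: np.ndarray = field(
        default_factory=lambda: CRN_INITIAL_STATE[1:16].copy())
    concentrations: np.ndarray = field(
        default_factory=lambda: CRN_INITIAL_STATE[16:21].copy())

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.vm], self.gates, self.concentrations))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "IonicState":
        y = np.asarray(y, dtype=float)
        return cls(vm=float(y[0]), gates=y[1:16].copy(),
                   concentrations=y[16:21].copy())

    def validate(self) -> None:
        y = self.as_vector()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite cardiomyocyte state")
        if np.any(self.gates < 0.0) or np.any(self.gates > 1.0):
            raise ValueError("gate variable outside [0, 1]")
        if np.any(self.concentrations <= 0.0):
            raise ValueError("non-positive ionic concentration")


@dataclass
class FibroticState:
    """Fibrotic-cell membrane state: potential and the two K+ gates."""

    vcfi: float = -49.6
    r: float = 0.0
    s: float = 1.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.vcfi, self.r, self.s])

    @classmethod
    def from_vector(cls, y) -> "FibroticState":
        return cls(vcfi=float(y[0]), r=float(y[1]), s=float(y[2]))


# ---------------------------------------------------------------------------
# CRN rate functions and currents (single transcription, numba-compiled)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _crn_gate_coeffs(v):
    """Steady states and time constants of the 12 voltage-dependent CRN gates.

    Order: m h j oa oi ua ui xr xs d f w.  Singular points of the rate
    expressions are replaced by their analytic limits.
    """
    inf = np.empty(12)
    tau = np.empty(12)

    # m
    if abs(v + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
    b_m = 0.08 * math.exp(-v / 11.0)
    inf[0] = a_m / (a_m + b_m)
    tau[0] = 1.0 / (a_m + b_m)

    # h, j
    if v >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(v + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        a_j = ((-1.2714e5 * math.exp(0.2444 * v)
                - 3.474e-5 * math.exp(-0.04391 * v)) * (v + 37.78)
               / (1.0 + math.exp(0.311 * (v + 79.23))))
        b_j = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    inf[1] = a_h / (a_h + b_h)
    tau[1] = 1.0 / (a_h + b_h)
    inf[2] = a_j / (a_j + b_j)
    tau[2] = 1.0 / (a_j + b_j)

    # oa, oi (transient outward)
    a_oa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau[3] = 1.0 / ((a_oa + b_oa) * K_Q10)
    inf[3] = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    tau[4] = 1.0 / ((a_oi + b_oi) * K_Q10)
    inf[4] = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))

    # ua, ui (ultra-rapid)
    a_ua = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau[5] = 1.0 / ((a_ua + b_ua) * K_Q10)
    inf[5] = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    b_ui = math.exp((v - 158.0) / 16.0)
    tau[6] = 1.0 / ((a_ui + b_ui) * K_Q10)
    inf[6] = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))

    # xr
    if abs(v + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (v + 14.1) / (1.0 - math.exp(-(v + 14.1) / 5.0))
    if abs(v - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * (v - 3.3328) / (math.exp((v - 3.3328) / 5.1237) - 1.0)
    tau[7] = 1.0 / (a_xr + b_xr)
    inf[7] = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5))

    # xs
    if abs(v - 19.9) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * (v - 19.9) / (1.0 - math.exp(-(v - 19.9) / 17.0))
        b_xs = 3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1.0)
    tau[8] = 0.5 / (a_xs + b_xs)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-(v - 19.9) / 12.7))

    # d
    inf[9] = 1.0 / (1.0 + math.exp(-(v + 10.0) / 8.0))
    if abs(v + 10.0) < 1e-10:
        tau[9] = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e = math.exp(-(v + 10.0) / 6.24)
        tau[9] = (1.0 - e) / (0.035 * (v + 10.0) * (1.0 + e))

    # f
    inf[10] = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)

    # w
    inf[11] = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))
    if abs(v - 7.9) < 1e-10:
        tau[11] = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-(v - 7.9) / 5.0)
        tau[11] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * (v - 7.9))

    return inf, tau


@njit(cache=False)
def _crn_voltage_factors(v):
    """Voltage-only factors of the CRN + I_KACh current equations.

    Returns (k1_den, g_kur, kr_fac, f_nak, naca_e1, naca_e2, kach_gate).
    """
    k1_den = 1.0 / (1.0 + math.exp(0.07 * (v + 80.0)))
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    kr_fac = 1.0 / (1.0 + math.exp((v + 15.0) / 22.4))
    sigma = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * FARADAY * v / (R_GAS * TEMP))
                   + 0.0365 * sigma * math.exp(-FARADAY * v / (R_GAS * TEMP)))
    naca_e1 = math.exp(GAMMA * FARADAY * v / (R_GAS * TEMP))
    naca_e2 = math.exp((GAMMA - 1.0) * FARADAY * v / (R_GAS * TEMP))
    kach_gate = 0.0517 + 0.4516 / (1.0 + math.exp((v + 59.53) / 17.18))
    return k1_den, g_kur, kr_fac, f_nak, naca_e1, naca_e2, kach_gate


@njit(cache=False)
def _crn_currents(y, gscale, ach):
    """All membrane currents (pA/pF) of the remodeled CRN + I_KACh model.

    Order: INa IK1 Ito IKur IKr IKs ICaL IpCa INaK INaCa IbNa IbCa IKACh.
    """
    v = y[0]
    m, h, j = y[1], y[2], y[3]
    oa, oi, ua, ui = y[4], y[5], y[6], y[7]
    xr, xs, d, f, fca = y[8], y[9], y[10], y[11], y[12]
    na_i, k_i, ca_i = y[16], y[17], y[18]

    e_na = RTF * math.log(NA_O / na_i)
    e_k = RTF * math.log(K_O / k_i)
    e_ca = 0.5 * RTF * math.log(CA_O / ca_i)

    k1_den, g_kur, kr_fac, f_nak, e1, e2, kach_gate = _crn_voltage_factors(v)

    i_na = G_NA * m ** 3 * h * j * (v - e_na)
    i_k1 = gscale[3] * G_K1 * (v - e_k) * k1_den
    i_to = gscale[0] * G_TO * oa ** 3 * oi * (v - e_k)
    i_kur = gscale[1] * g_kur * ua ** 3 * ui * (v - e_k)
    i_kr = G_KR * xr * (v - e_k) * kr_fac
    i_ks = gscale[2] * G_KS * xs * xs * (v - e_k)
    i_cal = gscale[4] * G_CAL * d * f * fca * (v - 65.0)
    i_pca = I_PCA_MAX * ca_i / (0.0005 + ca_i)
    i_nak = (I_NAK_MAX * f_nak * (1.0 / (1.0 + (KM_NA_I / na_i) ** 1.5))
             * (K_O / (K_O + KM_K_O)))
    i_naca = (I_NACA_MAX * (e1 * na_i ** 3 * CA_O - e2 * NA_O ** 3 * ca_i)
              / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * e2)))
    i_bna = G_B_NA * (v - e_na)
    i_bca = G_B_CA * (v - e_ca)
    if ach > 0.0:
        i_kach = (10.0 / (1.0 + 9.13652 / ach ** 0.477811)) * kach_gate * (v - e_k)
    else:
        i_kach = 0.0

    out = np.empty(13)
    out[0] = i_na
    out[1] = i_k1
    out[2] = i_to
    out[3] = i_kur
    out[4] = i_kr
    out[5] = i_ks
    out[6] = i_cal
    out[7] = i_pca
    out[8] = i_nak
    out[9] = i_naca
    out[10] = i_bna
    out[11] = i_bca
    out[12] = i_kach
    return out


@njit(cache=False)
def _crn_derivs(y, gscale, ach, ist):
    """Full right-hand side of the myocyte state vector; returns (dy, Iion)."""
    cur = _crn_currents(y, gscale, ach)
    (i_na, i_k1, i_to, i_kur, i_kr, i_ks, i_cal, i_pca, i_nak, i_naca,
     i_bna, i_bca, i_kach) = (cur[0], cur[1], cur[2], cur[3], cur[4], cur[5],
                              cur[6], cur[7], cur[8], cur[9], cur[10],
                              cur[11], cur[12])
    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca + i_kach)

    v = y[0]
    fca, u, vg, w = y[12], y[13], y[14], y[15]
    na_i, k_i, ca_i, ca_up, ca_rel = y[16], y[17], y[18], y[19], y[20]

    dy = np.empty(N_STATE_MYO)
    dy[0] = -(i_ion + ist)

    inf, tau = _crn_gate_coeffs(v)
    for g in range(12):
        idx = g + 1 if g < 11 else 15      # gates 1..11 then w at slot 15
        dy[idx] = (inf[g] - y[idx]) / tau[g]

    # Ca-dependent inactivation of ICaL
    fca_inf = 1.0 / (1.0 + ca_i / 0.00035)
    dy[12] = (fca_inf - fca) / TAU_F_CA

    # SR release gating driven by Fn (currents converted to pA with Cm)
    i_rel = K_REL * u * u * vg * w * (ca_rel - ca_i)
    fn = 1e3 * (1e-15 * V_REL * i_rel
                - (1e-15 / (2.0 * FARADAY))
                * (0.5 * i_cal * CM_MYO - 0.2 * i_naca * CM_MYO))
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    dy[13] = (u_inf - u) / TAU_U
    dy[14] = (v_inf - vg) / tau_v

    i_up = I_UP_MAX / (1.0 + K_UP / ca_i)
    i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX
    i_tr = (ca_up - ca_rel) / TAU_TR

    dy[16] = (-3.0 * i_nak - (3.0 * i_naca + i_bna + i_na)) * CM_MYO / (V_I * FARADAY)
    dy[17] = (2.0 * i_nak - (i_k1 + i_to + i_kur + i_kr + i_ks + i_kach)) \
        * CM_MYO / (V_I * FARADAY)
    b1 = ((2.0 * i_naca - (i_pca + i_cal + i_bca)) * CM_MYO / (2.0 * V_I * FARADAY)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2)
    dy[18] = b1 / b2
    dy[19] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[20] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2)
    return dy, i_ion


# ---------------------------------------------------------------------------
# MacCannell active fibroblast (shared by fibroblast / myofibroblast / fibrocyte)
# ---------------------------------------------------------------------------

# fixed intracellular milieu of the fibroblast
NA_I_FIB = 8.5547
K_I_FIB = 129.4349
G_KV_FIB = 0.25        # nS/pF, time- and voltage-dependent K+
G_K1_FIB = 0.4822      # nS/pF, inward rectifier
G_B_NA_FIB = 0.0095    # nS/pF, background Na+
I_NAK_MAX_FIB = 2.002  # pA/pF
KM_K_FIB = 1.0
KM_NA_FIB = 11.0
V_REV_NAK_FIB = -150.0
B_NAK_FIB = -200.0

FIB_INITIAL_STATE = np.array([-49.6, 0.0, 1.0])


@njit(cache=False)
def _fib_gate_coeffs(v):
    r_inf = 1.0 / (1.0 + math.exp(-(v + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * math.exp(-((v + 20.0) / 25.9) ** 2)
    s_inf = 1.0 / (1.0 + math.exp((v + 23.0) / 7.0))
    tau_s = 1574.0 + 5268.0 * math.exp(-((v + 23.0) / 22.7) ** 2)
    return r_inf, tau_r, s_inf, tau_s


@njit(cache=False)
def _fib_currents(v, r, s):
    """MacCannell fibroblast currents (pA/pF): I_Kv, I_K1, I_NaK, I_bNa."""
    e_k = RTF * math.log(K_O / K_I_FIB)
    e_na = RTF * math.log(NA_O / NA_I_FIB)
    i_kv = G_KV_FIB * r * s * (v - e_k)
    vk = v - e_k
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (vk - 200.0)))
    b_k1 = ((3.0 * math.exp(0.0002 * (vk + 100.0)) + math.exp(0.1 * (vk - 10.0)))
            / (1.0 + math.exp(-0.5 * vk)))
    i_k1 = G_K1_FIB * (a_k1 / (a_k1 + b_k1)) * vk
    i_nak = (I_NAK_MAX_FIB * (K_O / (K_O + KM_K_FIB))
             * (NA_I_FIB ** 1.5 / (NA_I_FIB ** 1.5 + KM_NA_FIB ** 1.5))
             * (v - V_REV_NAK_FIB) / (v - B_NAK_FIB))
    i_bna = G_B_NA_FIB * (v - e_na)
    return i_kv, i_k1, i_nak, i_bna


@njit(cache=False)
def _fib_derivs(y, ist):
    v, r, s = y[0], y[1], y[2]
    i_kv, i_k1, i_nak, i_bna = _fib_currents(v, r, s)
    i_tot = i_kv + i_k1 + i_nak + i_bna
    r_inf, tau_r, s_inf, tau_s = _fib_gate_coeffs(v)
    dy = np.empty(3)
    dy[0] = -(i_tot + ist)
    dy[1] = (r_inf - r) / tau_r
    dy[2] = (s_inf - s) / tau_s
    return dy, i_tot


# ---------------------------------------------------------------------------
# Public right-hand sides
# ---------------------------------------------------------------------------

def cardiomyocyte_rhs(state, profile: RemodelingProfile, ist: float = 0.0):
    """Time derivatives and total ionic current of the remodeled cardiomyocyte.

    Parameters
    ----------
    state : IonicState or state vector of length 21
    profile : RemodelingProfile
        Regional conductance scalings and [ACh] for I_KACh.
    ist : float
        Stimulus current density in pA/pF (negative = depolarizing, so that
        dVm/dt = -(Iion + Ist)).

    Returns
    -------
    (dstate, iion) : derivatives in the same layout as the state, and the
    total ionic current density in pA/pF.
    """
    if isinstance(state, IonicState):
        y = state.as_vector()
    else:
        y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state values")
    dy, i_ion = _crn_derivs(y, profile.gscale, profile.ach_concentration,
                            float(ist))
    return dy, float(i_ion)


def cardiomyocyte_currents(state, profile: RemodelingProfile) -> dict:
    """Per-current breakdown (pA/pF) at the given clamped state."""
    if isinstance(state, IonicState):
        y = state.as_vector()
    else:
        y = np.asarray(state, dtype=float)
    cur = _crn_currents(y, profile.gscale, profile.ach_concentration)
    names = ("I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
             "I_pCa", "I_NaK", "I_NaCa", "I_bNa", "I_bCa", "I_KACh")
    return {n: float(c) for n, c in zip(names, cur)}


def fibrotic_rhs(state, params: CellParams, ist: float = 0.0):
    """Derivatives and total membrane current of a fibrotic cell.

    The three fibrotic kinds share the same membrane model; the returned
    current ``icfi`` is the absolute current in pA (density times the kind's
    capacitance), while dVcfi/dt = -Icfi/Ccfi = -(density + ist) in mV/ms.
    """
    if params.kind == "cardiomyocyte":
        raise ValueError("cardiomyocyte is not a fibrotic cell kind")
    if isinstance(state, FibroticState):
        y = state.as_vector()
    else:
        y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state values")
    dy, i_density = _fib_derivs(y, float(ist))
    return dy, float(i_density) * params.capacitance


def fibrotic_currents(state) -> dict:
    if isinstance(state, FibroticState):
        y = state.as_vector()
    else:
        y = np.asarray(state, dtype=float)
    i_kv, i_k1, i_nak, i_bna = _fib_currents(y[0], y[1], y[2])
    return {"I_Kv": float(i_kv), "I_K1": float(i_k1), "I_NaK": float(i_nak),
            "I_bNa": float(i_bna)}


# ---------------------------------------------------------------------------
# Single-cell integration (exact rates, Rush-Larsen gates + forward Euler)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _crn_step(y, gscale, ach, ist, dt):
    """One Rush-Larsen / Euler step of the single myocyte, in place."""
    v = y[0]
    cur = _crn_currents(y, gscale, ach)
    i_cal = cur[6]
    i_naca = cur[9]
    i_ion = 0.0
    for k in range(13):
        i_ion += cur[k]

    inf, tau = _crn_gate_coeffs(v)
    for g in range(12):
        idx = g + 1 if g < 11 else 15
        y[idx] = inf[g] + (y[idx] - inf[g]) * math.exp(-dt / tau[g])

    ca_i, ca_up, ca_rel = y[18], y[19], y[20]
    fca_inf = 1.0 / (1.0 + ca_i / 0.00035)
    y[12] = fca_inf + (y[12] - fca_inf) * math.exp(-dt / TAU_F_CA)

    i_rel = K_REL * y[13] * y[13] * y[14] * y[15] * (ca_rel - ca_i)
    fn = 1e3 * (1e-15 * V_REL * i_rel
                - (1e-15 / (2.0 * FARADAY))
                * (0.5 * i_cal * CM_MYO - 0.2 * i_naca * CM_MYO))
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    y[13] = u_inf + (y[13] - u_inf) * math.exp(-dt / TAU_U)
    y[14] = v_inf + (y[14] - v_inf) * math.exp(-dt / tau_v)

    i_up = I_UP_MAX / (1.0 + K_UP / ca_i)
    i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX
    i_tr = (ca_up - ca_rel) / TAU_TR

    y[16] += dt * (-3.0 * cur[8] - (3.0 * i_naca + cur[10] + cur[0])) \
        * CM_MYO / (V_I * FARADAY)
    y[17] += dt * (2.0 * cur[8] - (cur[1] + cur[2] + cur[3] + cur[4]
                                   + cur[5] + cur[12])) * CM_MYO / (V_I * FARADAY)
    b1 = ((2.0 * i_naca - (cur[7] + i_cal + cur[11]))
          * CM_MYO / (2.0 * V_I * FARADAY)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2)
    y[18] += dt * b1 / b2
    y[19] += dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    y[20] += dt * (i_tr - i_rel) \
        / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2)

    y[0] = v + dt * (-(i_ion + ist))
    return i_ion


@njit(cache=False)
def _fib_step(y, ist, dt):
    dy, i_tot = _fib_derivs(y, ist)
    r_inf, tau_r, s_inf, tau_s = _fib_gate_coeffs(y[0])
    y[1] = r_inf + (y[1] - r_inf) * math.exp(-dt / tau_r)
    y[2] = s_inf + (y[2] - s_inf) * math.exp(-dt / tau_s)
    y[0] += dt * dy[0]
    return i_tot


@njit(cache=False)
def _integrate_myocyte(y, gscale, ach, dt, n_steps, stim_period, stim_start,
                       stim_duration, stim_amplitude, record_every):
    """Paced (or unstimulated) single-cell run; records t and Vm."""
    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    t_out[0] = 0.0
    v_out[0] = y[0]
    k = 1
    for i in range(n_steps):
        t = i * dt
        ist = 0.0
        if stim_period > 0.0:
            phase = (t - stim_start) % stim_period
            if t >= stim_start and phase < stim_duration:
                ist = -stim_amplitude
        _crn_step(y, gscale, ach, ist, dt)
        if (i + 1) % record_every == 0:
            t_out[k] = (i + 1) * dt
            v_out[k] = y[0]
            k += 1
    return t_out[:k], v_out[:k]


@njit(cache=False)
def _settle_myocyte(y, gscale, ach, dt, max_steps, drift_tol, check_every):
    """Advance the unstimulated myocyte until |dVm/dt| < drift_tol (mV/ms)."""
    drift = 1e30
    for i in range(max_steps):
        v_prev = y[0]
        _crn_step(y, gscale, ach, 0.0, dt)
        if (i + 1) % check_every == 0:
            drift = abs(y[0] - v_prev) / dt
            if drift < drift_tol:
                return (i + 1) * dt, drift
    return max_steps * dt, drift


@njit(cache=False)
def _settle_fibroblast(y, dt, max_steps, drift_tol, check_every):
    drift = 1e30
    for i in range(max_steps):
        v_prev = y[0]
        _fib_step(y, 0.0, dt)
        if (i + 1) % check_every == 0:
            drift = abs(y[0] - v_prev) / dt
            if drift < drift_tol:
                return (i + 1) * dt, drift
    return max_steps * dt, drift


def pace_single_cell(profile: RemodelingProfile, n_beats: int = 2,
                     cycle_length: float = 1000.0, dt: float = 0.01,
                     stim_duration: float = 2.0, stim_amplitude: float = 28.0,
                     y0: np.ndarray | None = None, record_every: int = 100):
    """Pace a single remodeled myocyte; returns (t, Vm, final state vector).

    The default two beats at 1000 ms cycle length are the pre-pacing
    equilibration used before tissue measurements.
    """
    y = CRN_INITIAL_STATE.copy() if y0 is None else np.asarray(y0, float).copy()
    n_steps = int(round(n_beats * cycle_length / dt))
    t, v = _integrate_myocyte(y, profile.gscale, profile.ach_concentration,
                              dt, n_steps, cycle_length, 0.0, stim_duration,
                              stim_amplitude, record_every)
    return t, v, y


@dataclass
class RestingPotentialResult:
    vm: float
    converged: bool
    drift: float          # |dVm/dt| at the end, mV/ms
    elapsed: float        # integrated model time, ms


def find_resting_potential(model_kind: str,
                           profile: RemodelingProfile | None = None,
                           dt: float = 0.01, time_limit: float = 20000.0,
                           drift_tol: float = 1e-6) -> RestingPotentialResult:
    """Integrate the unstimulated single cell to its resting potential.

    For the cardiomyocyte the AF-remodeled CRN model relaxes from the
    published initial state; fibrotic kinds share the MacCannell membrane and
    therefore one resting potential.  Non-convergence within ``time_limit``
    (ms of model time) is reported with the final drift magnitude.
    """
    if model_kind not in CELL_KINDS:
        raise ValueError(f"unknown cell kind: {model_kind!r}")
    max_steps = int(round(time_limit / dt))
    if model_kind == "cardiomyocyte":
        if profile is None:
            profile = RemodelingProfile.for_region("left_atrium")
        y = CRN_INITIAL_STATE.copy()
        elapsed, drift = _settle_myocyte(y, profile.gscale,
                                         profile.ach_concentration, dt,
                                         max_steps, drift_tol, 100)
    else:
        y = FIB_INITIAL_STATE.copy()
        elapsed, drift = _settle_fibroblast(y, dt, max_steps, drift_tol, 100)
    return RestingPotentialResult(vm=float(y[0]), converged=drift < drift_tol,
                                  drift=float(drift), elapsed=float(elapsed))


# ---------------------------------------------------------------------------
# Lookup tables for the tissue kernel
# ---------------------------------------------------------------------------

LUT_VMIN = -120.0
LUT_VMAX = 80.0
LUT_DV = 0.02

# table column layout: 12 gate steady states, 12 gate exp(-dt/tau) factors,
# then the 7 voltage factors of _crn_voltage_factors
LUT_N_COLS = 12 + 12 + 7


def build_voltage_tables(dt: float) -> np.ndarray:
    """Tabulate gate updates and voltage factors on a uniform Vm grid.

    The Rush-Larsen decay factor exp(-dt/tau(V)) is tabulated for the given
    time step, so tables are rebuilt whenever dt changes.
    """
    n = int(round((LUT_VMAX - LUT_VMIN) / LUT_DV)) + 1
    table = np.empty((LUT_N_COLS, n))
    for i in range(n):
        v = LUT_VMIN + i * LUT_DV
        inf, tau = _crn_gate_coeffs(v)
        for g in range(12):
            table[g, i] = inf[g]
            table[12 + g, i] = math.exp(-dt / tau[g])
        vf = _crn_voltage_factors(v)
        for k in range(7):
            table[24 + k, i] = vf[k]
    return table


def serialize_parameters() -> dict:
    """Versioned JSON-ready dump of cell parameters and remodeling factors."""
    return {
        "version": 1,
        "cells": {k: asdict(p) for k, p in CELL_PARAMS.items()},
        "baseline_conductances": dict(BASELINE_CONDUCTANCES),
        "af_remodeling_factors": {r: dict(f)
                                  for r, f in AF_REMODELING_FACTORS.items()},
        "default_ach_concentration": DEFAULT_ACH,
    }
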