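"""Independent transcription of the membrane current equations.

Used as the brute-force oracle for the right-hand sides in the package: each
current is written here as its own function, straight from the published
formulations, sharing no code with the implementation under test.
"""

import numpy as np

R = 8.3143
T = 310.0
F = 96.4867


def nernst(z, c_out, c_in):
    return R * T / (z * F) * np.log(c_out / c_in)


# --- human atrial myocyte (CRN) currents, densities in pA/pF ---

def i_na(v, m, h, j, na_i, na_o=140.0):
    return 7.8 * m ** 3 * h * j * (v - nernst(1, na_o, na_i))


def i_k1(v, k_i, k_o=5.4, scale=1.0):
    return scale * 0.09 * (v - nernst(1, k_o, k_i)) \
        / (1.0 + np.exp(0.07 * (v + 80.0)))


def i_to(v, oa, oi, k_i, k_o=5.4, scale=1.0):
    return scale * 0.1652 * oa ** 3 * oi * (v - nernst(1, k_o, k_i))


def i_kur(v, ua, ui, k_i, k_o=5.4, scale=1.0):
    g = 0.005 + 0.05 / (1.0 + np.exp((v - 15.0) / -13.0))
    return scale * g * ua ** 3 * ui * (v - nernst(1, k_o, k_i))


def i_kr(v, xr, k_i, k_o=5.4):
    return 0.029411765 * xr * (v - nernst(1, k_o, k_i)) \
        / (1.0 + np.exp((v + 15.0) / 22.4))


def i_ks(v, xs, k_i, k_o=5.4, scale=1.0):
    return scale * 0.12941176 * xs ** 2 * (v - nernst(1, k_o, k_i))


def i_ca_l(v, d, f, f_ca, scale=1.0):
    return scale * 0.12375 * d * f * f_ca * (v - 65.0)


def i_p_ca(ca_i):
    return 0.275 * ca_i / (0.0005 + ca_i)


def i_na_k(v, na_i, na_o=140.0, k_o=5.4):
    sigma = (np.exp(na_o / 67.3) - 1.0) / 7.0
    f_nak = (1.0 + 0.1245 * np.exp(-0.1 * F * v / (R * T))
             + 0.0365 * sigma * np.exp(-F * v / (R * T))) ** -1
    return 0.59933874 * f_nak * (1.0 + (10.0 / na_i) ** 1.5) ** -1 \
        * k_o / (k_o + 1.5)


def i_na_ca(v, na_i, ca_i, na_o=140.0, ca_o=1.8):
    gam = 0.35
    num = (np.exp(gam * F * v / (R * T)) * na_i ** 3 * ca_o
           - np.exp((gam - 1.0) * F * v / (R * T)) * na_o ** 3 * ca_i)
    den = ((87.5 ** 3 + na_o ** 3) * (1.38 + ca_o)
           * (1.0 + 0.1 * np.exp((gam - 1.0) * F * v / (R * T))))
    return 1600.0 * num / den


def i_b_na(v, na_i, na_o=140.0):
    return 0.0006744375 * (v - nernst(1, na_o, na_i))


def i_b_ca(v, ca_i, ca_o=1.8):
    return 0.001131 * (v - nernst(2, ca_o, ca_i))


def i_k_ach(v, ach, k_i, k_o=5.4):
    """Acetylcholine-activated K+ current (agonist concentration in uM)."""
    if ach <= 0:
        return 0.0
    dose = 10.0 / (1.0 + 9.13652 / ach ** 0.477811)
    gate = 0.0517 + 0.4516 / (1.0 + np.exp((v + 59.53) / 17.18))
    return dose * gate * (v - nernst(1, k_o, k_i))


def myocyte_total_current(y, scales, ach):
    """Sum of all myocyte currents; y is the 21-slot state vector.

    ``scales``: dict with keys to/kur/ks/k1/cal (AF-remodeling factors).
    """
    v = y[0]
    m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca = y[1:13]
    na_i, k_i, ca_i = y[16], y[17], y[18]
    return (i_na(v, m, h, j, na_i)
            + i_k1(v, k_i, scale=scales["k1"])
            + i_to(v, oa, oi, k_i, scale=scales["to"])
            + i_kur(v, ua, ui, k_i, scale=scales["kur"])
            + i_kr(v, xr, k_i)
            + i_ks(v, xs, k_i, scale=scales["ks"])
            + i_ca_l(v, d, f, fca, scale=scales["cal"])
            + i_p_ca(ca_i)
            + i_na_k(v, na_i)
            + i_na_ca(v, na_i, ca_i)
            + i_b_na(v, na_i)
            + i_b_ca(v, ca_i)
            + i_k_ach(v, ach, k_i))


# --- MacCannell fibroblast currents, densities in pA/pF ---

F_NA_I = 8.5547
F_K_I = 129.4349


def fib_i_kv(v, r, s):
    return 0.25 * r * s * (v - nernst(1, 5.4, F_K_I))


def fib_i_k1(v):
    ek = nernst(1, 5.4, F_K_I)
    x = v - ek
    alpha = 0.1 / (1.0 + np.exp(0.06 * (x - 200.0)))
    beta = (3.0 * np.exp(2e-4 * (x + 100.0)) + np.exp(0.1 * (x - 10.0))) \
        / (1.0 + np.exp(-0.5 * x))
    return 0.4822 * alpha / (alpha + beta) * x


def fib_i_na_k(v):
    return 2.002 * (5.4 / 6.4) \
        * F_NA_I ** 1.5 / (F_NA_I ** 1.5 + 11.0 ** 1.5) \
        * (v + 150.0) / (v + 200.0)


def fib_i_b_na(v):
    return 0.0095 * (v - nernst(1, 140.0, F_NA_I))


def fibroblast_total_current(v, r, s):
    return fib_i_kv(v, r, s) + fib_i_k1(v) + fib_i_na_k(v) + fib_i_b_na(v)
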