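"""Reference transcription of both ionic models, kept independent of the
simulation kernels.

Every current is written as one closed-form expression straight from the
published model formulations, using ``math`` scalars and named local
variables.  The simulation kernels in :mod:`cardiofib._kernels` must agree
with these expressions to near machine precision on random valid states;
the regression ("golden") tables produced by
:func:`cardiofib.surrogates.make_rhs_golden` are evaluated with this
module.  Nothing here is used by the simulators themselves.
"""

from math import exp, log, sqrt

# physical constants (same convention as the kernels: mV, ms, mM, pA/pF)
_F = 96485.3415
_R = 8314.472
_T = 310.0
_RTF = _R * _T / _F

MYO_STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s", "xr1", "xr2", "xs",
    "Na_i", "K_i", "Ca_i", "Ca_SR", "Ca_SS", "R_rel",
)

CURRENT_NAMES = (
    "I_Na", "I_to", "I_K1", "I_Kr", "I_Ks", "I_CaL",
    "I_NaK", "I_NaCa", "I_pCa", "I_pK", "I_bCa", "I_bNa",
)

FIB_CURRENT_NAMES = ("I_fKv", "I_fK1", "I_fNaK", "I_bNa")


def oracle_myocyte_currents(sv, p):
    """Membrane currents for a packed myocyte state vector ``sv`` and a
    :class:`~cardiofib.myocyte.MyocyteParams` ``p``.  Returns a dict keyed
    by current name."""
    V, m, h, j, d, f, f2, fCass, r, s, xr1, xr2, xs = sv[:13]
    Na_i, K_i, Ca_i, Ca_SR, Ca_SS = sv[13:18]
    Ko, Nao, Cao = p.K_o, p.Na_o, p.Ca_o

    E_Na = _RTF * log(Nao / Na_i)
    E_K = _RTF * log(Ko / K_i)
    E_Ks = _RTF * log((Ko + 0.03 * Nao) / (K_i + 0.03 * Na_i))
    E_Ca = 0.5 * _RTF * log(Cao / Ca_i)

    I_Na = p.g_Na * m * m * m * h * j * (V - E_Na)

    I_to = p.g_to * r * s * (V - E_K)

    I_K1 = p.g_K1 * (V - E_K) * (0.1 / (1.0 + exp(0.06 * (V - E_K - 200.0)))) / (
        0.1 / (1.0 + exp(0.06 * (V - E_K - 200.0)))
        + (3.0 * exp(0.0002 * (V - E_K + 100.0)) + exp(0.1 * (V - E_K - 10.0)))
        / (1.0 + exp(-0.5 * (V - E_K)))
    )

    I_Kr = p.y * p.g_Kr * sqrt(Ko / 5.4) * xr1 * xr2 * (V - E_K)

    I_Ks = p.g_Ks * xs * xs * (V - E_Ks)

    zeta = 2.0 * (V - 15.0) * _F / (_R * _T)
    if abs(zeta) < 1e-7:
        I_CaL = (p.g_cal_ead_scale * p.x * p.g_CaL) * d * f * f2 * fCass * 2.0 * _F * (
            0.25 * Ca_SS - Cao
        )
    else:
        I_CaL = (
            (p.g_cal_ead_scale * p.x * p.g_CaL)
            * d * f * f2 * fCass
            * 4.0 * (V - 15.0) * _F * _F / (_R * _T)
            * (0.25 * Ca_SS * exp(zeta) - Cao)
            / (exp(zeta) - 1.0)
        )

    I_NaK = (
        p.P_NaK * (Ko / (Ko + 1.0)) * (Na_i / (Na_i + 40.0))
        / (1.0 + 0.1245 * exp(-0.1 * V / _RTF) + 0.0353 * exp(-V / _RTF))
    )

    I_NaCa = (
        p.k_NaCa
        * (exp(0.35 * V / _RTF) * Na_i ** 3 * Cao - exp(-0.65 * V / _RTF) * Nao ** 3 * Ca_i * 2.5)
        / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao) * (1.0 + 0.1 * exp(-0.65 * V / _RTF)))
    )

    I_pCa = p.g_pCa * Ca_i / (Ca_i + 0.0005)

    I_pK = p.g_pK * (V - E_K) / (1.0 + exp((25.0 - V) / 5.98))

    I_bCa = p.g_bCa * (V - E_Ca)

    I_bNa = p.g_bNa * (V - E_Na)

    return dict(zip(CURRENT_NAMES, (
        I_Na, I_to, I_K1, I_Kr, I_Ks, I_CaL, I_NaK, I_NaCa, I_pCa, I_pK, I_bCa, I_bNa,
    )))


def oracle_myocyte_rhs(sv, p, I_stim=0.0, I_gap=0.0):
    """Full state derivative for the myocyte, as a dict keyed by state name."""
    cur = oracle_myocyte_currents(sv, p)
    V = sv[0]
    Ca_i, Ca_SR, Ca_SS, R_rel = sv[15], sv[16], sv[17], sv[18]

    out = {}
    out["V"] = -(sum(cur.values()) + I_stim + I_gap)

    # gate steady states / time constants
    m_inf = 1.0 / (1.0 + exp((-56.86 - V) / 9.03)) ** 2
    tau_m = (1.0 / (1.0 + exp((-60.0 - V) / 5.0))) * (
        0.1 / (1.0 + exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + exp((V - 50.0) / 200.0))
    )
    h_inf = 1.0 / (1.0 + exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        tau_h = 1.0 / (0.77 / (0.13 * (1.0 + exp(-(V + 10.66) / 11.1))))
        tau_j = 1.0 / (0.6 * exp(0.057 * V) / (1.0 + exp(-0.1 * (V + 32.0))))
    else:
        tau_h = 1.0 / (
            0.057 * exp(-(V + 80.0) / 6.8) + 2.7 * exp(0.079 * V) + 3.1e5 * exp(0.3485 * V)
        )
        tau_j = 1.0 / (
            (-2.5428e4 * exp(0.2444 * V) - 6.948e-6 * exp(-0.04391 * V)) * (V + 37.78)
            / (1.0 + exp(0.311 * (V + 79.23)))
            + 0.02424 * exp(-0.01052 * V) / (1.0 + exp(-0.1378 * (V + 40.14)))
        )
    d_inf = 1.0 / (1.0 + exp((-8.0 - V) / 7.5))
    tau_d = (1.4 / (1.0 + exp((-35.0 - V) / 13.0)) + 0.25) * (1.4 / (1.0 + exp((V + 5.0) / 5.0))) + 1.0 / (
        1.0 + exp((50.0 - V) / 20.0)
    )
    f_inf = 1.0 / (1.0 + exp((V + 20.0) / 7.0))
    tau_f = p.tau_f_scale * (
        1102.5 * exp(-((V + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + exp((13.0 - V) / 10.0))
        + 180.0 / (1.0 + exp((V + 30.0) / 10.0))
        + 20.0
    )
    f2_inf = 0.67 / (1.0 + exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * exp(-((V + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + exp((25.0 - V) / 10.0))
        + 80.0 / (1.0 + exp((V + 30.0) / 10.0))
    )
    fCass_inf = 0.6 / (1.0 + (Ca_SS / 0.05) ** 2) + 0.4
    tau_fCass = 80.0 / (1.0 + (Ca_SS / 0.05) ** 2) + 2.0
    r_inf = 1.0 / (1.0 + exp((20.0 - V) / 6.0))
    tau_r = 9.5 * exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + exp((V + 20.0) / 5.0))
    tau_s = 85.0 * exp(-((V + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + exp((V - 20.0) / 5.0)) + 3.0
    xr1_inf = 1.0 / (1.0 + exp((-26.0 - V) / 7.0))
    tau_xr1 = (450.0 / (1.0 + exp((-45.0 - V) / 10.0))) * (6.0 / (1.0 + exp((V + 30.0) / 11.5)))
    xr2_inf = 1.0 / (1.0 + exp((V + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + exp((-60.0 - V) / 20.0))) * (1.12 / (1.0 + exp((V - 60.0) / 20.0)))
    xs_inf = 1.0 / (1.0 + exp((-5.0 - V) / 14.0))
    tau_xs = (1400.0 / sqrt(1.0 + exp((5.0 - V) / 6.0))) * (1.0 / (1.0 + exp((V - 35.0) / 15.0))) + 80.0

    infs = (m_inf, h_inf, h_inf, d_inf, f_inf, f2_inf, fCass_inf, r_inf, s_inf, xr1_inf, xr2_inf, xs_inf)
    taus = (tau_m, tau_h, tau_j, tau_d, tau_f, tau_f2, tau_fCass, tau_r, tau_s, tau_xr1, tau_xr2, tau_xs)
    for name, gi, gt, g in zip(MYO_STATE_NAMES[1:13], infs, taus, sv[1:13]):
        out[name] = (gi - g) / gt

    # calcium subsystem
    k_casr = 2.5 - 1.5 / (1.0 + (1.5 / Ca_SR) ** 2)
    k1 = 0.15 / k_casr
    k2 = 0.045 * k_casr
    out["R_rel"] = 0.005 * (1.0 - R_rel) - k2 * Ca_SS * R_rel
    O_rel = k1 * Ca_SS ** 2 * R_rel / (0.060 + k1 * Ca_SS ** 2)
    I_rel = 0.102 * O_rel * (Ca_SR - Ca_SS)
    I_leak = 0.00036 * (Ca_SR - Ca_i)
    I_up = 0.006375 / (1.0 + (0.00025 / Ca_i) ** 2)
    I_xfer = 0.0038 * (Ca_SS - Ca_i)

    Vc, Vsr, Vss, Cm = 0.016404, 0.001094, 0.00005468, 0.185
    out["Ca_SR"] = (I_up - I_rel - I_leak) / (1.0 + 10.0 * 0.3 / (Ca_SR + 0.3) ** 2)
    out["Ca_SS"] = (
        -I_xfer * (Vc / Vss) + I_rel * (Vsr / Vss) - cur["I_CaL"] * Cm / (2.0 * Vss * _F)
    ) / (1.0 + 0.4 * 0.00025 / (Ca_SS + 0.00025) ** 2)
    out["Ca_i"] = (
        -(cur["I_bCa"] + cur["I_pCa"] - 2.0 * cur["I_NaCa"]) * Cm / (2.0 * Vc * _F)
        - (I_up - I_leak) * (Vsr / Vc)
        + I_xfer
    ) / (1.0 + 0.2 * 0.001 / (Ca_i + 0.001) ** 2)

    out["Na_i"] = -(cur["I_Na"] + cur["I_bNa"] + 3.0 * cur["I_NaK"] + 3.0 * cur["I_NaCa"]) * Cm / (Vc * _F)
    out["K_i"] = -(
        I_stim + cur["I_K1"] + cur["I_to"] + cur["I_Kr"] + cur["I_Ks"] - 2.0 * cur["I_NaK"] + cur["I_pK"]
    ) * Cm / (Vc * _F)
    return out


def oracle_fibroblast_currents(sv, p):
    """Fibroblast membrane currents (pA/pF) for packed state (V_F, r, s)."""
    V, r, s = sv[0], sv[1], sv[2]
    E_K = _RTF * log(p.K_o / p.K_i)
    E_Na = _RTF * log(p.Na_o / p.Na_i)

    I_fKv = p.g_Kv * r * s * (V - E_K)

    I_fK1 = p.g_K1 * (V - E_K) * (0.1 / (1.0 + exp(0.06 * (V - E_K - 200.0)))) / (
        0.1 / (1.0 + exp(0.06 * (V - E_K - 200.0)))
        + (3.0 * exp(0.0002 * (V - E_K + 100.0)) + exp(0.1 * (V - E_K - 10.0)))
        / (1.0 + exp(-0.5 * (V - E_K)))
    )

    I_fNaK = (
        p.P_NaK
        * (p.K_o / (p.K_o + p.K_mK))
        * (p.Na_i ** 1.5 / (p.Na_i ** 1.5 + p.K_mNa ** 1.5))
        * (V + 150.0) / (V + 200.0)
    )

    I_bNa = p.g_bNa * (V - E_Na)

    return dict(zip(FIB_CURRENT_NAMES, (I_fKv, I_fK1, I_fNaK, I_bNa)))


def oracle_fibroblast_rhs(sv, p, I_gap_pA=0.0):
    """Fibroblast state derivative as a dict (V_F, r, s)."""
    cur = oracle_fibroblast_currents(sv, p)
    V, r, s = sv[0], sv[1], sv[2]
    Vs = V - p.kv_shift
    r_inf = 1.0 / (1.0 + exp(-(Vs + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * exp(-(((Vs + 20.0) / 25.9) ** 2))
    s_inf = 1.0 / (1.0 + exp((Vs + 23.0) / 7.0))
    tau_s = 1574.0 + 5268.0 * exp(-(((Vs + 23.0) / 22.7) ** 2))
    return {
        "V_F": -(sum(cur.values()) - I_gap_pA / p.C_F),
        "r": (r_inf - r) / tau_r,
        "s": (s_inf - s) / tau_s,
    }
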