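"""Numba kernels for the ionic models and time stepping.

Myocyte: ten Tusscher & Panfilov 2006 (TP06) human ventricular model,
epicardial parameter set, with the standard EAD-enabling modifications
(halved tau_f of the L-type calcium f-gate, doubled base G_CaL) and the
two sweep multipliers x (on G_CaL) and y (on G_Kr).

Fibroblast: MacCannell "active" fibroblast (I_Kv, I_K1, I_NaK, I_bNa),
with an optional voltage offset applied to the I_Kv gating to retune the
resting potential.

Units: V in mV, t in ms, currents in pA/pF, concentrations in mM,
conductances in nS/pF unless noted.  Everything here operates on packed
float64 state/parameter vectors; the public dataclass API lives in
myocyte.py / fibroblast.py.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------- constants
F = 96485.3415  # C/mol
R = 8314.472    # mJ/(mol K)
T = 310.0       # K
RTONF = R * T / F  # mV
FONRT = 1.0 / RTONF

# cell geometry / buffering (TP06)
CAPACITANCE = 0.185  # uF, effective capacitance in concentration updates
VC = 0.016404
VSR = 0.001094
VSS = 0.00005468
BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025
VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038
PKNA = 0.03
KMK = 1.0
KMNA = 40.0
KMNAI = 87.5
KMCA = 1.38
KSAT = 0.1
NCXGAMMA = 0.35
KPCA = 0.0005

# myocyte state vector layout
IV, IM, IH, IJ, ID, IF, IF2, IFCASS, IR, IS, IXR1, IXR2, IXS = range(13)
INAI, IKI, ICAI, ICASR, ICASS, IRR = 13, 14, 15, 16, 17, 18
NVAR_M = 19

# myocyte parameter vector layout
PG_NA, PG_CAL, PG_TO, PG_KR, PG_KS, PG_K1, PG_PCA, PG_PK, PG_BNA, PG_BCA = range(10)
PP_NAK, PK_NACA, PX, PY, PTAUF, PEAD, PKO, PNAO, PCAO = range(10, 19)
NPAR_M = 19

# fibroblast state vector layout: V, r (Kv activation), s (Kv inactivation)
NVAR_F = 3

# fibroblast parameter layout
FC_F, FG_KV, FG_K1, FG_BNA, FP_NAK, FSHIFT, FKO, FNAO, FKI, FNAI, FKMK, FKMNA = range(12)
NPAR_F = 12

N_CURRENTS = 12  # INa Ito IK1 IKr IKs ICaL INaK INaCa IpCa IpK IbCa IbNa


@njit(cache=True)
def myocyte_currents_kernel(s, p, out):
    """All twelve TP06 membrane currents (pA/pF) for state s, params p."""
    v = s[IV]
    nai = s[INAI]
    ki = s[IKI]
    cai = s[ICAI]
    cass = s[ICASS]

    ko = p[PKO]
    nao = p[PNAO]
    cao = p[PCAO]

    ena = RTONF * np.log(nao / nai)
    ek = RTONF * np.log(ko / ki)
    eks = RTONF * np.log((ko + PKNA * nao) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * np.log(cao / cai)

    # fast sodium
    ina = p[PG_NA] * s[IM] ** 3 * s[IH] * s[IJ] * (v - ena)

    # transient outward (epicardial r,s gates)
    ito = p[PG_TO] * s[IR] * s[IS] * (v - ek)

    # inward rectifier
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (v - ek + 100.0)) + np.exp(0.1 * (v - ek - 10.0))) / (
        1.0 + np.exp(-0.5 * (v - ek))
    )
    ik1 = p[PG_K1] * ak1 / (ak1 + bk1) * (v - ek)

    # rapid delayed rectifier; y multiplier is the sweep knob
    ikr = p[PY] * p[PG_KR] * np.sqrt(ko / 5.4) * s[IXR1] * s[IXR2] * (v - ek)

    # slow delayed rectifier
    iks = p[PG_KS] * s[IXS] * s[IXS] * (v - eks)

    # L-type calcium; effective conductance = ead_scale * x * G_CaL
    gcal = p[PEAD] * p[PX] * p[PG_CAL]
    z = 2.0 * (v - 15.0) * FONRT
    gate = s[ID] * s[IF] * s[IF2] * s[IFCASS]
    if np.abs(z) < 1e-7:
        ical = gcal * gate * 2.0 * F * (0.25 * cass - cao)
    else:
        ez = np.exp(z)
        ical = gcal * gate * 4.0 * (v - 15.0) * F * FONRT * (0.25 * cass * ez - cao) / (ez - 1.0)

    # Na/K pump
    inak = (
        p[PP_NAK]
        * (ko / (ko + KMK))
        * (nai / (nai + KMNA))
        / (1.0 + 0.1245 * np.exp(-0.1 * v * FONRT) + 0.0353 * np.exp(-v * FONRT))
    )

    # Na/Ca exchanger
    eg = np.exp(NCXGAMMA * v * FONRT)
    eg1 = np.exp((NCXGAMMA - 1.0) * v * FONRT)
    inaca = (
        p[PK_NACA]
        * (eg * nai ** 3 * cao - eg1 * nao ** 3 * cai * 2.5)
        / ((KMNAI ** 3 + nao ** 3) * (KMCA + cao) * (1.0 + KSAT * eg1))
    )

    ipca = p[PG_PCA] * cai / (cai + KPCA)
    ipk = p[PG_PK] * (v - ek) / (1.0 + np.exp((25.0 - v) / 5.98))
    ibca = p[PG_BCA] * (v - eca)
    ibna = p[PG_BNA] * (v - ena)

    out[0] = ina
    out[1] = ito
    out[2] = ik1
    out[3] = ikr
    out[4] = iks
    out[5] = ical
    out[6] = inak
    out[7] = inaca
    out[8] = ipca
    out[9] = ipk
    out[10] = ibca
    out[11] = ibna


@njit(cache=True)
def myocyte_gate_rates(v, cass, p, inf, tau):
    """Steady states and time constants for the 12 voltage/Ca gates.

    Index order matches the state layout (IM..IXS), with fCass depending on
    subspace calcium.  tau_f carries the EAD modification (scaled by p[PTAUF]).
    """
    # m
    inf[0] = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    tau[0] = am * bm
    # h, j
    inf[1] = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    inf[2] = inf[1]
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
        aj = (
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    tau[1] = 1.0 / (ah + bh)
    tau[2] = 1.0 / (aj + bj)
    # d
    inf[3] = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau[3] = ad * bd + gd
    # f (tau halved in the EAD configuration via p[PTAUF])
    inf[4] = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau[4] = p[PTAUF] * (
        1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0))
        + 20.0
    )
    # f2
    inf[5] = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau[5] = (
        562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0))
    )
    # fCass
    inf[6] = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau[6] = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    # r
    inf[7] = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau[7] = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    # s (epicardial)
    inf[8] = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tau[8] = (
        85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
        + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0))
        + 3.0
    )
    # xr1
    inf[9] = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tau[9] = axr1 * bxr1
    # xr2
    inf[10] = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau[10] = axr2 * bxr2
    # xs
    inf[11] = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tau[11] = axs * bxs + 80.0


@njit(cache=True)
def myocyte_rhs_kernel(s, p, istim, igap, ds, cur, inf, tau):
    """Time derivatives of the full myocyte state.

    istim, igap in pA/pF follow the membrane-equation sign convention
    dV/dt = -(I_ion + I_stim + I_gap): positive values repolarize, a
    depolarizing stimulus is negative.  Buffered calcium derivatives use
    the instantaneous-buffer chain-rule form equivalent to the TP06
    algebraic update.
    """
    myocyte_currents_kernel(s, p, cur)
    myocyte_gate_rates(s[IV], s[ICASS], p, inf, tau)

    iion = (
        cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
        + cur[6] + cur[7] + cur[8] + cur[9] + cur[10] + cur[11]
    )
    ds[IV] = -(iion + istim + igap)

    for g in range(12):
        ds[IM + g] = (inf[g] - s[IM + g]) / tau[g]

    cai = s[ICAI]
    casr = s[ICASR]
    cass = s[ICASS]

    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    ds[IRR] = K4 * (1.0 - s[IRR]) - k2 * cass * s[IRR]
    oo = k1 * cass * cass * s[IRR] / (K3 + k1 * cass * cass)

    irel = VREL * oo * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    bufsr_fac = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
    bufss_fac = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
    bufc_fac = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)

    ds[ICASR] = bufsr_fac * (iup - irel - ileak)
    ds[ICASS] = bufss_fac * (
        -ixfer * (VC / VSS) + irel * (VSR / VSS) - cur[5] / (2.0 * VSS * F) * CAPACITANCE
    )
    ds[ICAI] = bufc_fac * (
        -(cur[10] + cur[8] - 2.0 * cur[7]) / (2.0 * VC * F) * CAPACITANCE
        - (iup - ileak) * (VSR / VC)
        + ixfer
    )

    ds[INAI] = -(cur[0] + cur[11] + 3.0 * cur[6] + 3.0 * cur[7]) / (VC * F) * CAPACITANCE
    ds[IKI] = -(istim + cur[2] + cur[1] + cur[3] + cur[4] - 2.0 * cur[6] + cur[9]) / (VC * F) * CAPACITANCE


@njit(cache=True)
def myocyte_step_kernel(s, p, dt, istim, igap, rl, ds, cur, inf, tau):
    """Advance one myocyte by dt: forward Euler, or Rush-Larsen for gates."""
    myocyte_rhs_kernel(s, p, istim, igap, ds, cur, inf, tau)
    if rl:
        s[IV] += dt * ds[IV]
        for g in range(12):
            s[IM + g] = inf[g] + (s[IM + g] - inf[g]) * np.exp(-dt / tau[g])
        for k in range(INAI, NVAR_M):
            if k != IRR:
                s[k] += dt * ds[k]
        # release gate: linear in RR at frozen CaSS, exact exponential update
        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / s[ICASR]) ** 2)
        k2 = K2P * kcasr
        rate = K4 + k2 * s[ICASS]
        rinf = K4 / rate
        s[IRR] = rinf + (s[IRR] - rinf) * np.exp(-dt * rate)
    else:
        for k in range(NVAR_M):
            s[k] += dt * ds[k]


@njit(cache=True)
def fibroblast_currents_kernel(s, p, out):
    """MacCannell fibroblast currents (pA/pF): I_Kv, I_K1, I_NaK, I_bNa.

    The kv_shift parameter offsets the voltage dependence of the I_Kv
    gating (both activation and inactivation), which is how the resting
    potential is retuned.
    """
    v = s[0]
    ek = RTONF * np.log(p[FKO] / p[FKI])
    ena = RTONF * np.log(p[FNAO] / p[FNAI])

    ikv = p[FG_KV] * s[1] * s[2] * (v - ek)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (v - ek + 100.0)) + np.exp(0.1 * (v - ek - 10.0))) / (
        1.0 + np.exp(-0.5 * (v - ek))
    )
    ik1 = p[FG_K1] * ak1 / (ak1 + bk1) * (v - ek)

    nai15 = p[FNAI] ** 1.5
    inak = (
        p[FP_NAK]
        * (p[FKO] / (p[FKO] + p[FKMK]))
        * (nai15 / (nai15 + p[FKMNA] ** 1.5))
        * (v + 150.0)
        / (v + 200.0)
    )

    ibna = p[FG_BNA] * (v - ena)

    out[0] = ikv
    out[1] = ik1
    out[2] = inak
    out[3] = ibna


@njit(cache=True)
def fibroblast_rhs_kernel(s, p, igap_pA, ds, cur):
    """Fibroblast derivatives; igap_pA is the junctional current entering
    the fibroblast in pA (positive depolarizes it when V_M > V_F)."""
    fibroblast_currents_kernel(s, p, cur)
    v = s[0]
    vs = v - p[FSHIFT]
    rinf = 1.0 / (1.0 + np.exp(-(vs + 20.0) / 11.0))
    taur = 20.3 + 138.0 * np.exp(-(((vs + 20.0) / 25.9) ** 2))
    sinf = 1.0 / (1.0 + np.exp((vs + 23.0) / 7.0))
    taus = 1574.0 + 5268.0 * np.exp(-(((vs + 23.0) / 22.7) ** 2))

    iion = cur[0] + cur[1] + cur[2] + cur[3]  # pA/pF
    ds[0] = -(iion - igap_pA / p[FC_F])
    ds[1] = (rinf - s[1]) / taur
    ds[2] = (sinf - s[2]) / taus


@njit(cache=True)
def fibroblast_step_kernel(s, p, dt, igap_pA, rl, ds, cur):
    fibroblast_rhs_kernel(s, p, igap_pA, ds, cur)
    if rl:
        s[0] += dt * ds[0]
        vs = s[0] - p[FSHIFT]
        rinf = 1.0 / (1.0 + np.exp(-(vs + 20.0) / 11.0))
        taur = 20.3 + 138.0 * np.exp(-(((vs + 20.0) / 25.9) ** 2))
        sinf = 1.0 / (1.0 + np.exp((vs + 23.0) / 7.0))
        taus = 1574.0 + 5268.0 * np.exp(-(((vs + 23.0) / 22.7) ** 2))
        s[1] = rinf + (s[1] - rinf) * np.exp(-dt / taur)
        s[2] = sinf + (s[2] - sinf) * np.exp(-dt / taus)
    else:
        s[0] += dt * ds[0]
        s[1] += dt * ds[1]
        s[2] += dt * ds[2]


@njit(cache=True)
def pace_unit_kernel(
    ms,
    fs,
    pm,
    pf,
    gs,
    nfib,
    cm_tot,
    dt,
    nsteps,
    t0,
    stim_amp,
    cl,
    stim_dur,
    stim_t_end,
    rl,
    rec_stride,
    vm_out,
    vf_out,
    ical_out,
    imtof_out,
):
    """Paced 0D myocyte + representative fibroblast integration.

    stim_amp > 0 is a depolarizing stimulus in pA/pF applied for stim_dur
    at every multiple of cl until stim_t_end.  The myocyte junctional load
    is nfib * gs * (V_M - V_F) pA, normalized by cm_tot (pF); each
    fibroblast of the cluster receives gs * (V_M - V_F) pA.  Returns the
    step index of an integration blow-up (|V| > 200 mV), or -1.
    """
    ds = np.empty(NVAR_M)
    cur = np.empty(N_CURRENTS)
    inf = np.empty(12)
    tau = np.empty(12)
    dsf = np.empty(NVAR_F)
    curf = np.empty(4)
    nrec = vm_out.shape[0]
    for n in range(nsteps):
        t = t0 + n * dt
        istim = 0.0
        if t < stim_t_end and (t % cl) < stim_dur:
            istim = -stim_amp
        igap_pA = gs * (ms[IV] - fs[0])  # per fibroblast, pA
        if n % rec_stride == 0:
            k = n // rec_stride
            if k < nrec:
                vm_out[k] = ms[IV]
                vf_out[k] = fs[0]
                myocyte_currents_kernel(ms, pm, cur)
                ical_out[k] = cur[5]
                imtof_out[k] = nfib * igap_pA
        igap_m = nfib * igap_pA / cm_tot  # pA/pF on the myocyte
        myocyte_step_kernel(ms, pm, dt, istim, igap_m, rl, ds, cur, inf, tau)
        if gs > 0.0 or nfib > 0:
            fibroblast_step_kernel(fs, pf, dt, igap_pA, rl, dsf, curf)
        if np.abs(ms[IV]) > 200.0:
            return n
    return -1


@njit(cache=True)
def relax_fibroblast_kernel(fs, pf, dt, max_steps, tol):
    """Integrate an uncoupled fibroblast until max |ds| < tol.

    Returns (converged, steps used)."""
    ds = np.empty(NVAR_F)
    cur = np.empty(4)
    for n in range(max_steps):
        fibroblast_rhs_kernel(fs, pf, 0.0, ds, cur)
        m = 0.0
        for k in range(NVAR_F):
            a = np.abs(ds[k])
            if a > m:
                m = a
            fs[k] += dt * ds[k]
        if m < tol:
            return True, n
    return False, max_steps


# ------------------------------------------------------------------
# Voltage-indexed lookup tables for the tissue kernel.  The 2D stepper
# replaces every voltage-dependent transcendental with a linearly
# interpolated table at 0.05 mV resolution (interpolation error ~1e-6
# relative), the standard acceleration for explicit monodomain codes.
# The 0D/API path keeps exact evaluation.
TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.05
TAB_NV = int(round((TAB_VMAX - TAB_VMIN) / TAB_DV)) + 1
# u = V - E_K axis for the inward-rectifier factor
TAB_UMIN = -80.0
TAB_UMAX = 220.0
TAB_NU = int(round((TAB_UMAX - TAB_UMIN) / TAB_DV)) + 1

# myocyte table columns: 11 voltage gates x (inf, exp(-dt/tau)) then
# current factors
TC_NAK = 22      # I_NaK voltage factor
TC_NCX1 = 23     # exp(gamma V F/RT)
TC_NCX2 = 24     # exp((gamma-1) V F/RT)
TC_CALA = 25     # I_CaL: coefficient of 0.25*Ca_SS
TC_CALB = 26     # I_CaL: coefficient of Ca_o
TC_PK = 27       # I_pK voltage factor
NT_MYO = 28
# gate order in the tables (fCass excluded; it depends on Ca_SS and has
# no transcendental): m h j d f f2 r s xr1 xr2 xs
TAB_GATE_STATE_IDX = np.array([IM, IH, IJ, ID, IF, IF2, IR, IS, IXR1, IXR2, IXS], dtype=np.int64)


@njit(cache=True)
def build_myocyte_tables(p, dt):
    tv = np.empty((TAB_NV, NT_MYO))
    tu = np.empty(TAB_NU)
    inf = np.empty(12)
    tau = np.empty(12)
    for k in range(TAB_NV):
        v = TAB_VMIN + k * TAB_DV
        myocyte_gate_rates(v, 0.0002, p, inf, tau)
        col = 0
        for g in range(12):
            if g == 6:  # fCass handled analytically
                continue
            tv[k, col] = inf[g]
            tv[k, col + 1] = np.exp(-dt / tau[g])
            col += 2
        tv[k, TC_NAK] = 1.0 / (
            1.0 + 0.1245 * np.exp(-0.1 * v * FONRT) + 0.0353 * np.exp(-v * FONRT)
        )
        tv[k, TC_NCX1] = np.exp(NCXGAMMA * v * FONRT)
        tv[k, TC_NCX2] = np.exp((NCXGAMMA - 1.0) * v * FONRT)
        z = 2.0 * (v - 15.0) * FONRT
        if np.abs(z) < 1e-7:
            tv[k, TC_CALA] = 2.0 * F
            tv[k, TC_CALB] = 2.0 * F
        else:
            ez = np.exp(z)
            base = 4.0 * (v - 15.0) * F * FONRT / (ez - 1.0)
            tv[k, TC_CALA] = base * ez
            tv[k, TC_CALB] = base
        tv[k, TC_PK] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))
    for k in range(TAB_NU):
        u = TAB_UMIN + k * TAB_DV
        ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
        bk1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (
            1.0 + np.exp(-0.5 * u)
        )
        tu[k] = ak1 / (ak1 + bk1)
    return tv, tu


@njit(cache=True)
def build_fibroblast_tables(p, dt):
    """Columns: r_inf, exp(-dt/tau_r), s_inf, exp(-dt/tau_s) over V (with
    the kv_shift folded in)."""
    tf = np.empty((TAB_NV, 4))
    for k in range(TAB_NV):
        v = TAB_VMIN + k * TAB_DV
        vs = v - p[FSHIFT]
        rinf = 1.0 / (1.0 + np.exp(-(vs + 20.0) / 11.0))
        taur = 20.3 + 138.0 * np.exp(-(((vs + 20.0) / 25.9) ** 2))
        sinf = 1.0 / (1.0 + np.exp((vs + 23.0) / 7.0))
        taus = 1574.0 + 5268.0 * np.exp(-(((vs + 23.0) / 22.7) ** 2))
        tf[k, 0] = rinf
        tf[k, 1] = np.exp(-dt / taur)
        tf[k, 2] = sinf
        tf[k, 3] = np.exp(-dt / taus)
    return tf


@njit(inline="always")
def _tab_frac(v, vmin, n):
    idx = (v - vmin) / TAB_DV
    if idx < 0.0:
        idx = 0.0
    elif idx > n - 2:
        idx = float(n - 2)
    i0 = int(idx)
    return i0, idx - i0


@njit(cache=True)
def myocyte_step_tab(s, p, dt, istim, igap, tv, tu):
    """Table-accelerated myocyte step: Euler for V/concentrations,
    Rush-Larsen for gates.  Matches the exact path to table-interpolation
    accuracy (~1e-6)."""
    v = s[IV]
    nai = s[INAI]
    ki = s[IKI]
    cai = s[ICAI]
    casr = s[ICASR]
    cass = s[ICASS]
    ko = p[PKO]
    nao = p[PNAO]
    cao = p[PCAO]

    i0, w = _tab_frac(v, TAB_VMIN, TAB_NV)

    ena = RTONF * np.log(nao / nai)
    ek = RTONF * np.log(ko / ki)
    eks = RTONF * np.log((ko + PKNA * nao) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * np.log(cao / cai)

    ina = p[PG_NA] * s[IM] ** 3 * s[IH] * s[IJ] * (v - ena)
    ito = p[PG_TO] * s[IR] * s[IS] * (v - ek)

    j0, wu = _tab_frac(v - ek, TAB_UMIN, TAB_NU)
    rec = tu[j0] + wu * (tu[j0 + 1] - tu[j0])
    ik1 = p[PG_K1] * rec * (v - ek)

    ikr = p[PY] * p[PG_KR] * np.sqrt(ko / 5.4) * s[IXR1] * s[IXR2] * (v - ek)
    iks = p[PG_KS] * s[IXS] * s[IXS] * (v - eks)

    gcal = p[PEAD] * p[PX] * p[PG_CAL]
    ca_a = tv[i0, TC_CALA] + w * (tv[i0 + 1, TC_CALA] - tv[i0, TC_CALA])
    ca_b = tv[i0, TC_CALB] + w * (tv[i0 + 1, TC_CALB] - tv[i0, TC_CALB])
    gate = s[ID] * s[IF] * s[IF2] * s[IFCASS]
    ical = gcal * gate * (ca_a * 0.25 * cass - ca_b * cao)

    fnak = tv[i0, TC_NAK] + w * (tv[i0 + 1, TC_NAK] - tv[i0, TC_NAK])
    inak = p[PP_NAK] * (ko / (ko + KMK)) * (nai / (nai + KMNA)) * fnak

    e1 = tv[i0, TC_NCX1] + w * (tv[i0 + 1, TC_NCX1] - tv[i0, TC_NCX1])
    e2 = tv[i0, TC_NCX2] + w * (tv[i0 + 1, TC_NCX2] - tv[i0, TC_NCX2])
    inaca = (
        p[PK_NACA]
        * (e1 * nai ** 3 * cao - e2 * nao ** 3 * cai * 2.5)
        / ((KMNAI ** 3 + nao ** 3) * (KMCA + cao) * (1.0 + KSAT * e2))
    )

    ipca = p[PG_PCA] * cai / (cai + KPCA)
    fpk = tv[i0, TC_PK] + w * (tv[i0 + 1, TC_PK] - tv[i0, TC_PK])
    ipk = p[PG_PK] * fpk * (v - ek)
    ibca = p[PG_BCA] * (v - eca)
    ibna = p[PG_BNA] * (v - ena)

    iion = ina + ito + ik1 + ikr + iks + ical + inak + inaca + ipca + ipk + ibca + ibna
    s[IV] = v + dt * (-(iion + istim + igap))

    # Rush-Larsen gate updates from the tables
    col = 0
    for g in range(11):
        gi = TAB_GATE_STATE_IDX[g]
        ginf = tv[i0, col] + w * (tv[i0 + 1, col] - tv[i0, col])
        gef = tv[i0, col + 1] + w * (tv[i0 + 1, col + 1] - tv[i0, col + 1])
        s[gi] = ginf + (s[gi] - ginf) * gef
        col += 2
    # fCass (depends on subspace calcium only)
    fci = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    fct = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    s[IFCASS] = fci + (s[IFCASS] - fci) * np.exp(-dt / fct)

    # calcium subsystem + concentrations (forward Euler, chain-rule buffers)
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    rate = K4 + k2 * cass
    rinf = K4 / rate
    s[IRR] = rinf + (s[IRR] - rinf) * np.exp(-dt * rate)
    oo = k1 * cass * cass * s[IRR] / (K3 + k1 * cass * cass)
    irel = VREL * oo * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)
    bufsr_fac = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
    bufss_fac = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
    bufc_fac = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
    s[ICASR] = casr + dt * bufsr_fac * (iup - irel - ileak)
    s[ICASS] = cass + dt * bufss_fac * (
        -ixfer * (VC / VSS) + irel * (VSR / VSS) - ical / (2.0 * VSS * F) * CAPACITANCE
    )
    s[ICAI] = cai + dt * bufc_fac * (
        -(ibca + ipca - 2.0 * inaca) / (2.0 * VC * F) * CAPACITANCE
        - (iup - ileak) * (VSR / VC)
        + ixfer
    )
    s[INAI] = nai + dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca) / (VC * F) * CAPACITANCE)
    s[IKI] = ki + dt * (
        -(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) / (VC * F) * CAPACITANCE
    )


@njit(cache=True)
def fibroblast_step_tab(s, p, dt, igap_pA, tf, tu):
    v = s[0]
    ek = RTONF * np.log(p[FKO] / p[FKI])
    ena = RTONF * np.log(p[FNAO] / p[FNAI])
    ikv = p[FG_KV] * s[1] * s[2] * (v - ek)
    j0, wu = _tab_frac(v - ek, TAB_UMIN, TAB_NU)
    rec = tu[j0] + wu * (tu[j0 + 1] - tu[j0])
    ik1 = p[FG_K1] * rec * (v - ek)
    nai15 = p[FNAI] ** 1.5
    inak = (
        p[FP_NAK]
        * (p[FKO] / (p[FKO] + p[FKMK]))
        * (nai15 / (nai15 + p[FKMNA] ** 1.5))
        * (v + 150.0)
        / (v + 200.0)
    )
    ibna = p[FG_BNA] * (v - ena)
    s[0] = v + dt * (-(ikv + ik1 + inak + ibna - igap_pA / p[FC_F]))
    i0, w = _tab_frac(v, TAB_VMIN, TAB_NV)
    rinf = tf[i0, 0] + w * (tf[i0 + 1, 0] - tf[i0, 0])
    ref = tf[i0, 1] + w * (tf[i0 + 1, 1] - tf[i0, 1])
    sinf = tf[i0, 2] + w * (tf[i0 + 1, 2] - tf[i0, 2])
    sef = tf[i0, 3] + w * (tf[i0 + 1, 3] - tf[i0, 3])
    s[1] = rinf + (s[1] - rinf) * ref
    s[2] = sinf + (s[2] - sinf) * sef


@njit(cache=True)
def advance_tissue_kernel(
    myo,
    fib,
    mask,
    pm,
    pf,
    gs,
    nfib,
    cm_tot,
    dcoef,
    dx,
    dt,
    nsteps,
    step0,
    tv,             # myocyte voltage tables
    tu,             # inward-rectifier factor table (shared)
    tf,             # fibroblast gate tables
    stim_spec,      # (K, 7): r0, r1, c0, c1, amp(pA/pF, >0 depol), t_on, t_off
    frame_stride,
    frame_offset,
    frames_v,
    frames_ca,
    frames_na,
    probe_idx,      # (P, 2) int
    probe_stride,
    probe_offset,
    probes_v,
    act_count,
    ready,
    events,         # (E, 3) float: t, row, col of re-activation events
    n_events_in,
):
    """Advance the 2D monodomain lattice by nsteps forward-Euler steps.

    mask: 0 = myocyte node, 1 = fibroblast-cluster node.  Diffusion uses a
    five-point stencil over myocyte nodes only; fibroblast nodes and the
    outer edges are no-flux (mirror) boundaries.  Fibroblast clusters
    exchange gap-junctional current with each von-Neumann myocyte
    neighbour, nfib identical fibroblasts per cluster.

    Records voltage / L-type-gate / Na-gate frames and probe traces at the
    given strides (global step counter step0+n controls alignment), tracks
    per-node activation counts for ectopic detection and appends
    re-activation events (time, row, col).  Returns (blowup_step, n_events).
    blowup_step is -1 if stable.
    """
    L0 = mask.shape[0]
    L1 = mask.shape[1]
    vold = np.empty((L0, L1))
    alpha = dcoef * dt / (dx * dx)
    nstim = stim_spec.shape[0]
    nframes = frames_v.shape[0]
    nprobe_samples = probes_v.shape[0]
    nprobes = probe_idx.shape[0]
    max_events = events.shape[0]
    n_events = n_events_in
    blowup = -1

    for n in range(nsteps):
        gstep = step0 + n
        t = gstep * dt

        # snapshot voltages for the explicit diffusion / coupling update
        for i in range(L0):
            for j in range(L1):
                if mask[i, j] == 0:
                    vold[i, j] = myo[i, j, IV]
                else:
                    vold[i, j] = fib[i, j, 0]

        # recorders
        if frame_stride > 0 and gstep % frame_stride == 0:
            k = gstep // frame_stride - frame_offset
            if 0 <= k < nframes:
                for i in range(L0):
                    for j in range(L1):
                        if mask[i, j] == 0:
                            frames_v[k, i, j] = myo[i, j, IV]
                            frames_ca[k, i, j] = (
                                myo[i, j, ID] * myo[i, j, IF] * myo[i, j, IF2] * myo[i, j, IFCASS]
                            )
                            frames_na[k, i, j] = myo[i, j, IM] ** 3 * myo[i, j, IH] * myo[i, j, IJ]
                        else:
                            frames_v[k, i, j] = fib[i, j, 0]
                            frames_ca[k, i, j] = 0.0
                            frames_na[k, i, j] = 0.0
        if probe_stride > 0 and gstep % probe_stride == 0:
            k = gstep // probe_stride - probe_offset
            if 0 <= k < nprobe_samples:
                for q in range(nprobes):
                    pi = probe_idx[q, 0]
                    pj = probe_idx[q, 1]
                    if mask[pi, pj] == 0:
                        probes_v[k, q] = myo[pi, pj, IV]
                    else:
                        probes_v[k, q] = fib[pi, pj, 0]

        for i in range(L0):
            for j in range(L1):
                if mask[i, j] == 0:
                    v = vold[i, j]
                    # five-point Laplacian, mirror at edges and at
                    # fibroblast obstacles; gap current from fibroblast
                    # neighbours
                    lap = 0.0
                    igap = 0.0
                    # up
                    if i > 0:
                        if mask[i - 1, j] == 0:
                            lap += vold[i - 1, j] - v
                        else:
                            igap += nfib * gs * (v - vold[i - 1, j])
                    if i < L0 - 1:
                        if mask[i + 1, j] == 0:
                            lap += vold[i + 1, j] - v
                        else:
                            igap += nfib * gs * (v - vold[i + 1, j])
                    if j > 0:
                        if mask[i, j - 1] == 0:
                            lap += vold[i, j - 1] - v
                        else:
                            igap += nfib * gs * (v - vold[i, j - 1])
                    if j < L1 - 1:
                        if mask[i, j + 1] == 0:
                            lap += vold[i, j + 1] - v
                        else:
                            igap += nfib * gs * (v - vold[i, j + 1])

                    istim = 0.0
                    inside_stim = False
                    for q in range(nstim):
                        if (
                            t >= stim_spec[q, 5]
                            and t < stim_spec[q, 6]
                            and i >= stim_spec[q, 0]
                            and i < stim_spec[q, 1]
                            and j >= stim_spec[q, 2]
                            and j < stim_spec[q, 3]
                        ):
                            istim -= stim_spec[q, 4]
                            inside_stim = True

                    myocyte_step_tab(myo[i, j], pm, dt, istim, igap / cm_tot, tv, tu)
                    vnew = myo[i, j, IV] + alpha * lap
                    myo[i, j, IV] = vnew

                    if np.abs(vnew) > 200.0 and blowup < 0:
                        blowup = gstep

                    # activation bookkeeping for ectopic detection
                    if vnew < -70.0:
                        ready[i, j] = 1
                    elif ready[i, j] == 1 and vnew > -20.0:
                        ready[i, j] = 0
                        act_count[i, j] += 1
                        if act_count[i, j] >= 2 and not inside_stim and n_events < max_events:
                            events[n_events, 0] = t
                            events[n_events, 1] = i
                            events[n_events, 2] = j
                            n_events += 1
                else:
                    vf = vold[i, j]
                    igap_f = 0.0  # pA entering one fibroblast of the cluster
                    if i > 0 and mask[i - 1, j] == 0:
                        igap_f += gs * (vold[i - 1, j] - vf)
                    if i < L0 - 1 and mask[i + 1, j] == 0:
                        igap_f += gs * (vold[i + 1, j] - vf)
                    if j > 0 and mask[i, j - 1] == 0:
                        igap_f += gs * (vold[i, j - 1] - vf)
                    if j < L1 - 1 and mask[i, j + 1] == 0:
                        igap_f += gs * (vold[i, j + 1] - vf)
                    fibroblast_step_tab(fib[i, j], pf, dt, igap_f, tf, tu)

    return blowup, n_events
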