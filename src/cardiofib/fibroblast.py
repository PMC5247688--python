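"""MacCannell "active" fibroblast model with resting-potential calibration.

The model carries four membrane currents: a time- and voltage-dependent
K+ current I_fKv (activation gate r, inactivation gate s), an inwardly
rectifying K+ current I_fK1, an Na+/K+ pump current I_fNaK and a
background sodium current I_bNa.  Intracellular concentrations are fixed.
The uncoupled model relaxes to about -49.6 mV; a common voltage offset
``kv_shift`` applied to the I_fKv gating voltage dependence retunes the
resting potential, which is how the depolarized -24.5 mV profile is
produced.

Two phenotypes differ only in whole-cell capacitance: "fibroblast"
(C_F = 6.3 pF) and "myofibroblast" (C_F = 50 pF).  Capacitance rescales
the membrane time constant but not the resting fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from cardiofib import _kernels as K

CURRENT_NAMES = ("I_fKv", "I_fK1", "I_fNaK", "I_bNa")


@dataclass
class FibroblastParams:
    """Fibroblast membrane parameters.

    Conductances in nS/pF, pump maximum in pA/pF, C_F in pF (whole cell),
    concentrations mM.  ``kv_shift`` (mV) offsets the I_fKv gating voltage
    dependence; ``V_FR_target`` is the nominal resting-potential label of
    the profile (-49.7 or -24.5 mV in the shipped profiles).
    """

    C_F: float = 6.3
    g_Kv: float = 0.25
    g_K1: float = 0.4822
    g_bNa: float = 0.0095
    P_NaK: float = 2.002
    K_mK: float = 1.0
    K_mNa: float = 10.0
    kv_shift: float = 0.0
    V_FR_target: float = -49.7
    K_o: float = 5.4
    Na_o: float = 130.011
    K_i: float = 129.4349
    Na_i: float = 8.5547

    def to_array(self) -> np.ndarray:
        p = np.empty(K.NPAR_F)
        p[K.FC_F] = self.C_F
        p[K.FG_KV] = self.g_Kv
        p[K.FG_K1] = self.g_K1
        p[K.FG_BNA] = self.g_bNa
        p[K.FP_NAK] = self.P_NaK
        p[K.FSHIFT] = self.kv_shift
        p[K.FKO] = self.K_o
        p[K.FNAO] = self.Na_o
        p[K.FKI] = self.K_i
        p[K.FNAI] = self.Na_i
        p[K.FKMK] = self.K_mK
        p[K.FKMNA] = self.K_mNa
        return p

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "FibroblastParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


def initial_fibroblast_state(params: FibroblastParams | None = None) -> np.ndarray:
    """Initial conditions: V_F at the nominal uncoupled rest, gates at
    their steady state for that voltage."""
    v0 = -49.6
    shift = 0.0 if params is None else params.kv_shift
    vs = v0 - shift
    r0 = 1.0 / (1.0 + np.exp(-(vs + 20.0) / 11.0))
    s0 = 1.0 / (1.0 + np.exp((vs + 23.0) / 7.0))
    return np.array([v0, r0, s0])


def _check_state(state: np.ndarray) -> None:
    if not np.all(np.isfinite(state)):
        raise ValueError("invalid fibroblast state: non-finite component")


def fibroblast_currents(state: np.ndarray, params: FibroblastParams) -> dict:
    """Membrane currents in pA/pF."""
    _check_state(state)
    out = np.empty(4)
    K.fibroblast_currents_kernel(np.asarray(state, dtype=float), params.to_array(), out)
    return dict(zip(CURRENT_NAMES, out))


def fibroblast_rhs(state: np.ndarray, params: FibroblastParams, I_gap: float = 0.0) -> np.ndarray:
    """d(state)/dt for (V_F, r, s); I_gap in pA entering the fibroblast
    (positive depolarizes it when V_M > V_F)."""
    _check_state(state)
    ds = np.empty(K.NVAR_F)
    cur = np.empty(4)
    K.fibroblast_rhs_kernel(np.asarray(state, dtype=float), params.to_array(), I_gap, ds, cur)
    return ds


def resting_potential(
    params: FibroblastParams,
    dt: float = 0.1,
    tol: float = 1e-8,
    t_max_ms: float = 60000.0,
) -> tuple[float, bool]:
    """Relax the uncoupled fibroblast to its fixed point.

    Returns (V_F in mV, converged flag); converged means max |d state/dt|
    fell below ``tol`` within ``t_max_ms`` of simulated time.
    """
    s = initial_fibroblast_state(params)
    converged, _ = K.relax_fibroblast_kernel(s, params.to_array(), dt, int(t_max_ms / dt), tol)
    return float(s[0]), bool(converged)


def calibrate_kv_shift(
    target_VFR: float,
    params: FibroblastParams | None = None,
    bracket: tuple[float, float] = (-30.0, 50.0),
    tol: float = 0.1,
) -> float:
    """Find the kv_shift for which the uncoupled resting potential equals
    ``target_VFR`` (mV) to within ``tol``, by scalar root finding on the
    given bracket.  Depolarized targets need positive shifts (the Kv
    current deactivates at rest).

    The default bracket is the interval on which the resting potential is
    monotone in the shift; below about -35 mV the Kv inactivation gate
    takes over and the fixed point jumps to a depolarized branch.
    """
    if not (-60.0 < target_VFR < -10.0):
        raise ValueError("target resting potential outside supported range (-60, -10) mV")
    base = params if params is not None else FibroblastParams()

    def err(shift: float) -> float:
        v, _ = resting_potential(replace(base, kv_shift=shift))
        return v - target_VFR

    lo, hi = bracket
    elo, ehi = err(lo), err(hi)
    if elo * ehi > 0:
        raise ValueError(f"target {target_VFR} mV not bracketed by kv_shift in {bracket}")
    return float(brentq(err, lo, hi, xtol=tol / 4.0))
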