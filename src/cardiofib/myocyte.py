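"""Human ventricular myocyte model (TP06, epicardial) with EAD modifications.

The model is the 2006 ten Tusscher-Panfilov formulation with the epicardial
parameter set.  Two modifications enable early afterdepolarizations: the
time constant of the L-type calcium f-gate is halved (``tau_f_scale``) and
the base maximal L-type conductance is doubled (``g_cal_ead_scale``).  On
top of that, two dimensionless sweep multipliers scale the conductances
that control EAD onset: ``x`` on G_CaL and ``y`` on G_Kr, so the effective
conductances are ``g_cal_ead_scale * x * g_CaL`` and ``y * g_Kr``.

Units: voltage mV, time ms, currents pA/pF, concentrations mM.  A
depolarizing stimulus of amplitude A (pA/pF) enters the membrane equation
as I_stim = -A, i.e. dV/dt = -(I_ion + I_stim + I_gap).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from cardiofib import _kernels as K

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s", "xr1", "xr2", "xs",
    "Na_i", "K_i", "Ca_i", "Ca_SR", "Ca_SS", "R_rel",
)

CURRENT_NAMES = (
    "I_Na", "I_to", "I_K1", "I_Kr", "I_Ks", "I_CaL",
    "I_NaK", "I_NaCa", "I_pCa", "I_pK", "I_bCa", "I_bNa",
)


@dataclass
class MyocyteParams:
    """TP06 epicardial maximal conductances and the EAD/sweep multipliers.

    Conductances in nS/pF except ``g_CaL`` (cm^3 uF^-1 s^-1 convention of
    the source model), pump/exchanger maxima in pA/pF.  ``C_m_total`` is
    the whole-cell capacitance (pF) used to normalize gap-junctional pA
    into pA/pF.
    """

    g_Na: float = 14.838
    g_CaL: float = 3.980e-5
    g_to: float = 0.294
    g_Kr: float = 0.153
    g_Ks: float = 0.392
    g_K1: float = 5.405
    g_pCa: float = 0.1238
    g_pK: float = 0.0146
    g_bNa: float = 0.00029
    g_bCa: float = 0.000592
    P_NaK: float = 2.724
    k_NaCa: float = 1000.0
    x: float = 1.0
    y: float = 1.0
    tau_f_scale: float = 0.5
    g_cal_ead_scale: float = 2.0
    K_o: float = 5.4
    Na_o: float = 140.0
    Ca_o: float = 2.0
    C_m_total: float = 185.0

    def __post_init__(self):
        if not self.x > 0:
            raise ValueError("x must be positive")
        if self.y < 0:
            raise ValueError("y must be non-negative")

    def to_array(self) -> np.ndarray:
        p = np.empty(K.NPAR_M)
        p[K.PG_NA] = self.g_Na
        p[K.PG_CAL] = self.g_CaL
        p[K.PG_TO] = self.g_to
        p[K.PG_KR] = self.g_Kr
        p[K.PG_KS] = self.g_Ks
        p[K.PG_K1] = self.g_K1
        p[K.PG_PCA] = self.g_pCa
        p[K.PG_PK] = self.g_pK
        p[K.PG_BNA] = self.g_bNa
        p[K.PG_BCA] = self.g_bCa
        p[K.PP_NAK] = self.P_NaK
        p[K.PK_NACA] = self.k_NaCa
        p[K.PX] = self.x
        p[K.PY] = self.y
        p[K.PTAUF] = self.tau_f_scale
        p[K.PEAD] = self.g_cal_ead_scale
        p[K.PKO] = self.K_o
        p[K.PNAO] = self.Na_o
        p[K.PCAO] = self.Ca_o
        return p

    def with_xy(self, x: float | None = None, y: float | None = None) -> "MyocyteParams":
        kw = {}
        if x is not None:
            kw["x"] = x
        if y is not None:
            kw["y"] = y
        return replace(self, **kw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "MyocyteParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


def initial_myocyte_state() -> np.ndarray:
    """Source-model resting initial conditions (packed state vector)."""
    s = np.empty(K.NVAR_M)
    s[K.IV] = -86.2
    s[K.IM] = 0.0
    s[K.IH] = 0.75
    s[K.IJ] = 0.75
    s[K.ID] = 0.0
    s[K.IF] = 1.0
    s[K.IF2] = 1.0
    s[K.IFCASS] = 1.0
    s[K.IR] = 0.0
    s[K.IS] = 1.0
    s[K.IXR1] = 0.0
    s[K.IXR2] = 1.0
    s[K.IXS] = 0.0
    s[K.INAI] = 7.67
    s[K.IKI] = 138.3
    s[K.ICAI] = 0.00007
    s[K.ICASR] = 1.3
    s[K.ICASS] = 0.00007
    s[K.IRR] = 1.0
    return s


def _check_state(state: np.ndarray) -> None:
    if not np.all(np.isfinite(state)):
        raise ValueError("invalid myocyte state: non-finite component")


def myocyte_currents(state: np.ndarray, params: MyocyteParams) -> dict:
    """All twelve membrane currents (pA/pF), with the EAD modifications
    and sweep multipliers applied."""
    _check_state(state)
    out = np.empty(K.N_CURRENTS)
    K.myocyte_currents_kernel(np.asarray(state, dtype=float), params.to_array(), out)
    return dict(zip(CURRENT_NAMES, out))


def myocyte_rhs(
    state: np.ndarray,
    params: MyocyteParams,
    I_stim: float = 0.0,
    I_gap: float = 0.0,
) -> np.ndarray:
    """d(state)/dt; I_stim and I_gap in pA/pF (positive = repolarizing)."""
    _check_state(state)
    ds = np.empty(K.NVAR_M)
    cur = np.empty(K.N_CURRENTS)
    inf = np.empty(12)
    tau = np.empty(12)
    K.myocyte_rhs_kernel(
        np.asarray(state, dtype=float), params.to_array(), I_stim, I_gap, ds, cur, inf, tau
    )
    return ds


class IntegrationBlowupError(RuntimeError):
    """Raised when |V| exceeds 200 mV; carries the simulated time (ms)."""

    def __init__(self, t_ms: float):
        self.t_ms = t_ms
        super().__init__(f"integration blow-up at t = {t_ms:g} ms")


def step_cell(
    state: np.ndarray,
    params: MyocyteParams,
    dt: float,
    I_stim: float = 0.0,
    I_gap: float = 0.0,
    rush_larsen: bool = True,
) -> np.ndarray:
    """One explicit step of the myocyte; returns the new state.

    The voltage and concentrations advance by forward Euler; the gates
    use the exponential (Rush-Larsen) rule by default, as in the source
    model's own explicit integrator -- the sodium activation gate's time
    constant is far below any practical dt, so a plain-Euler gate update
    (``rush_larsen=False``) is only usable for tiny dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_state(state)
    s = np.array(state, dtype=float)
    ds = np.empty(K.NVAR_M)
    cur = np.empty(K.N_CURRENTS)
    inf = np.empty(12)
    tau = np.empty(12)
    K.myocyte_step_kernel(s, params.to_array(), dt, I_stim, I_gap, rush_larsen, ds, cur, inf, tau)
    if abs(s[K.IV]) > 200.0:
        raise IntegrationBlowupError(dt)
    return s


def relax_myocyte(
    params: MyocyteParams,
    t_ms: float = 10000.0,
    dt: float = 0.02,
    state: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate the unstimulated myocyte for ``t_ms`` to approach its
    resting fixed point."""
    s = initial_myocyte_state() if state is None else np.array(state, dtype=float)
    fs = np.zeros(K.NVAR_F)
    fp = np.zeros(K.NPAR_F)
    fp[K.FC_F] = 1.0
    nsteps = int(round(t_ms / dt))
    dummy = np.empty(0, dtype=np.float32)
    blow = K.pace_unit_kernel(
        s, fs, params.to_array(), fp, 0.0, 0, params.C_m_total, dt, nsteps, 0.0,
        0.0, 1e30, 1.0, 0.0, True, nsteps + 1, dummy, dummy, dummy, dummy,
    )
    if blow >= 0:
        raise IntegrationBlowupError(blow * dt)
    return s
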