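"""0D unit: one myocyte gap-junctionally coupled to N identical fibroblasts.

The N fibroblasts of a cluster share parameters, coupling and initial
conditions, so their trajectories are identical: the unit integrates one
representative fibroblast and multiplies its junctional load on the
myocyte by N (exact reduction, verified in the tests by running all N
explicitly).  The junctional current per pair is the ohmic
I = Gs (V_M - V_F) in pA (Gs in nS); the myocyte-side load is divided by
the whole-cell myocyte capacitance (185 pF) to give pA/pF.

Also provides the per-beat action-potential metrics used throughout:
APD90, EAD counting, and the NO-EAD -> EAD transition boundary scan in
the G_CaL multiplier x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardiofib import _kernels as K
from cardiofib.myocyte import MyocyteParams, initial_myocyte_state, IntegrationBlowupError
from cardiofib.fibroblast import FibroblastParams, initial_fibroblast_state

# EAD detection thresholds (exposed here; see the methods note)
DELTA_V_EAD = 1.0        # mV secondary rise that counts as an EAD
V_PLATEAU_FLOOR = -40.0  # EADs are only counted while V is above this
V_REPOL_END = -70.0      # detection window ends when V first falls below


@dataclass
class CouplingConfig:
    """Gap-junction configuration: conductance per M-F pair and cluster size."""

    Gs: float = 0.0      # nS per myocyte-fibroblast pair
    N_fib: int = 5

    def __post_init__(self):
        if self.Gs < 0:
            raise ValueError("Gs must be non-negative")
        if self.N_fib < 0:
            raise ValueError("N_fib must be non-negative")


@dataclass
class Trace:
    """Uniformly sampled voltage trace of a 0D run (last beat or full run).

    I_MtoF is the total junctional current myocyte -> cluster in pA.
    """

    t: np.ndarray
    V_M: np.ndarray
    V_F: np.ndarray | None = None
    I_CaL: np.ndarray | None = None
    I_MtoF: np.ndarray | None = None
    cl: float = 500.0
    stim_onsets: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def gap_current(V_M: float, V_F: float, Gs: float) -> float:
    """Ohmic junctional current in pA (Gs in nS, voltages in mV); positive
    current leaves the myocyte and enters the fibroblast."""
    if not (np.isfinite(V_M) and np.isfinite(V_F) and np.isfinite(Gs)):
        raise ValueError("non-finite input to gap_current")
    return Gs * (V_M - V_F)


def pace_unit(
    m_params: MyocyteParams,
    f_params: FibroblastParams | None = None,
    coupling: CouplingConfig | None = None,
    n_beats: int = 10,
    cl: float = 500.0,
    stim_amp: float = 52.0,
    stim_dur: float = 2.0,
    dt: float = 0.02,
    rec_stride: int = 5,
    rush_larsen: bool = True,
    m_state: np.ndarray | None = None,
    f_state: np.ndarray | None = None,
    full_trace: bool = False,
) -> Trace:
    """Pace the coupled unit for ``n_beats`` at cycle length ``cl`` (ms).

    stim_amp > 0 is a depolarizing stimulus in pA/pF lasting ``stim_dur``
    ms at the start of each cycle.  Returns the trace of the last beat
    (or the whole run with ``full_trace=True``) sampled every
    ``rec_stride`` time steps.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    coupling = coupling or CouplingConfig()
    f_params = f_params or FibroblastParams()
    ms = initial_myocyte_state() if m_state is None else np.array(m_state, dtype=float)
    fs = initial_fibroblast_state(f_params) if f_state is None else np.array(f_state, dtype=float)

    t_end = n_beats * cl
    nsteps = int(round(t_end / dt))
    nrec = (nsteps - 1) // rec_stride + 1
    vm = np.empty(nrec, dtype=np.float32)
    vf = np.empty(nrec, dtype=np.float32)
    ical = np.empty(nrec, dtype=np.float32)
    imtof = np.empty(nrec, dtype=np.float32)

    blow = K.pace_unit_kernel(
        ms, fs, m_params.to_array(), f_params.to_array(),
        float(coupling.Gs), int(coupling.N_fib), float(m_params.C_m_total),
        dt, nsteps, 0.0, float(stim_amp), float(cl), float(stim_dur), float(t_end),
        rush_larsen, rec_stride, vm, vf, ical, imtof,
    )
    if blow >= 0:
        raise IntegrationBlowupError(blow * dt)

    t = np.arange(nrec) * (dt * rec_stride)
    onsets = np.arange(n_beats) * cl
    if not full_trace:
        i0 = int(round((n_beats - 1) * cl / (dt * rec_stride)))
        t, vm, vf, ical, imtof = t[i0:] - t[i0], vm[i0:], vf[i0:], ical[i0:], imtof[i0:]
        onsets = np.array([0.0])
    return Trace(
        t=t, V_M=vm.astype(float), V_F=vf.astype(float),
        I_CaL=ical.astype(float), I_MtoF=imtof.astype(float),
        cl=cl, stim_onsets=onsets,
        meta=dict(
            n_beats=n_beats, dt=dt, stim_amp=stim_amp, stim_dur=stim_dur,
            Gs=coupling.Gs, N_fib=coupling.N_fib, full_trace=full_trace,
            final_m_state=ms, final_f_state=fs,
        ),
    )


def apd90(trace: Trace) -> list[dict]:
    """Per-beat APD90 values.

    Activation = time of maximum dV/dt after each stimulus onset; the
    repolarization level is diastolic V just before that onset plus 10%
    of the beat amplitude.  Beats that never return to that level before
    the next onset are flagged ``unrepolarized`` with APD NaN.
    """
    t, v = trace.t, trace.V_M
    onsets = trace.stim_onsets
    if onsets is None:
        onsets = np.array([t[0]])
    dt = trace.dt
    out = []
    for b, t_on in enumerate(onsets):
        t_next = onsets[b + 1] if b + 1 < len(onsets) else t[-1] + dt
        i_on = int(np.searchsorted(t, t_on - 1e-9))
        i_next = int(np.searchsorted(t, t_next - 1e-9))
        seg = v[i_on:i_next]
        if len(seg) < 3:
            continue
        v_rest = v[max(i_on - 1, 0)]
        dv = np.diff(seg)
        i_act = int(np.argmax(dv))
        v_peak = float(np.max(seg))
        if v_peak - v_rest < 20.0:  # no upstroke captured
            out.append(dict(beat=b, apd90=np.nan, unrepolarized=False, captured=False,
                            v_rest=float(v_rest), v_max=v_peak))
            continue
        v90 = v_rest + 0.1 * (v_peak - v_rest)
        above = np.nonzero(seg[i_act:] > v90)[0]
        if len(above) == 0:
            continue
        i_up = i_act + int(above[0])
        below = np.nonzero(seg[i_up:] <= v90)[0]
        if len(below) == 0:
            out.append(dict(beat=b, apd90=np.nan, unrepolarized=True, captured=True,
                            v_rest=float(v_rest), v_max=v_peak))
        else:
            out.append(dict(beat=b, apd90=float((i_up - i_act + below[0]) * dt),
                            unrepolarized=False, captured=True,
                            v_rest=float(v_rest), v_max=v_peak))
    return out


def count_eads(
    trace: Trace,
    delta_v: float = DELTA_V_EAD,
    plateau_floor: float = V_PLATEAU_FLOOR,
    repol_end: float = V_REPOL_END,
    skip_ms: float = 50.0,
) -> int:
    """Number of secondary depolarizations on a single-beat trace.

    Counts local minima of V followed by a rise of at least ``delta_v``
    while V stays above ``plateau_floor``, between the primary upstroke
    and the first time V falls below ``repol_end``.  The first ``skip_ms``
    after the upstroke are excluded so that the epicardial spike-notch-
    dome morphology (notch within ~10 ms) is not mistaken for an EAD.
    """
    v = np.asarray(trace.V_M, dtype=float)
    if len(v) < 3:
        return 0
    i_act = int(np.argmax(np.diff(v))) + int(round(skip_ms / trace.dt))
    if i_act >= len(v) - 1:
        return 0
    below = np.nonzero(v[i_act:] < repol_end)[0]
    i_end = i_act + (int(below[0]) if len(below) else len(v) - i_act)
    seg = v[i_act:i_end]
    n = 0
    i = 1
    while i < len(seg) - 1:
        if seg[i] <= seg[i - 1] and seg[i] < seg[i + 1] and seg[i] > plateau_floor:
            # local minimum above the plateau floor; find the subsequent rise
            peak = seg[i]
            k = i + 1
            while k < len(seg) and seg[k] >= seg[k - 1]:
                peak = max(peak, seg[k])
                k += 1
            if peak - seg[i] >= delta_v:
                n += 1
            i = k
        else:
            i += 1
    return n


def ead_boundary_scan(
    y: float,
    Gs_values,
    f_params: FibroblastParams | None = None,
    x_range: tuple[float, float] = (1.0, 8.0),
    dx_scan: float = 0.05,
    m_params: MyocyteParams | None = None,
    n_fib: int = 1,
    n_beats: int = 20,
    check_beats: int = 5,
    coarse_step: float = 0.25,
    cl: float = 500.0,
    **pace_kw,
) -> dict:
    """Smallest x = G_CaL multiplier with >= 1 EAD near the end of the
    paced train, for each gap conductance in ``Gs_values`` at fixed
    y = G_Kr multiplier.

    The train is ``n_beats`` beats; EADs are counted on each of the last
    ``check_beats`` beats (EAD dynamics near threshold are beat-to-beat
    irregular, so a single-beat criterion is noisy).  Coarse scan at
    ``coarse_step`` followed by a fine linear scan at ``dx_scan`` inside
    the bracketing coarse interval: near threshold the EAD indicator is
    not monotone in x (chaotic alternans opens EAD-free islands above
    onset), so bisection would land on an arbitrary island edge; the
    linear scan deterministically returns the smallest x with an EAD at
    the requested resolution.  Returns {Gs: x*}; x* is NaN when no
    transition lies in ``x_range`` (open boundary).
    """
    base = (m_params or MyocyteParams()).with_xy(y=y)
    f_params = f_params or FibroblastParams()

    def has_ead(x: float, gs: float) -> bool:
        tr = pace_unit(base.with_xy(x=x), f_params, CouplingConfig(Gs=gs, N_fib=n_fib),
                       n_beats=n_beats, cl=cl, full_trace=True, **pace_kw)
        spb = int(round(cl / tr.dt))
        for b in range(max(0, n_beats - check_beats), n_beats):
            beat = Trace(t=tr.t[:spb], V_M=tr.V_M[b * spb:(b + 1) * spb])
            if count_eads(beat) >= 1:
                return True
        return False

    out = {}
    x_lo, x_hi = x_range
    for gs in Gs_values:
        lo, hi = None, None
        xs = np.arange(x_lo, x_hi + 1e-9, coarse_step)
        prev = x_lo
        for xv in xs:
            if has_ead(float(xv), gs):
                lo, hi = prev, float(xv)
                break
            prev = float(xv)
        if hi is None:
            out[gs] = float("nan")
            continue
        xstar = hi
        xv = lo + dx_scan
        while xv < hi - 1e-12:
            if has_ead(float(xv), gs):
                xstar = float(xv)
                break
            xv += dx_scan
        out[gs] = xstar
    return out
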