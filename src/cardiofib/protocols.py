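"""Stimulation protocols for the 2D studies.

P1: after pacing preconditioning of the (fibroblast-free) medium, a
single focal stimulus is applied over a 6-column x 200-row rectangle
placed slightly off the domain centre, and the fate of the resulting
wave is observed.  P2: an S1 plane wave is launched from the left edge;
once its front has crossed mid-domain, an S2 stimulus over the upper-left
quarter creates a free wave end that curls into a spiral.  A slow ramp of
the G_CaL multiplier x (steps of 0.25 every 4 s by default) carries the
spiral through the dynamical regimes.

All stimulus rectangles scale with the lattice side L; the paper-scale
geometry corresponds to L = 1024.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardiofib import _kernels as K
from cardiofib.myocyte import MyocyteParams, initial_myocyte_state
from cardiofib.tissue import Texture, TissueGrid, TissueSim, make_texture
from cardiofib.recording import Recording

STIM_AMP_DEFAULT = 52.0  # pA/pF, depolarizing; see the methods note on units
STIM_DUR_DEFAULT = 2.0   # ms


@dataclass
class StimulusSpec:
    """Rectangular stimulus: half-open region [r0, r1) x [c0, c1) in
    0-based (row, col) lattice coordinates."""

    r0: int
    r1: int
    c0: int
    c1: int
    amplitude: float = STIM_AMP_DEFAULT  # pA/pF, > 0 depolarizes
    duration: float = STIM_DUR_DEFAULT   # ms
    onset: float = 0.0                   # ms

    def validate(self, L: int) -> None:
        if not (0 <= self.r0 < self.r1 <= L and 0 <= self.c0 < self.c1 <= L):
            raise ValueError(f"stimulus region [{self.r0},{self.r1})x[{self.c0},{self.c1}) outside {L}x{L} grid")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    def to_row(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.c0, self.c1, self.amplitude,
                         self.onset, self.onset + self.duration], dtype=float)


def stimuli_to_array(stimuli, L: int) -> np.ndarray:
    rows = []
    for s in stimuli or []:
        if isinstance(s, StimulusSpec):
            s.validate(L)
            rows.append(s.to_row())
        else:
            rows.append(np.asarray(s, dtype=float))
    return np.vstack(rows) if rows else np.zeros((0, 7))


def p1_stimulus(L: int, amplitude: float = STIM_AMP_DEFAULT, onset: float = 0.0) -> StimulusSpec:
    """Focal P1 stimulus: 6 columns x 200 rows at paper scale (scaled with
    L), centred vertically, displaced +L/8 columns from the centre."""
    h = max(2, int(round(200 * L / 1024)))
    w = max(2, int(round(6 * L / 1024)) if L < 1024 else 6)
    w = max(w, 2)
    r0 = L // 2 - h // 2
    c0 = L // 2 + L // 8 - w // 2
    return StimulusSpec(r0=r0, r1=r0 + h, c0=c0, c1=c0 + w, amplitude=amplitude, onset=onset)


def s1_stimulus(L: int, onset: float = 0.0, amplitude: float = STIM_AMP_DEFAULT) -> StimulusSpec:
    """S1 plane-wave stimulus along the left edge (wave travels left to right)."""
    return StimulusSpec(r0=0, r1=L, c0=0, c1=max(2, L // 64), amplitude=amplitude, onset=onset)


def s2_stimulus(L: int, onset: float, amplitude: float = STIM_AMP_DEFAULT, mirrored: bool = False) -> StimulusSpec:
    """S2 over the first (upper-left) quarter of the domain; ``mirrored``
    uses the lower-left quarter instead (opposite chirality)."""
    if mirrored:
        return StimulusSpec(r0=L - L // 2, r1=L, c0=0, c1=L // 2, amplitude=amplitude, onset=onset)
    return StimulusSpec(r0=0, r1=L // 2, c0=0, c1=L // 2, amplitude=amplitude, onset=onset)


def precondition_p1(
    L: int,
    n_waves: int = 50,
    m_params: MyocyteParams | None = None,
    D: float | None = None,
    dt: float = 0.02,
    dx: float = 0.25,
    period_ms: float = 1000.0,
    tail_ms: float = 400.0,
) -> np.ndarray:
    """Pacing preconditioning: n plane waves at 1 Hz through a
    fibroblast-free medium at x = y = 1.  Returns the final myocyte state
    field (L, L, NVAR_M) used to initialize P1 runs.

    n_waves = 0 returns the source-model resting state at every node.
    """
    mp = (m_params or MyocyteParams()).with_xy(x=1.0, y=1.0)
    if n_waves == 0:
        return np.tile(initial_myocyte_state(), (L, L, 1))
    tex = make_texture(L, 0.0, seed=0)
    kw = {} if D is None else {"D": D}
    grid = TissueGrid(texture=tex, m_params=mp, dt=dt, dx=dx, **kw)
    sim = TissueSim(grid, frame_stride_ms=1e9, probe_stride_ms=1e9)
    stims = [s1_stimulus(L, onset=k * period_ms) for k in range(n_waves)]
    sim.advance((n_waves - 1) * period_ms + tail_ms, stimuli_to_array(stims, L))
    # let the last wave finish crossing and the medium fully repolarize
    # (conduction can be much slower than at paper scale when D is
    # rescaled, so a fixed tail is not enough)
    from cardiofib import _kernels as K

    extra = 0.0
    while np.any(grid.myo[:, :, K.IV] > -70.0) and extra < 8000.0:
        sim.advance(200.0)
        extra += 200.0
    return grid.myo.copy()


def run_p1(
    grid: TissueGrid,
    init: np.ndarray | None = None,
    t_end: float = 4000.0,
    frame_stride_ms: float = 10.0,
    probe_stride_ms: float = 1.0,
    stim_amp: float = STIM_AMP_DEFAULT,
) -> Recording:
    """Apply the off-centre focal stimulus to a preconditioned medium and
    record the outcome."""
    if init is not None:
        grid.set_myocyte_field(init)
    stim = p1_stimulus(grid.L, amplitude=stim_amp)
    stim.validate(grid.L)
    sim = TissueSim(grid, frame_stride_ms, probe_stride_ms)
    sim.advance(t_end, stimuli_to_array([stim], grid.L))
    rec = sim.recording(meta=dict(protocol="P1", stim=vars(stim)))
    return rec


def run_p2(
    grid: TissueGrid,
    t_end: float = 3000.0,
    frame_stride_ms: float = 10.0,
    probe_stride_ms: float = 1.0,
    stim_amp: float = STIM_AMP_DEFAULT,
    front_threshold: float = -20.0,
    check_ms: float = 5.0,
    max_wait_ms: float = 2000.0,
    s2_delay_ms: float = 0.0,
    mirrored_s2: bool = False,
    sim_out: list | None = None,
) -> Recording:
    """S1-S2 cross-field spiral initiation.

    S1 launches a plane wave from the left edge; when the front (any
    myocyte node of the mid column above ``front_threshold``) has crossed
    half the domain, S2 is applied over the first quarter.  The
    front-crossing trigger fires exactly once.  If the front never
    crosses, the run is marked a protocol failure.
    """
    L = grid.L
    sim = TissueSim(grid, frame_stride_ms, probe_stride_ms)
    if sim_out is not None:
        sim_out.append(sim)
    s1 = s1_stimulus(L, amplitude=stim_amp)
    sim.advance(check_ms, stimuli_to_array([s1], L))
    mid = L // 2
    crossed = False
    while sim.t < max_wait_ms:
        col = grid.myo[:, mid, K.IV][grid.mask[:, mid] == 0]
        if col.size and np.max(col) > front_threshold:
            crossed = True
            break
        sim.advance(check_ms)
    meta = dict(protocol="P2", s2_applied=False, protocol_failure=False, mirrored_s2=mirrored_s2)
    if not crossed:
        meta["protocol_failure"] = True
        if sim.t < t_end:
            sim.advance(t_end - sim.t)
        return sim.recording(meta=meta)
    t_s2 = sim.t + s2_delay_ms
    s2 = s2_stimulus(L, onset=t_s2, amplitude=stim_amp, mirrored=mirrored_s2)
    meta.update(s2_applied=True, t_s2=t_s2)
    if t_end > sim.t:
        sim.advance(t_end - sim.t, stimuli_to_array([s2], L))
    return sim.recording(meta=meta)


def run_ramp(
    grid: TissueGrid,
    x_start: float = 1.75,
    dx_step: float = 0.25,
    dwell: float = 4000.0,
    x_end: float = 4.75,
    p2_t_end: float = 1500.0,
    frame_stride_ms: float = 20.0,
    probe_stride_ms: float = 2.0,
) -> list[Recording]:
    """Slow G_CaL ramp: initialize a spiral with P2 at x_start, then raise
    x by dx_step every ``dwell`` ms, carrying the tissue state across
    steps.  Returns one Recording per dwell (x recorded in metadata)."""
    grid.m_params = grid.m_params.with_xy(x=x_start)
    sims: list = []
    run_p2(grid, t_end=p2_t_end, frame_stride_ms=frame_stride_ms,
           probe_stride_ms=probe_stride_ms, sim_out=sims)
    recs = []
    nsteps = int(round((x_end - x_start) / dx_step)) + 1 if dx_step > 0 else 1
    x = x_start
    for k in range(nsteps):
        grid.m_params = grid.m_params.with_xy(x=x)
        sim = TissueSim(grid, frame_stride_ms, probe_stride_ms)
        sim.advance(dwell)
        recs.append(sim.recording(meta=dict(protocol="P2-ramp", x=x, step=k, dwell=dwell)))
        x += dx_step
    return recs
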