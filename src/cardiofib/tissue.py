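"""2D isotropic monodomain lattice with randomly inserted fibroblast clusters.

Each lattice node is either a myocyte (continuum reading: a group of
myocytes represented by one state) or a cluster of N identical
fibroblasts.  Voltage diffuses between myocyte nodes only (five-point
stencil, explicit Euler); fibroblast nodes are excluded from diffusion
and act as internal no-flux boundaries, interacting with their von
Neumann myocyte neighbours exclusively through ohmic gap junctions of
conductance Gs per myocyte-fibroblast pair.  Fibroblast-fibroblast
neighbours exchange nothing.

Paper-profile numerics: D = 0.00154 cm^2/ms, dx = 0.25 mm, dt = 0.02 ms,
L = 1024 (reduced L for desk-scale runs is a configuration choice and is
labelled in the recording metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardiofib import _kernels as K
from cardiofib.myocyte import MyocyteParams, initial_myocyte_state, IntegrationBlowupError
from cardiofib.fibroblast import FibroblastParams, initial_fibroblast_state
from cardiofib.recording import Recording, default_probe_grid

D_PAPER = 0.00154   # cm^2/ms
DX_PAPER = 0.25     # mm
DT_PAPER = 0.02     # ms


@dataclass
class Texture:
    """Binary fibrosis texture: which nodes hold fibroblast clusters."""

    L: int
    mask: np.ndarray  # (L, L) uint8, 1 = fibroblast-cluster node
    phi: float
    seed: int

    @property
    def n_fibroblast_nodes(self) -> int:
        return int(self.mask.sum())

    def save_txt(self, path) -> None:
        np.savetxt(path, self.mask, fmt="%d")


def make_texture(L: int, phi: float, seed: int) -> Texture:
    """Uniform random texture with exactly round(phi * L^2) flagged nodes."""
    if not 0 <= phi < 1:
        raise ValueError("phi must be in [0, 1)")
    n = int(round(phi * L * L))
    rng = np.random.default_rng(seed)
    mask = np.zeros(L * L, dtype=np.uint8)
    if n:
        mask[rng.choice(L * L, size=n, replace=False)] = 1
    return Texture(L=L, mask=mask.reshape(L, L), phi=phi, seed=seed)


@dataclass
class TissueGrid:
    """Lattice state + numerical parameters for one 2D simulation."""

    texture: Texture
    m_params: MyocyteParams = field(default_factory=MyocyteParams)
    f_params: FibroblastParams = field(default_factory=FibroblastParams)
    Gs: float = 0.0            # nS per M-F pair
    N_fib: int = 5             # fibroblasts per cluster node
    D: float = D_PAPER         # cm^2/ms
    dx: float = DX_PAPER       # mm
    dt: float = DT_PAPER       # ms
    myo: np.ndarray | None = None   # (L, L, NVAR_M)
    fib: np.ndarray | None = None   # (L, L, NVAR_F)

    def __post_init__(self):
        if self.cfl() >= 0.25:
            raise ValueError(f"CFL number {self.cfl():.3f} >= 0.25: unstable configuration")
        L = self.texture.L
        if self.myo is None:
            self.myo = np.tile(initial_myocyte_state(), (L, L, 1))
        if self.fib is None:
            self.fib = np.tile(initial_fibroblast_state(self.f_params), (L, L, 1))

    @property
    def L(self) -> int:
        return self.texture.L

    @property
    def mask(self) -> np.ndarray:
        return self.texture.mask

    def cfl(self) -> float:
        dx_cm = self.dx / 10.0
        return self.D * self.dt / dx_cm ** 2

    def set_myocyte_field(self, state_field: np.ndarray) -> None:
        """Initialize every myocyte node from a state field (L,L,NVAR_M)
        or a single state vector broadcast to all nodes."""
        if state_field.ndim == 1:
            self.myo = np.tile(state_field, (self.L, self.L, 1))
        else:
            self.myo = np.array(state_field, dtype=float)

    def copy(self) -> "TissueGrid":
        return TissueGrid(
            texture=self.texture, m_params=self.m_params, f_params=self.f_params,
            Gs=self.Gs, N_fib=self.N_fib, D=self.D, dx=self.dx, dt=self.dt,
            myo=self.myo.copy(), fib=self.fib.copy(),
        )


def laplacian_step(V_field: np.ndarray, mask: np.ndarray, D: float, dx: float, dt: float) -> np.ndarray:
    """Diffusion increment D*dt*lap(V) on myocyte nodes (mV).

    Five-point stencil over myocyte nodes only; fibroblast nodes and the
    outer edges are no-flux mirrors.  Returns an array that is zero on
    fibroblast nodes.  dx in mm, D in cm^2/ms.
    """
    V = np.asarray(V_field, dtype=float)
    myoc = mask == 0
    alpha = D * dt / (dx / 10.0) ** 2
    inc = np.zeros_like(V)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_v = np.roll(V, shift, axis=axis)
        nb_m = np.roll(myoc, shift, axis=axis)
        # mirror at outer edge: the rolled-in row/column is invalid
        valid = np.ones_like(myoc)
        if axis == 0:
            idx = 0 if shift == 1 else -1
            valid[idx, :] = False
        else:
            idx = 0 if shift == 1 else -1
            valid[:, idx] = False
        contrib = np.where(valid & nb_m & myoc, nb_v - V, 0.0)
        inc += contrib
    return alpha * inc


def couple_fibroblast_nodes(grid: TissueGrid) -> dict:
    """Junctional currents per node (pA) at the current voltages.

    Returns 'myocyte' (current leaving each myocyte node through M-F
    junctions) and 'fibroblast' (current entering each cluster); the two
    sum to zero globally by construction.
    """
    L = grid.L
    mask = grid.mask
    vm = grid.myo[:, :, K.IV]
    vf = grid.fib[:, :, 0]
    v = np.where(mask == 0, vm, vf)
    out_m = np.zeros((L, L))
    in_f = np.zeros((L, L))
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_v = np.roll(v, shift, axis=axis)
        nb_mask = np.roll(mask, shift, axis=axis)
        valid = np.ones((L, L), dtype=bool)
        idx = 0 if shift == 1 else -1
        if axis == 0:
            valid[idx, :] = False
        else:
            valid[:, idx] = False
        # myocyte node with fibroblast neighbour
        pair_m = valid & (mask == 0) & (nb_mask == 1)
        out_m += np.where(pair_m, grid.N_fib * grid.Gs * (v - nb_v), 0.0)
        # fibroblast node with myocyte neighbour
        pair_f = valid & (mask == 1) & (nb_mask == 0)
        in_f += np.where(pair_f, grid.N_fib * grid.Gs * (nb_v - v), 0.0)
    return {"myocyte": out_m, "fibroblast": in_f}


class TissueSim:
    """Stateful 2D simulation supporting chunked advancing, recording and
    event tracking; used by the protocol drivers."""

    def __init__(
        self,
        grid: TissueGrid,
        frame_stride_ms: float = 10.0,
        probe_stride_ms: float = 1.0,
        probe_idx: np.ndarray | None = None,
        max_events: int = 4096,
    ):
        self.grid = grid
        self.dt = grid.dt
        self.frame_stride = max(1, int(round(frame_stride_ms / self.dt)))
        self.probe_stride = max(1, int(round(probe_stride_ms / self.dt)))
        self.probe_idx = (
            probe_idx if probe_idx is not None else default_probe_grid(grid.L, grid.mask)
        ).astype(np.int64)
        self.step = 0
        self._frames_v, self._frames_ca, self._frames_na = [], [], []
        self._frame_steps: list[np.ndarray] = []
        self._probes: list[np.ndarray] = []
        self._probe_steps: list[np.ndarray] = []
        self.events = np.zeros((max_events, 3))
        self.n_events = 0
        self._tab_key = None
        L = grid.L
        self.act_count = np.zeros((L, L), dtype=np.int64)
        vm = grid.myo[:, :, K.IV]
        self.ready = ((grid.mask == 0) & (vm < -70.0)).astype(np.uint8)

    def advance(self, duration_ms: float, stimuli: np.ndarray | None = None) -> None:
        """Advance by duration_ms; stimuli is an (S,7) array of
        (r0, r1, c0, c1, amp, t_on, t_off) with absolute times in ms."""
        nsteps = int(round(duration_ms / self.dt))
        if nsteps <= 0:
            return
        spec = np.zeros((0, 7)) if stimuli is None else np.atleast_2d(np.asarray(stimuli, dtype=float))
        step0 = self.step
        f0 = -(-step0 // self.frame_stride)  # ceil
        f1 = -(-(step0 + nsteps) // self.frame_stride)
        nframes = f1 - f0
        p0 = -(-step0 // self.probe_stride)
        p1 = -(-(step0 + nsteps) // self.probe_stride)
        npr = p1 - p0
        L = self.grid.L
        fv = np.empty((nframes, L, L), dtype=np.float32)
        fca = np.empty((nframes, L, L), dtype=np.float32)
        fna = np.empty((nframes, L, L), dtype=np.float32)
        pv = np.empty((npr, len(self.probe_idx)), dtype=np.float32)

        g = self.grid
        pm = g.m_params.to_array()
        pf = g.f_params.to_array()
        tkey = (pm.tobytes(), self.dt)
        if self._tab_key != tkey:
            self._tv, self._tu = K.build_myocyte_tables(pm, self.dt)
            self._tf = K.build_fibroblast_tables(pf, self.dt)
            self._tab_key = tkey
        blow, self.n_events = K.advance_tissue_kernel(
            g.myo, g.fib, g.mask, pm, pf,
            float(g.Gs), int(g.N_fib), float(g.m_params.C_m_total),
            float(g.D), float(g.dx / 10.0), float(self.dt), nsteps, step0,
            self._tv, self._tu, self._tf, spec,
            self.frame_stride, f0, fv, fca, fna,
            self.probe_idx, self.probe_stride, p0, pv,
            self.act_count, self.ready, self.events, self.n_events,
        )
        self.step += nsteps
        self._frames_v.append(fv)
        self._frames_ca.append(fca)
        self._frames_na.append(fna)
        self._frame_steps.append((np.arange(f0, f1) * self.frame_stride))
        self._probes.append(pv)
        self._probe_steps.append((np.arange(p0, p1) * self.probe_stride))
        if blow >= 0:
            i, j = np.unravel_index(
                np.argmax(np.abs(np.where(g.mask == 0, g.myo[:, :, K.IV], 0.0))), g.mask.shape
            )
            raise IntegrationBlowupError(blow * self.dt)

    @property
    def t(self) -> float:
        return self.step * self.dt

    def recording(self, meta: dict | None = None) -> Recording:
        tf = np.concatenate(self._frame_steps) * self.dt if self._frame_steps else np.zeros(0)
        tp = np.concatenate(self._probe_steps) * self.dt if self._probe_steps else np.zeros(0)
        cat = lambda lst, w: np.concatenate(lst) if lst else np.zeros((0, w, w), dtype=np.float32)
        L = self.grid.L
        return Recording(
            t_frames=tf,
            V=cat(self._frames_v, L),
            ca_gate=cat(self._frames_ca, L),
            na_gate=cat(self._frames_na, L),
            probe_t=tp,
            probe_V=np.concatenate(self._probes) if self._probes else np.zeros((0, len(self.probe_idx))),
            probe_idx=self.probe_idx,
            mask=self.grid.mask.copy(),
            dx=self.grid.dx,
            events=self.events[: self.n_events].copy(),
            meta={
                **dict(
                    dt=self.dt,
                    L=L,
                    D=self.grid.D,
                    Gs=self.grid.Gs,
                    N_fib=self.grid.N_fib,
                    phi=self.grid.texture.phi,
                    seed=self.grid.texture.seed,
                    x=self.grid.m_params.x,
                    y=self.grid.m_params.y,
                    scaled=L != 1024,
                ),
                **(meta or {}),
            },
        )


def run_tissue(
    grid: TissueGrid,
    stimuli,
    t_end: float,
    frame_stride_ms: float = 10.0,
    probe_stride_ms: float = 1.0,
    probe_idx: np.ndarray | None = None,
    meta: dict | None = None,
) -> Recording:
    """Integrate the lattice to t_end (ms) under a list of StimulusSpec
    (or raw (S,7) rows) and return the Recording."""
    from cardiofib.protocols import stimuli_to_array

    sim = TissueSim(grid, frame_stride_ms, probe_stride_ms, probe_idx)
    sim.advance(t_end, stimuli_to_array(stimuli, grid.L))
    return sim.recording(meta=meta)
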