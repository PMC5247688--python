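"""Analytic surrogate recordings and regression ("golden") tables.

The surrogates are constructed voltage/gate frame stacks with known
ground-truth labels, used to validate the state classifier independently
of any tissue simulation: a travelling pulse (quiescent outcome), a
single rotating spiral, paired multi-spiral wavelets with a
full-repolarization toggle emulating the sodium- vs calcium-driven
fibrillation gate signatures, and a spatially near-uniform oscillation
(phase-wave regime).  All are exact functions of (t, row, col) evaluated
on the frame and probe grids, reproducible bit-exactly from their
parameters.

The golden tables pin both ionic-model transcriptions: random valid
states evaluated with the independent reference expressions
(:mod:`cardiofib._oracle`), against which the simulation kernels are
checked to near machine precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from cardiofib.recording import Recording, default_probe_grid
from cardiofib import _oracle as oracle
from cardiofib.myocyte import MyocyteParams
from cardiofib.fibroblast import FibroblastParams

V_REST = -85.0
V_PEAK = 15.0


def _smooth_step(x, w=4.0):
    return 0.5 * (1.0 + np.tanh(x / w))


def _spiral_phase(ii, jj, t, core, omega, wavelength, chirality=1):
    ci, cj = core
    theta = np.arctan2(ii - ci, jj - cj)
    r = np.hypot(ii - ci, jj - cj)
    return chirality * theta - 2.0 * np.pi * r / wavelength - omega * t


def _pulse(phase, sharp=3.0):
    """Periodic AP-like pulse in [0, 1] as a function of phase."""
    return (0.5 + 0.5 * np.cos(phase)) ** sharp


def make_surrogate_recording(
    kind: str,
    L: int = 48,
    span_ms: float = 2500.0,
    dt_frame: float = 10.0,
    dt_probe: float = 2.0,
    seed: int = 0,
    full_repol: bool = True,
    focal: tuple | None = None,
) -> Recording:
    """Analytic recording of the requested kind.

    kind: 'plane' (single passing wave -> NO_EAD), 'spiral' (one stable
    rotation -> SW), 'multiwavelet' (several paired spirals; SF_B when
    ``full_repol`` else the calcium-driven SF_A signature), 'oscillation'
    (uniform phase oscillation -> OSC).  ``focal=(t0, i, j)`` adds one
    focal re-excitation source to the 'plane' kind (ectopic-detector
    ground truth).
    """
    rng = np.random.default_rng(seed)
    period = 200.0
    omega = 2.0 * np.pi / period
    wavelength = 0.9 * L

    if kind == "plane":
        speed = 0.5          # nodes per ms
        t_offset = 20.0
        apd = 250.0

        def fields(t, ii, jj):
            ta = t_offset + jj / speed
            u = _smooth_step(t - ta) - _smooth_step(t - ta - apd)
            na = np.exp(-(((t - ta) / 6.0) ** 2))
            ca = 0.35 * u
            if focal is not None:
                t0, fi, fj = focal
                r = np.hypot(ii - fi, jj - fj)
                tb = t0 + r / speed
                ub = _smooth_step(t - tb) - _smooth_step(t - tb - apd)
                u = np.maximum(u, ub)
                na = np.maximum(na, np.exp(-(((t - tb) / 6.0) ** 2)))
                ca = 0.35 * u
            return V_REST + (V_PEAK - V_REST) * u, ca, na

    elif kind == "spiral":
        core = ((L - 1) / 2.0, (L - 1) / 2.0)

        def fields(t, ii, jj):
            u = _pulse(_spiral_phase(ii, jj, t, core, omega, wavelength))
            return V_REST + (V_PEAK - V_REST) * u, 0.35 * u, 0.8 * u ** 2

    elif kind == "multiwavelet":
        cores = []
        for _ in range(2):
            cores.append((rng.uniform(0.25, 0.45) * L, rng.uniform(0.2, 0.8) * L, 1))
            cores.append((rng.uniform(0.55, 0.75) * L, rng.uniform(0.2, 0.8) * L, -1))
        wl = 0.45 * L

        def fields(t, ii, jj):
            u = np.zeros(np.broadcast(ii, jj).shape)
            for ci, cj, chi in cores:
                u = np.maximum(
                    u, _pulse(_spiral_phase(ii, jj, t, (ci, cj), omega * (1.1 ** chi), wl, chi))
                )
            if full_repol:
                v = V_REST + (V_PEAK - V_REST) * u   # sodium-driven: full repol
                na = 0.8 * u ** 2
                ca = 0.35 * u
            else:
                v = -62.0 + 67.0 * u                 # calcium-driven: incomplete repol
                na = 0.001 * u
                ca = 0.5 * u
            return v, ca, na

    elif kind == "oscillation":

        def fields(t, ii, jj):
            # near-uniform oscillation, never below -50 mV, sodium silent
            ph = omega * t - 0.03 * jj
            v = -27.5 + 22.5 * np.sin(ph)
            one = np.ones(np.broadcast(ii, jj).shape)
            return v * one, (0.35 + 0.3 * np.sin(ph)) * one, 0.0 * one

    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")

    t_frames = np.arange(0.0, span_ms + 1e-9, dt_frame)
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    V = np.empty((len(t_frames), L, L), dtype=np.float32)
    ca = np.empty_like(V)
    na = np.empty_like(V)
    for k, t in enumerate(t_frames):
        v_, c_, n_ = fields(t, ii, jj)
        V[k], ca[k], na[k] = v_, c_, n_

    mask = np.zeros((L, L), dtype=np.uint8)
    probe_idx = default_probe_grid(L, mask)
    probe_t = np.arange(0.0, span_ms + 1e-9, dt_probe)
    pV = np.empty((len(probe_t), len(probe_idx)), dtype=np.float32)
    pii = probe_idx[:, 0].astype(float)
    pjj = probe_idx[:, 1].astype(float)
    for k, t in enumerate(probe_t):
        v_, _, _ = fields(t, pii, pjj)
        pV[k] = v_

    return Recording(
        t_frames=t_frames, V=V, ca_gate=ca, na_gate=na,
        probe_t=probe_t, probe_V=pV, probe_idx=probe_idx, mask=mask, dx=0.25,
        events=None,
        meta=dict(surrogate=kind, seed=seed, full_repol=full_repol, focal=focal, L=L),
    )


# ------------------------------------------------------------------ golden
def random_myocyte_states(n: int, seed: int) -> np.ndarray:
    """Random states satisfying the state invariants (gates in [0,1],
    positive concentrations, physiological voltage)."""
    rng = np.random.default_rng(seed)
    s = np.empty((n, 19))
    s[:, 0] = rng.uniform(-95.0, 45.0, n)          # V
    s[:, 1:13] = rng.uniform(0.0, 1.0, (n, 12))    # gates
    s[:, 13] = rng.uniform(4.0, 14.0, n)           # Na_i
    s[:, 14] = rng.uniform(120.0, 145.0, n)        # K_i
    s[:, 15] = rng.uniform(2e-5, 1e-3, n)          # Ca_i
    s[:, 16] = rng.uniform(0.2, 4.5, n)            # Ca_SR
    s[:, 17] = rng.uniform(2e-5, 1e-2, n)          # Ca_SS
    s[:, 18] = rng.uniform(0.0, 1.0, n)            # R_rel
    return s


def random_fibroblast_states(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    s = np.empty((n, 3))
    s[:, 0] = rng.uniform(-90.0, 30.0, n)
    s[:, 1:] = rng.uniform(0.0, 1.0, (n, 2))
    return s


def make_rhs_golden(
    n_states: int = 100,
    seed: int = 2024,
    m_params: MyocyteParams | None = None,
    f_params: FibroblastParams | None = None,
) -> dict:
    """Reference table of (state, currents, derivatives) for both ionic
    models, evaluated with the independent oracle transcription.  The
    simulation kernels must reproduce it to 1e-12 relative."""
    mp = m_params or MyocyteParams(x=1.7, y=0.8)
    fp = f_params or FibroblastParams(kv_shift=5.0)
    ms = random_myocyte_states(n_states, seed)
    fs = random_fibroblast_states(n_states, seed + 1)
    rows_m, rows_f = [], []
    for k in range(n_states):
        cur = oracle.oracle_myocyte_currents(ms[k], mp)
        rhs = oracle.oracle_myocyte_rhs(ms[k], mp, I_stim=0.0, I_gap=0.3)
        rows_m.append(dict(state=list(ms[k]), currents=cur, rhs=rhs))
        curf = oracle.oracle_fibroblast_currents(fs[k], fp)
        rhsf = oracle.oracle_fibroblast_rhs(fs[k], fp, I_gap_pA=2.0)
        rows_f.append(dict(state=list(fs[k]), currents=curf, rhs=rhsf))
    return dict(
        seed=seed,
        n=n_states,
        myocyte_params=vars(mp).copy(),
        fibroblast_params=vars(fp).copy(),
        I_gap_myocyte=0.3,
        I_gap_fibroblast_pA=2.0,
        myocyte=rows_m,
        fibroblast=rows_f,
    )


def save_golden(table: dict, path) -> None:
    Path(path).write_text(json.dumps(table, sort_keys=True))


def load_golden(path) -> dict:
    return json.loads(Path(path).read_text())


def golden_hash(table: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(table, sort_keys=True).encode()).hexdigest()


# ------------------------------------------------- preconditioned fixtures
_PRECOND_CACHE: dict = {}


def make_preconditioned_state(n_waves: int, L_small: int, dt: float = 0.02, **kw) -> np.ndarray:
    """Cached post-pacing-train myocyte state field on a small grid (the
    reduced analogue of the 50-wave 1 Hz preconditioning)."""
    from cardiofib.protocols import precondition_p1

    key = (n_waves, L_small, dt, tuple(sorted(kw.items())))
    if key not in _PRECOND_CACHE:
        _PRECOND_CACHE[key] = precondition_p1(L_small, n_waves=n_waves, dt=dt, **kw)
    return _PRECOND_CACHE[key].copy()
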