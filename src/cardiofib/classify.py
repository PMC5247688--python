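"""Classification of 2D dynamical states and ectopic-origin statistics.

The taxonomy follows the wave-dynamics regimes of EAD-prone ventricular
tissue: NO_EAD (a wave passes, the action potential shows no
oscillation), EAD (oscillations ride on the action potential but no
sustained activity follows), SW (one stable rotating spiral), SF_B
(multi-wavelet fibrillation driven by sodium waves: cells repolarize
fully between activations and the fast-sodium gate product m^3*h*j shows
large excursions), SF_A (fibrillation driven by L-type calcium waves:
incomplete repolarization, sodium gates essentially silent, large
d*f*f2*fCass excursions), and OSC (all cells oscillate; the apparent
waves are phase waves, not propagated excitation).

The regimes are operationalized with voltage/gate thresholds documented
in the methods note; the classifier is deterministic given a recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from cardiofib.recording import Recording


class StateLabel(str, Enum):
    NO_EAD = "NO_EAD"
    EAD = "EAD"
    SW = "SW"
    SF_A = "SF_A"
    SF_B = "SF_B"
    OSC = "OSC"
    PROTOCOL_FAILURE = "PROTOCOL_FAILURE"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass
class EctopicEvent:
    """First non-protocol depolarizing wave: when, where, and whether it
    arose in the boundary band or the interior."""

    time: float            # ms
    row: int
    col: int
    origin_class: str      # "boundary" | "middle"
    ordinal: int = 0


# classification thresholds (see methods note)
V_ACTIVE = -20.0        # a node above this is "active"
V_FULL_REPOL = -70.0    # full repolarization level
V_OSC_FLOOR = -55.0     # OSC: no myocyte node ever falls below this
NA_GATE_THRESH = 0.1    # m^3*h*j excursion marking sodium-driven activity
CA_GATE_THRESH = 0.1    # d*f*f2*fCass excursion marking calcium-driven activity
ACTIVE_NODE_FRAC = 0.05
OSC_NODE_FRAC = 0.95
SW_AUTOCORR = 0.9
MIN_WINDOW_MS = 2000.0


def _myocyte_probe_traces(rec: Recording) -> np.ndarray:
    """(S, P') probe voltages restricted to probes on myocyte nodes."""
    keep = [q for q, (i, j) in enumerate(rec.probe_idx) if rec.mask[i, j] == 0]
    return rec.probe_V[:, keep]


def count_phase_singularities(V_frames: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Phase-singularity count per frame via topological charge.

    The phase of each node is obtained from the analytic signal (Hilbert
    transform in time) of its mean-subtracted voltage; a singularity is a
    2x2 plaquette whose winding number is +-1.  Returns the per-frame
    counts; use the time-median for a robust summary.
    """
    V = np.asarray(V_frames, dtype=float)
    if V.ndim != 3 or V.shape[0] < 2:
        raise ValueError("need a (frames, L, L) stack with at least 2 frames")
    from scipy.signal import hilbert

    x = V - V.mean(axis=0, keepdims=True)
    phase = np.angle(hilbert(x, axis=0))
    # winding number around each plaquette
    d1 = _wrap(phase[:, :-1, 1:] - phase[:, :-1, :-1])
    d2 = _wrap(phase[:, 1:, 1:] - phase[:, :-1, 1:])
    d3 = _wrap(phase[:, 1:, :-1] - phase[:, 1:, 1:])
    d4 = _wrap(phase[:, :-1, :-1] - phase[:, 1:, :-1])
    charge = (d1 + d2 + d3 + d4) / (2.0 * np.pi)
    sing = np.abs(charge) > 0.5
    if mask is not None:
        # ignore plaquettes touching fibroblast nodes (phase undefined there)
        bad = (mask[:-1, :-1] | mask[:-1, 1:] | mask[1:, :-1] | mask[1:, 1:]) != 0
        sing = sing & ~bad[None, :, :]
    return sing.sum(axis=(1, 2))


def phase_singularity_charges(V_frames: np.ndarray) -> np.ndarray:
    """Summed topological charge per frame (chirality bookkeeping)."""
    V = np.asarray(V_frames, dtype=float)
    from scipy.signal import hilbert

    x = V - V.mean(axis=0, keepdims=True)
    phase = np.angle(hilbert(x, axis=0))
    d1 = _wrap(phase[:, :-1, 1:] - phase[:, :-1, :-1])
    d2 = _wrap(phase[:, 1:, 1:] - phase[:, :-1, 1:])
    d3 = _wrap(phase[:, 1:, :-1] - phase[:, 1:, 1:])
    d4 = _wrap(phase[:, :-1, :-1] - phase[:, 1:, :-1])
    charge = (d1 + d2 + d3 + d4) / (2.0 * np.pi)
    return np.round(charge).sum(axis=(1, 2))


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _autocorr_peak(x: np.ndarray) -> float:
    """Largest normalized autocorrelation at a non-zero lag."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0):
        return 1.0
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    ac /= ac[0]
    # skip the zero-lag peak: first local minimum, then global max beyond it
    i = 1
    while i < len(ac) - 1 and ac[i] >= ac[i + 1]:
        i += 1
    return float(np.max(ac[i:])) if i < len(ac) else 0.0


def classify_recording(rec: Recording, protocol: str = "P2") -> StateLabel:
    """Label one recording with the dynamical-state taxonomy.

    Uses the final (up to) 2 s of the recording; shorter windows are
    inconclusive.  See the module docstring for the decision cascade.
    """
    if rec.meta.get("protocol_failure"):
        return StateLabel.PROTOCOL_FAILURE
    if len(rec.t_frames) < 2:
        return StateLabel.INCONCLUSIVE
    t = rec.t_frames
    window = min(MIN_WINDOW_MS, t[-1] - t[0])
    if window < MIN_WINDOW_MS - 1e-6:
        return StateLabel.INCONCLUSIVE
    w = t >= t[-1] - window
    V = rec.V[w]
    na = rec.na_gate[w]
    tw = t[w]
    myoc = rec.mask == 0

    # (1) sustained activity: any myocyte node active in the last 500 ms
    tail = tw >= tw[-1] - 500.0
    sustained = bool(np.any(V[tail][:, myoc] > V_ACTIVE))
    probes = _myocyte_probe_traces(rec)
    pw = rec.probe_t >= rec.probe_t[-1] - window if len(rec.probe_t) else np.zeros(0, bool)
    if not sustained:
        from cardiofib.coupled import Trace, count_eads

        n_ead = 0
        if probes.size and pw.any():
            tt = rec.probe_t[pw]
            for q in range(probes.shape[1]):
                n_ead = max(n_ead, count_eads(Trace(t=tt, V_M=probes[pw, q].astype(float))))
        return StateLabel.EAD if n_ead >= 1 else StateLabel.NO_EAD

    # node-wise statistics over the window
    vmin = V[:, myoc].min(axis=0)
    na_max = na[:, myoc].max(axis=0)
    na_active = float(np.mean(na_max > NA_GATE_THRESH)) > ACTIVE_NODE_FRAC

    # (2) single stable rotation (P2 only)
    if protocol.upper() == "P2":
        ps = count_phase_singularities(V, rec.mask)
        periodic = True
        if probes.size and pw.any():
            periodic = all(
                _autocorr_peak(probes[pw, q]) > SW_AUTOCORR for q in range(probes.shape[1])
            )
        if int(np.median(ps)) == 1 and periodic:
            return StateLabel.SW

    # (5) global oscillation without any full repolarization
    tail1s = tw >= tw[-1] - 1000.0
    vmin_1s = V[tail1s][:, myoc].min(axis=0)
    if float(np.mean(vmin_1s > V_OSC_FLOOR)) >= OSC_NODE_FRAC:
        return StateLabel.OSC

    # (3) sodium-wave fibrillation: full repolarization + Na-gate activity
    full_repol = float(np.mean(vmin < V_FULL_REPOL)) >= 0.5
    if full_repol and na_active:
        return StateLabel.SF_B

    # (4) calcium-wave fibrillation: incomplete repolarization and/or
    # silent sodium gates; sustained non-SW, non-OSC, non-SF_B dynamics
    # in this model are L-type-calcium mediated
    return StateLabel.SF_A


def locate_first_ectopic(
    rec: Recording,
    boundary_band: int | None = None,
    exclude_region: tuple[int, int, int, int] | None = None,
) -> EctopicEvent | None:
    """First non-protocol depolarizing wave in a P1 recording.

    A re-activation is a node crossing -20 mV upward after having
    repolarized below -70 mV following its primary activation.  Uses the
    per-step events tracked by the simulation kernel when present,
    otherwise reconstructs activations from the voltage frames.  Origin
    is "boundary" within ``boundary_band`` nodes of any edge (default
    16/1024 of the side), else "middle".
    """
    L = rec.L
    band = boundary_band if boundary_band is not None else max(1, round(16 * L / 1024))
    events = rec.events
    if events is None or len(events) == 0:
        events = _events_from_frames(rec)
    if len(events) == 0:
        return None
    if exclude_region is not None:
        r0, r1, c0, c1 = exclude_region
        keep = ~(
            (events[:, 1] >= r0) & (events[:, 1] < r1)
            & (events[:, 2] >= c0) & (events[:, 2] < c1)
        )
        events = events[keep]
        if len(events) == 0:
            return None
    # all events sharing the earliest timestamp belong to the same focal
    # front (frame-resolution reconstructions report a small disc); its
    # centroid localizes the source
    t0 = events[0, 0]
    first = events[events[:, 0] == t0]
    t = t0
    i = int(round(first[:, 1].mean()))
    j = int(round(first[:, 2].mean()))
    on_boundary = i < band or j < band or i >= L - band or j >= L - band
    return EctopicEvent(time=float(t), row=i, col=j,
                       origin_class="boundary" if on_boundary else "middle", ordinal=0)


def _events_from_frames(rec: Recording) -> np.ndarray:
    """Frame-resolution reconstruction of re-activation events."""
    V = rec.V
    myoc = rec.mask == 0
    L = rec.L
    ready = (V[0] < V_FULL_REPOL) & myoc
    act = np.zeros((L, L), dtype=int)
    out = []
    for k in range(1, V.shape[0]):
        vk = V[k]
        crossing = ready & (vk > V_ACTIVE)
        if crossing.any():
            act[crossing] += 1
            ready[crossing] = False
            new = crossing & (act >= 2)
            for i, j in zip(*np.nonzero(new)):
                out.append((rec.t_frames[k], i, j))
        ready |= (vk < V_FULL_REPOL) & myoc
    return np.array(out) if out else np.zeros((0, 3))


def ectopic_origin_stats(events: list[EctopicEvent | None]) -> tuple[float, float, float]:
    """Percentages (no-new-waves, boundary-first, middle-first) over runs;
    sums to 100 (exactly when n divides 100, to float rounding
    otherwise)."""
    if not events:
        raise ValueError("no runs supplied")
    n = len(events)
    nb = sum(1 for e in events if e is not None and e.origin_class == "boundary")
    nm = sum(1 for e in events if e is not None and e.origin_class == "middle")
    pb = 100.0 * nb / n
    pm = 100.0 * nm / n
    return (100.0 - pb - pm, pb, pm)  # exact complement: sums to 100.0
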