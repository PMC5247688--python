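"""Recording container for 2D runs, with HDF5 persistence.

A Recording bundles coarse-stride pseudocolor frames of the voltage and
of the two gate products that discriminate the fibrillatory regimes
(L-type calcium gate product d*f*f2*fCass, sodium gate product m^3*h*j),
fine-stride point traces at probe sites, the fibrotic texture mask, the
raw re-activation events tracked during the run, and provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    t_frames: np.ndarray          # ms, shape (F,)
    V: np.ndarray                 # (F, L, L) float32, mV
    ca_gate: np.ndarray           # (F, L, L) float32, d*f*f2*fCass
    na_gate: np.ndarray           # (F, L, L) float32, m^3*h*j
    probe_t: np.ndarray           # ms, shape (S,)
    probe_V: np.ndarray           # (S, P) float32
    probe_idx: np.ndarray         # (P, 2) int
    mask: np.ndarray              # (L, L) uint8; 1 = fibroblast-cluster node
    dx: float                     # mm
    events: np.ndarray | None = None   # (E, 3): t, row, col of re-activations
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return int(self.mask.shape[0])

    @property
    def dt_frame(self) -> float:
        return float(self.t_frames[1] - self.t_frames[0]) if len(self.t_frames) > 1 else 0.0

    @property
    def dt_probe(self) -> float:
        return float(self.probe_t[1] - self.probe_t[0]) if len(self.probe_t) > 1 else 0.0

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.t_frames, self.V, self.ca_gate, self.na_gate, self.probe_V, self.mask):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("t_frames", "V", "ca_gate", "na_gate", "probe_t", "probe_V", "probe_idx", "mask"):
                f.create_dataset(name, data=getattr(self, name))
            if self.events is not None:
                f.create_dataset("events", data=self.events)
            f.attrs["dx"] = self.dx
            f.attrs["meta"] = json.dumps(self.meta, default=str)

    @classmethod
    def load(cls, path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][...]
                for name in ("t_frames", "V", "ca_gate", "na_gate", "probe_t", "probe_V", "probe_idx", "mask")
            }
            events = f["events"][...] if "events" in f else None
            return cls(events=events, dx=float(f.attrs["dx"]), meta=json.loads(f.attrs["meta"]), **kw)


def default_probe_grid(L: int, mask: np.ndarray | None = None, n_side: int = 3) -> np.ndarray:
    """An n_side x n_side lattice of probe sites, nudged onto myocyte nodes."""
    coords = np.linspace(L / (2 * n_side), L - L / (2 * n_side), n_side).round().astype(int)
    pts = []
    for i in coords:
        for j in coords:
            ii, jj = int(i), int(j)
            if mask is not None and mask[ii, jj] != 0:
                found = False
                for radius in range(1, L):
                    for di in range(-radius, radius + 1):
                        for dj in range(-radius, radius + 1):
                            a, b = ii + di, jj + dj
                            if 0 <= a < L and 0 <= b < L and mask[a, b] == 0:
                                ii, jj, found = a, b, True
                                break
                        if found:
                            break
                    if found:
                        break
            pts.append((ii, jj))
    return np.array(pts, dtype=np.int64)
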