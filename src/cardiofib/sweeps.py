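"""Two-parameter sweeps, pathological-fraction summaries and ectopic
ensembles.

A phase diagram classifies one run per (x, y) = (G_CaL, G_Kr multiplier)
grid point at fixed gap conductance Gs and fibroblast profile.  Diagram
cells are independent fresh runs (P2 cells each initiate their own
spiral at that x; the slow-ramp alternative is available through
:func:`cardiofib.protocols.run_ramp`).  Completed sweeps are cached on
disk by a hash of their full configuration, so re-running an identical
configuration touches no simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cardiofib.myocyte import MyocyteParams
from cardiofib.fibroblast import FibroblastParams
from cardiofib.tissue import TissueGrid, make_texture
from cardiofib.protocols import run_p1, run_p2
from cardiofib.classify import StateLabel, classify_recording, locate_first_ectopic, ectopic_origin_stats
from cardiofib.surrogates import make_preconditioned_state

PATHOLOGICAL = {StateLabel.SF_A, StateLabel.SF_B, StateLabel.OSC}


@dataclass
class PhaseDiagram:
    x_grid: np.ndarray
    y_grid: np.ndarray
    Gs: float
    profile_name: str
    protocol: str
    labels: np.ndarray          # (len(y_grid), len(x_grid)) of str
    L: int
    phi: float
    seed: int
    meta: dict = field(default_factory=dict)

    def label_at(self, x: float, y: float) -> str:
        i = int(np.argmin(np.abs(self.y_grid - y)))
        j = int(np.argmin(np.abs(self.x_grid - x)))
        return str(self.labels[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.y_grid, columns=self.x_grid)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_phase_diagram(
    protocol: str,
    x_grid,
    y_grid,
    Gs: float,
    profile: FibroblastParams,
    phi: float,
    L: int,
    seed: int,
    t_end: float = 3000.0,
    D: float | None = None,
    dt: float = 0.02,
    n_precond_waves: int = 2,
    cache_dir: str | Path | None = None,
    profile_name: str = "custom",
    frame_stride_ms: float = 20.0,
    _run_counter: list | None = None,
) -> PhaseDiagram:
    """Classify one run per (x, y) cell; failures become INCONCLUSIVE
    without aborting the sweep.  Results are cached by config hash."""
    x_grid = np.asarray(list(x_grid), dtype=float)
    y_grid = np.asarray(list(y_grid), dtype=float)
    if x_grid.size == 0 or y_grid.size == 0:
        raise ValueError("empty sweep grid")
    cfg = dict(
        protocol=protocol, x=list(x_grid), y=list(y_grid), Gs=Gs,
        profile=vars(profile).copy(), phi=phi, L=L, seed=seed, t_end=t_end,
        D=D, dt=dt, npw=n_precond_waves,
    )
    key = _config_hash(cfg)
    cache_file = Path(cache_dir) / f"diagram_{key}.json" if cache_dir else None
    if cache_file is not None and cache_file.exists():
        payload = json.loads(cache_file.read_text())
        return PhaseDiagram(
            x_grid=x_grid, y_grid=y_grid, Gs=Gs, profile_name=profile_name,
            protocol=protocol, labels=np.array(payload["labels"]),
            L=L, phi=phi, seed=seed, meta=payload.get("meta", {}),
        )

    texture = make_texture(L, phi, seed)
    kw = {} if D is None else {"D": D}
    labels = np.empty((len(y_grid), len(x_grid)), dtype=object)
    init = None
    if protocol.upper() == "P1":
        init = make_preconditioned_state(n_precond_waves, L, dt=dt, **kw)
    for i, y in enumerate(y_grid):
        for j, x in enumerate(x_grid):
            mp = MyocyteParams(x=float(x), y=float(y))
            grid = TissueGrid(texture=texture, m_params=mp, f_params=profile,
                              Gs=Gs, dt=dt, **kw)
            try:
                if protocol.upper() == "P1":
                    rec = run_p1(grid, init=init, t_end=t_end, frame_stride_ms=frame_stride_ms)
                else:
                    rec = run_p2(grid, t_end=t_end, frame_stride_ms=frame_stride_ms)
                labels[i, j] = classify_recording(rec, protocol).value
            except Exception:
                labels[i, j] = StateLabel.INCONCLUSIVE.value
            if _run_counter is not None:
                _run_counter.append((float(x), float(y)))
    diag = PhaseDiagram(
        x_grid=x_grid, y_grid=y_grid, Gs=Gs, profile_name=profile_name,
        protocol=protocol, labels=labels.astype(str), L=L, phi=phi, seed=seed,
        meta=dict(config_hash=key, t_end=t_end, scaled=L != 1024, mode="fresh-per-cell"),
    )
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(json.dumps(dict(
            labels=diag.labels.tolist(), meta=diag.meta, protocol=protocol,
            Gs=Gs, profile_name=profile_name, x=list(x_grid), y=list(y_grid),
            L=L, phi=phi, seed=seed,
        )))
    return diag


def pathological_fraction(diagrams: dict) -> pd.DataFrame:
    """Count non-trivial pathological cells (SF_A, SF_B or OSC) per diagram.

    ``diagrams`` maps (protocol, Gs) -> PhaseDiagram sharing grids.
    Reports the counts N1 (P2) / N2 (P1), the grid size, and the fraction
    of cells that are pathological.
    """
    if not diagrams:
        raise ValueError("no diagrams supplied")
    shapes = {d.labels.shape for d in diagrams.values()}
    if len(shapes) != 1:
        raise ValueError("diagrams do not share a common grid")
    rows = []
    for (protocol, gs), d in sorted(diagrams.items()):
        n_path = int(np.isin(d.labels, [s.value for s in PATHOLOGICAL]).sum())
        n_tot = d.labels.size
        rows.append(dict(protocol=protocol, Gs=gs, n_pathological=n_path,
                         n_cells=n_tot, fraction=n_path / n_tot,
                         profile=d.profile_name))
    return pd.DataFrame(rows)


def ectopic_ensemble(
    y: float,
    x_values,
    phi: float,
    profile: FibroblastParams,
    Gs: float,
    n_textures: int,
    seeds,
    L: int = 128,
    t_end: float = 2000.0,
    D: float | None = None,
    dt: float = 0.02,
    n_precond_waves: int = 2,
) -> dict:
    """P1 runs over an (x, texture) ensemble; first-ectopic-origin
    statistics in the three-column layout (no new waves / boundary-first /
    middle-first percentages).

    ``seeds`` supplies one RNG seed per texture; every run's provenance
    (x, seed, event) is returned alongside the percentages.
    """
    if n_textures < 1:
        raise ValueError("need at least one texture")
    seeds = list(seeds)[:n_textures]
    kw = {} if D is None else {"D": D}
    init = make_preconditioned_state(n_precond_waves, L, dt=dt, **kw)
    events, prov = [], []
    for seed in seeds:
        texture = make_texture(L, phi, seed)
        for x in x_values:
            mp = MyocyteParams(x=float(x), y=float(y))
            grid = TissueGrid(texture=texture, m_params=mp, f_params=profile,
                              Gs=Gs, dt=dt, **kw)
            rec = run_p1(grid, init=init, t_end=t_end, frame_stride_ms=50.0,
                         probe_stride_ms=5.0)
            ev = locate_first_ectopic(rec)
            events.append(ev)
            prov.append(dict(x=float(x), seed=int(seed),
                             event=None if ev is None else vars(ev)))
    pct = ectopic_origin_stats(events)
    return dict(
        no_new_waves=pct[0], boundary_first=pct[1], middle_first=pct[2],
        n_runs=len(events), runs=prov,
        config=dict(y=y, phi=phi, Gs=Gs, L=L, t_end=t_end, seeds=seeds),
    )


def load_cached_diagrams(cache_dir) -> dict:
    """Reload every cached diagram in ``cache_dir`` keyed by
    (protocol, Gs), ready for :func:`pathological_fraction`."""
    out = {}
    for f in sorted(Path(cache_dir).glob("diagram_*.json")):
        payload = json.loads(f.read_text())
        if "protocol" not in payload:
            continue
        d = PhaseDiagram(
            x_grid=np.asarray(payload["x"]), y_grid=np.asarray(payload["y"]),
            Gs=payload["Gs"], profile_name=payload["profile_name"],
            protocol=payload["protocol"], labels=np.array(payload["labels"]),
            L=payload["L"], phi=payload["phi"], seed=payload["seed"],
            meta=payload.get("meta", {}),
        )
        out[(d.protocol, d.Gs)] = d
    return out
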