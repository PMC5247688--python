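"""Shipped parameter profiles.

Fibroblast profiles combine the two phenotypes (capacitance 6.3 pF
"fibroblast", 50 pF "myofibroblast") with the two nominal resting
potentials: -49.7 mV (unshifted gating; the model's computed uncoupled
rest is about -49.6 mV) and -24.5 mV (I_fKv gating shifted by the
calibrated offset).  The 2D studies use "fibroblast1" (6.3 pF, -49.7 mV)
and "fibroblast2" (50 pF, -24.5 mV).
"""

from __future__ import annotations

from importlib import resources

import yaml

from cardiofib.fibroblast import FibroblastParams
from cardiofib.myocyte import MyocyteParams

# kv_shift calibrated once with calibrate_kv_shift(-24.5) at 0.025 mV
# root-finding resolution; regenerable, see tests
KV_SHIFT_24_5 = 35.928

_FIB_PROFILES = {
    "fibroblast1": dict(C_F=6.3, kv_shift=0.0, V_FR_target=-49.7),
    "fibroblast2": dict(C_F=50.0, kv_shift=KV_SHIFT_24_5, V_FR_target=-24.5),
    "fibroblast_-49.7": dict(C_F=6.3, kv_shift=0.0, V_FR_target=-49.7),
    "fibroblast_-24.5": dict(C_F=6.3, kv_shift=KV_SHIFT_24_5, V_FR_target=-24.5),
    "myofibroblast_-49.7": dict(C_F=50.0, kv_shift=0.0, V_FR_target=-49.7),
    "myofibroblast_-24.5": dict(C_F=50.0, kv_shift=KV_SHIFT_24_5, V_FR_target=-24.5),
}


def fibroblast_profile(name: str) -> FibroblastParams:
    try:
        return FibroblastParams(**_FIB_PROFILES[name])
    except KeyError:
        raise KeyError(f"unknown fibroblast profile {name!r}; available: {sorted(_FIB_PROFILES)}")


def myocyte_paper_profile(x: float = 1.0, y: float = 1.0) -> MyocyteParams:
    """The myocyte configuration used throughout: TP06 epicardial with the
    EAD modifications (tau_f halved, base G_CaL doubled)."""
    return MyocyteParams(x=x, y=y)


def load_profile_file(path) -> dict:
    return yaml.safe_load(open(path))


def write_default_profiles(directory) -> None:
    """Write the frozen default profiles as key/value YAML files."""
    from pathlib import Path
    import dataclasses

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "myocyte_paper.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(myocyte_paper_profile()), sort_keys=False)
    )
    for name in _FIB_PROFILES:
        (d / f"{name}.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(fibroblast_profile(name)), sort_keys=False)
        )
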