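"""Active fibroblast model: transcription, resting potential, calibration."""

import numpy as np
import pytest
from dataclasses import replace

from cardiofib import _oracle as oracle
from cardiofib.fibroblast import (
    FibroblastParams,
    calibrate_kv_shift,
    fibroblast_currents,
    fibroblast_rhs,
    initial_fibroblast_state,
    resting_potential,
)
from cardiofib.profiles import fibroblast_profile, KV_SHIFT_24_5
from cardiofib.surrogates import random_fibroblast_states

RTF = 8314.472 * 310.0 / 96485.3415


def test_currents_match_independent_transcription():
    p = FibroblastParams(kv_shift=5.0)
    for s in random_fibroblast_states(100, seed=11):
        cur = fibroblast_currents(s, p)
        ref = oracle.oracle_fibroblast_currents(s, p)
        for name in cur:
            assert cur[name] == pytest.approx(ref[name], rel=1e-12, abs=1e-25)
        rhs = fibroblast_rhs(s, p, I_gap=2.0)
        ref_rhs = oracle.oracle_fibroblast_rhs(s, p, I_gap_pA=2.0)
        for i, name in enumerate(("V_F", "r", "s")):
            assert rhs[i] == pytest.approx(ref_rhs[name], rel=1e-12, abs=1e-25)


def test_resting_potential_matches_published_value():
    """The uncoupled model relaxes to -49.6 mV (+-0.3)."""
    v, converged = resting_potential(FibroblastParams())
    assert v == pytest.approx(-49.6, abs=0.3)


def test_resting_potential_independent_of_capacitance():
    """Capacitance rescales time, not the fixed point."""
    v1, _ = resting_potential(FibroblastParams(C_F=6.3))
    v2, _ = resting_potential(FibroblastParams(C_F=50.0))
    assert v1 == pytest.approx(v2, abs=1e-6)


def test_capacitance_scales_voltage_derivative():
    s = initial_fibroblast_state()
    s[0] = -30.0
    d1 = fibroblast_rhs(s, FibroblastParams(C_F=6.3), I_gap=10.0)
    # at fixed membrane current density, only the gap term (in pA) is
    # divided by C_F
    d2 = fibroblast_rhs(s, FibroblastParams(C_F=12.6), I_gap=20.0)
    assert d1[0] == pytest.approx(d2[0], rel=1e-12)


def test_inward_rectification_of_background_k_current():
    """The I_fK1 chord conductance decreases with depolarization above
    the K+ reversal."""
    p = FibroblastParams()
    ek = RTF * np.log(p.K_o / p.K_i)
    conducts = []
    for v in (ek + 10.0, ek + 30.0, ek + 60.0, ek + 90.0):
        s = np.array([v, 0.2, 0.8])
        g = fibroblast_currents(s, p)["I_fK1"] / (v - ek)
        conducts.append(g)
    assert all(a > b for a, b in zip(conducts, conducts[1:]))


def test_calibrated_profile_reaches_depolarized_rest():
    """The shipped kv-shift reproduces the -24.5 mV profile."""
    v, _ = resting_potential(FibroblastParams(kv_shift=KV_SHIFT_24_5))
    assert v == pytest.approx(-24.5, abs=0.3)


def test_calibration_identity_and_self_consistency():
    v0, _ = resting_potential(FibroblastParams())
    s0 = calibrate_kv_shift(v0)
    assert abs(s0) < 1.0
    s = calibrate_kv_shift(-24.5)
    v, _ = resting_potential(FibroblastParams(kv_shift=s))
    assert v == pytest.approx(-24.5, abs=0.1)


def test_resting_potential_monotone_in_shift():
    """Over the calibration bracket the rest potential increases with the
    gating shift (coarse 10 mV scan)."""
    vals = [resting_potential(FibroblastParams(kv_shift=s))[0] for s in range(-30, 51, 10)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_calibration_rejects_out_of_range_target():
    with pytest.raises(ValueError):
        calibrate_kv_shift(-5.0)


def test_profiles_cover_phenotypes():
    f1 = fibroblast_profile("fibroblast1")
    f2 = fibroblast_profile("fibroblast2")
    assert f1.C_F == 6.3 and f1.V_FR_target == -49.7 and f1.kv_shift == 0.0
    assert f2.C_F == 50.0 and f2.V_FR_target == -24.5 and f2.kv_shift > 0.0
    with pytest.raises(KeyError):
        fibroblast_profile("nope")
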