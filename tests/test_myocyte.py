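"""Ventricular myocyte model: transcription correctness and dynamics."""

import numpy as np
import pytest

from cardiofib import _oracle as oracle
from cardiofib.myocyte import (
    IntegrationBlowupError,
    MyocyteParams,
    initial_myocyte_state,
    myocyte_currents,
    myocyte_rhs,
    relax_myocyte,
    step_cell,
)
from cardiofib.coupled import pace_unit, apd90, count_eads
from cardiofib.surrogates import random_myocyte_states

RTF = 8314.472 * 310.0 / 96485.3415


def test_currents_match_independent_transcription():
    """Every current and every state derivative agrees with the
    term-by-term reference transcription to 1e-12 relative on 100 random
    valid states."""
    p = MyocyteParams(x=1.7, y=0.8)
    for s in random_myocyte_states(100, seed=7):
        cur = myocyte_currents(s, p)
        ref = oracle.oracle_myocyte_currents(s, p)
        for name in cur:
            assert cur[name] == pytest.approx(ref[name], rel=1e-12, abs=1e-25)
        rhs = myocyte_rhs(s, p, I_stim=0.0, I_gap=0.3)
        ref_rhs = oracle.oracle_myocyte_rhs(s, p, I_stim=0.0, I_gap=0.3)
        for i, name in enumerate(oracle.MYO_STATE_NAMES):
            assert rhs[i] == pytest.approx(ref_rhs[name], rel=1e-12, abs=1e-25)


def test_closed_d_gate_zeroes_l_type_current():
    s = initial_myocyte_state()
    s[4] = 0.0  # d gate
    assert myocyte_currents(s, MyocyteParams())["I_CaL"] == 0.0


def test_zero_driving_force_zeroes_inward_rectifier():
    p = MyocyteParams()
    s = initial_myocyte_state()
    s[0] = RTF * np.log(p.K_o / s[14])  # V = E_K
    assert myocyte_currents(s, p)["I_K1"] == pytest.approx(0.0, abs=1e-12)


def test_ead_modifications_scale_conductances():
    """Effective G_CaL = ead_scale * x * base and G_Kr = y * base."""
    s = random_myocyte_states(1, seed=1)[0]
    base = myocyte_currents(s, MyocyteParams(x=1.0, y=1.0, g_cal_ead_scale=1.0))
    mod = myocyte_currents(s, MyocyteParams(x=1.5, y=0.5, g_cal_ead_scale=2.0))
    assert mod["I_CaL"] == pytest.approx(3.0 * base["I_CaL"], rel=1e-12)
    assert mod["I_Kr"] == pytest.approx(0.5 * base["I_Kr"], rel=1e-12)
    assert mod["I_Na"] == pytest.approx(base["I_Na"], rel=1e-12)


def test_invalid_state_rejected():
    s = initial_myocyte_state()
    s[0] = np.nan
    with pytest.raises(ValueError):
        myocyte_currents(s, MyocyteParams())
    with pytest.raises(ValueError):
        myocyte_rhs(s, MyocyteParams())


def test_relaxed_state_is_fixed_point(relaxed_myocyte):
    """After 10 s of unstimulated integration all derivatives are tiny."""
    ds = myocyte_rhs(relaxed_myocyte, MyocyteParams())
    assert np.max(np.abs(ds)) < 1e-4
    assert relaxed_myocyte[0] == pytest.approx(-86.2, abs=0.5)


def test_gap_current_enters_linearly(relaxed_myocyte):
    """Adding I_gap = c shifts dV/dt by exactly -c."""
    p = MyocyteParams()
    base = myocyte_rhs(relaxed_myocyte, p, I_gap=0.0)
    for c in (0.5, -1.25, 3.0):
        shifted = myocyte_rhs(relaxed_myocyte, p, I_gap=c)
        assert shifted[0] - base[0] == pytest.approx(-c, rel=1e-12)
        assert np.allclose(shifted[1:], base[1:], rtol=0, atol=0)


def test_step_consistency_order():
    """Two half steps differ from one full step by O(dt^2) on a smooth
    segment."""
    p = MyocyteParams()
    s = relax_myocyte(p, t_ms=200.0)
    errs = []
    for dt in (0.04, 0.02):
        full = step_cell(s, p, dt, I_stim=-5.0)
        half = step_cell(step_cell(s, p, dt / 2, I_stim=-5.0), p, dt / 2, I_stim=-5.0)
        errs.append(np.max(np.abs(full - half)))
    # halving dt should shrink the consistency error ~4x
    assert errs[1] < 0.4 * errs[0]


def test_step_at_fixed_point_preserves_state():
    """A state with (numerically) zero derivatives stays put to Euler
    accuracy."""
    p = MyocyteParams()
    s = relax_myocyte(p, t_ms=10000.0)
    s2 = step_cell(s, p, 0.02)
    assert np.max(np.abs(s2 - s)) < 1e-6


def test_blowup_detection():
    s = initial_myocyte_state()
    with pytest.raises(IntegrationBlowupError):
        st = s
        for _ in range(2000):
            st = step_cell(st, MyocyteParams(), 0.02, I_stim=-5000.0)


def test_paced_baseline_single_upstroke_no_ead(baseline_last_beat):
    """At x = y = 1 the paced cell fires one clean action potential with
    monotone late repolarization (the no-fibroblast baseline)."""
    m = apd90(baseline_last_beat)[0]
    assert m["captured"] and not m["unrepolarized"]
    assert 200.0 < m["apd90"] < 330.0
    assert count_eads(baseline_last_beat) == 0


def test_gates_remain_bounded_over_paced_run():
    """All 12 gates stay within [0, 1] (up to 1e-9) over a 5 s train."""
    tr = pace_unit(MyocyteParams(x=3.5, y=0.6), n_beats=10, full_trace=True)
    s = tr.meta["final_m_state"]
    assert np.all(s[1:13] > -1e-9) and np.all(s[1:13] < 1.0 + 1e-9)
    # voltage stayed physiological throughout
    assert np.all(np.abs(tr.V_M) < 200.0)


def test_apd90_grid_refinement():
    """APD90 changes by < 1 ms between dt = 0.02 and dt = 0.01."""
    vals = {}
    for dt in (0.02, 0.01):
        tr = pace_unit(MyocyteParams(x=1.0, y=1.0), n_beats=6, dt=dt, rec_stride=1)
        vals[dt] = apd90(tr)[0]["apd90"]
    assert abs(vals[0.02] - vals[0.01]) < 1.0


def test_params_roundtrip(tmp_path):
    p = MyocyteParams(x=2.5, y=0.4)
    p.save(tmp_path / "m.yaml")
    q = MyocyteParams.load(tmp_path / "m.yaml")
    assert p == q
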