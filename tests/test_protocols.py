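"""Stimulation protocols: geometry, triggers, determinism, bookkeeping."""

import numpy as np
import pytest

from cardiofib.myocyte import MyocyteParams, initial_myocyte_state
from cardiofib.tissue import TissueGrid, make_texture
from cardiofib.protocols import (
    StimulusSpec,
    p1_stimulus,
    precondition_p1,
    run_p1,
    run_p2,
    run_ramp,
    s2_stimulus,
)
from cardiofib.profiles import fibroblast_profile


def test_stimulus_region_validation():
    s = StimulusSpec(r0=0, r1=10, c0=0, c1=4)
    s.validate(16)
    with pytest.raises(ValueError):
        StimulusSpec(r0=0, r1=20, c0=0, c1=4).validate(16)
    with pytest.raises(ValueError):
        StimulusSpec(r0=0, r1=4, c0=0, c1=4, duration=0.0).validate(16)


def test_p1_stimulus_geometry_scales_and_fits():
    for L in (32, 128, 1024):
        s = p1_stimulus(L)
        s.validate(L)
        # 6 x 200 at full scale, proportionally reduced otherwise
        assert (s.r1 - s.r0) == max(2, round(200 * L / 1024))
        # centre displaced +L/8 columns
        assert abs((s.c0 + s.c1) / 2 - (L / 2 + L / 8)) <= 1.5


def test_s2_quarter_and_mirror():
    s = s2_stimulus(64, onset=100.0)
    assert (s.r0, s.r1, s.c0, s.c1) == (0, 32, 0, 32)
    m = s2_stimulus(64, onset=100.0, mirrored=True)
    assert (m.r0, m.r1, m.c0, m.c1) == (32, 64, 0, 32)


def test_precondition_zero_waves_is_rest():
    field = precondition_p1(12, n_waves=0)
    assert np.array_equal(field[4, 7], initial_myocyte_state())
    assert field.shape == (12, 12, 19)


def test_precondition_one_wave_gives_normal_ap_afterwards():
    """A preconditioned cell still fires a normal AP (no EAD at x=y=1)."""
    from cardiofib.coupled import pace_unit, apd90, count_eads

    field = precondition_p1(16, n_waves=1, dt=0.05, tail_ms=600.0)
    s = field[8, 8]
    tr = pace_unit(MyocyteParams(x=1.0, y=1.0), n_beats=1, m_state=s)
    m = apd90(tr)[0]
    assert m["captured"] and not m["unrepolarized"]
    assert count_eads(tr) == 0


def test_p2_trigger_fires_and_is_marked():
    grid = TissueGrid(texture=make_texture(48, 0.0, 0), dt=0.05)
    rec = run_p2(grid, t_end=260.0, frame_stride_ms=20.0, probe_stride_ms=5.0)
    assert rec.meta["s2_applied"] and not rec.meta["protocol_failure"]
    assert rec.meta["t_s2"] > 0.0


def test_p2_protocol_failure_when_front_never_crosses():
    grid = TissueGrid(texture=make_texture(32, 0.0, 0), dt=0.05)
    # stimulus too weak to excite: the S1 wave never forms
    rec = run_p2(grid, t_end=120.0, stim_amp=0.5, max_wait_ms=100.0,
                 frame_stride_ms=20.0, probe_stride_ms=5.0)
    assert rec.meta["protocol_failure"] and not rec.meta["s2_applied"]
    from cardiofib.classify import classify_recording, StateLabel

    assert classify_recording(rec, "P2") is StateLabel.PROTOCOL_FAILURE


def test_p1_deterministic_recording_hash():
    def go():
        grid = TissueGrid(texture=make_texture(32, 0.2, seed=11), Gs=1.0,
                          f_params=fibroblast_profile("fibroblast1"), dt=0.05)
        return run_p1(grid, init=None, t_end=150.0, frame_stride_ms=25.0,
                      probe_stride_ms=5.0).content_hash()

    assert go() == go()


def test_ramp_schedule_bookkeeping():
    grid = TissueGrid(texture=make_texture(16, 0.0, 0), D=0.00154 / 16, dt=0.1)
    recs = run_ramp(grid, x_start=1.75, dx_step=0.25, dwell=40.0, x_end=2.25,
                    p2_t_end=40.0, frame_stride_ms=20.0, probe_stride_ms=10.0)
    xs = [r.meta["x"] for r in recs]
    assert xs == [1.75, 2.0, 2.25]
    assert all(r.meta["protocol"] == "P2-ramp" for r in recs)
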