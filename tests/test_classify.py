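"""State classifier: surrogate ground truth, phase singularities,
ectopic localization, ensemble statistics."""

import numpy as np
import pytest

from cardiofib.classify import (
    EctopicEvent,
    StateLabel,
    classify_recording,
    count_phase_singularities,
    locate_first_ectopic,
    phase_singularity_charges,
    ectopic_origin_stats,
)
from cardiofib.surrogates import make_surrogate_recording


@pytest.mark.parametrize(
    "kind,kw,expected",
    [
        ("plane", {}, StateLabel.NO_EAD),
        ("spiral", {}, StateLabel.SW),
        ("multiwavelet", {"full_repol": True}, StateLabel.SF_B),
        ("multiwavelet", {"full_repol": False}, StateLabel.SF_A),
        ("oscillation", {}, StateLabel.OSC),
    ],
)
def test_classifier_on_surrogate_ground_truth(kind, kw, expected):
    """100% label accuracy on the constructed surrogate recordings."""
    rec = make_surrogate_recording(kind, L=48, seed=3, **kw)
    assert classify_recording(rec, "P2") is expected


def test_classifier_deterministic():
    rec = make_surrogate_recording("multiwavelet", L=48, seed=5)
    assert classify_recording(rec, "P2") is classify_recording(rec, "P2")


def test_short_window_is_inconclusive():
    rec = make_surrogate_recording("spiral", L=32, span_ms=800.0)
    assert classify_recording(rec, "P2") is StateLabel.INCONCLUSIVE


def test_phase_singularity_counts():
    plane = make_surrogate_recording("plane", L=48, span_ms=2500.0)
    w = plane.t_frames <= 200.0  # while the wave is crossing
    assert int(np.median(count_phase_singularities(plane.V[w]))) == 0

    spiral = make_surrogate_recording("spiral", L=48)
    assert int(np.median(count_phase_singularities(spiral.V))) == 1


def test_stitched_mirror_field_has_two_cancelling_charges():
    spiral = make_surrogate_recording("spiral", L=48)
    V = spiral.V
    stitched = np.concatenate([V, V[:, :, ::-1]], axis=2)
    counts = count_phase_singularities(stitched)
    charges = phase_singularity_charges(stitched)
    assert int(np.median(counts)) == 2
    assert int(np.median(np.abs(charges))) == 0


def test_locate_first_ectopic_none_for_single_wave():
    rec = make_surrogate_recording("plane", L=48)
    assert locate_first_ectopic(rec) is None


def test_locate_first_ectopic_finds_injected_focal_source():
    L = 48
    rec = make_surrogate_recording("plane", L=L, focal=(1200.0, L // 2, L // 2), dt_frame=2.0)
    ev = locate_first_ectopic(rec)
    assert ev is not None
    assert ev.origin_class == "middle"
    assert abs(ev.row - L // 2) <= 1 and abs(ev.col - L // 2) <= 1


def test_locate_first_ectopic_boundary_band():
    L = 48
    rec = make_surrogate_recording("plane", L=L, focal=(1200.0, 0, L // 2), dt_frame=2.0)
    ev = locate_first_ectopic(rec)
    assert ev is not None and ev.origin_class == "boundary"


def test_ectopic_origin_stats_arithmetic():
    mid = EctopicEvent(1.0, 10, 10, "middle")
    bnd = EctopicEvent(1.0, 0, 10, "boundary")
    assert ectopic_origin_stats([None, None, bnd, mid]) == (50.0, 25.0, 25.0)
    assert ectopic_origin_stats([None, None]) == (100.0, 0.0, 0.0)
    assert sum(ectopic_origin_stats([mid, bnd, None])) == 100.0
    with pytest.raises(ValueError):
        ectopic_origin_stats([])
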