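"""2D lattice: textures, diffusion operator, gap coupling, stepping."""

import numpy as np
import pytest

from cardiofib import _kernels as K
from cardiofib.myocyte import MyocyteParams
from cardiofib.tissue import (
    TissueGrid,
    TissueSim,
    couple_fibroblast_nodes,
    laplacian_step,
    make_texture,
)
from cardiofib.protocols import s1_stimulus, stimuli_to_array
from cardiofib.profiles import fibroblast_profile


def test_texture_exact_count_and_determinism():
    tex = make_texture(100, 0.3, seed=5)
    assert tex.mask.sum() == 3000
    assert np.array_equal(tex.mask, make_texture(100, 0.3, seed=5).mask)
    other = make_texture(100, 0.3, seed=6)
    assert other.mask.sum() == 3000
    assert not np.array_equal(tex.mask, other.mask)
    assert make_texture(50, 0.0, seed=1).mask.sum() == 0
    with pytest.raises(ValueError):
        make_texture(10, 1.0, seed=0)


def test_laplacian_of_constant_field_is_zero():
    L = 40
    V = np.full((L, L), -37.5)
    for phi in (0.0, 0.3):
        mask = make_texture(L, phi, seed=2).mask
        inc = laplacian_step(V, mask, D=0.00154, dx=0.25, dt=0.02)
        assert np.max(np.abs(inc)) == 0.0


def test_diffusion_conserves_total_voltage_under_no_flux():
    L = 32
    rng = np.random.default_rng(3)
    V = rng.uniform(-90.0, 30.0, (L, L))
    for phi in (0.0, 0.25):
        mask = make_texture(L, phi, seed=4).mask
        inc = laplacian_step(V, mask, D=0.00154, dx=0.25, dt=0.02)
        # no-flux operator redistributes but does not create voltage
        assert abs(inc.sum()) < 1e-10 * np.abs(V).sum()
        assert np.all(inc[mask == 1] == 0.0)


def test_gap_coupling_arithmetic_and_conservation():
    L = 9
    tex = make_texture(L, 0.0, seed=0)
    tex.mask[4, 4] = 1  # isolated fibroblast-cluster node
    grid = TissueGrid(texture=tex, Gs=2.0, N_fib=5)
    grid.myo[:, :, K.IV] = -20.0
    grid.fib[:, :, 0] = -50.0
    cur = couple_fibroblast_nodes(grid)
    # fibroblast receives 4 * N * Gs * (V_M - V_F)
    assert cur["fibroblast"][4, 4] == pytest.approx(4 * 5 * 2.0 * 30.0)
    assert cur["myocyte"][4, 3] == pytest.approx(5 * 2.0 * 30.0)
    assert cur["myocyte"].sum() == pytest.approx(cur["fibroblast"].sum())
    # equal voltages: everything zero
    grid.fib[:, :, 0] = -20.0
    cur = couple_fibroblast_nodes(grid)
    assert np.max(np.abs(cur["myocyte"])) == 0.0
    assert np.max(np.abs(cur["fibroblast"])) == 0.0


def test_cfl_guard():
    with pytest.raises(ValueError):
        TissueGrid(texture=make_texture(8, 0.0, 0), dt=0.2)


def _short_run(grid, t_ms=80.0, stim=True):
    sim = TissueSim(grid, frame_stride_ms=10.0, probe_stride_ms=2.0)
    stims = stimuli_to_array([s1_stimulus(grid.L)], grid.L) if stim else None
    sim.advance(t_ms, stims)
    return sim.recording()


def test_decoupled_fibroblasts_equal_pure_obstacles():
    """With Gs = 0, fibroblast nodes affect myocytes only as no-flux
    obstacles; depolarizing the fibroblasts must not matter."""
    L = 32
    tex = make_texture(L, 0.3, seed=7)
    a = TissueGrid(texture=tex, Gs=0.0, f_params=fibroblast_profile("fibroblast1"))
    b = TissueGrid(texture=tex, Gs=0.0, f_params=fibroblast_profile("fibroblast2"))
    b.fib[:, :, 0] = 10.0  # wildly different fibroblast state
    ra = _short_run(a)
    rb = _short_run(b)
    assert np.array_equal(ra.V[:, tex.mask == 0], rb.V[:, tex.mask == 0])


def test_mirror_symmetry_preserved():
    """Symmetric texture + symmetric stimulus gives mirror-symmetric
    voltage fields at all recorded times."""
    L = 32
    tex = make_texture(L, 0.0, seed=0)
    half = np.zeros((L // 2, L), dtype=np.uint8)
    half[3, 10] = half[8, 20] = 1
    tex.mask[:] = np.vstack([half, half[::-1]])
    grid = TissueGrid(texture=tex, Gs=1.0, f_params=fibroblast_profile("fibroblast1"))
    rec = _short_run(grid)
    assert np.array_equal(rec.V, rec.V[:, ::-1, :])


def test_bitwise_reproducibility():
    L = 24
    def go():
        grid = TissueGrid(texture=make_texture(L, 0.2, seed=9), Gs=2.0,
                          f_params=fibroblast_profile("fibroblast1"))
        return _short_run(grid).content_hash()
    assert go() == go()


def test_plane_wave_propagates_and_extinguishes():
    L = 48
    grid = TissueGrid(texture=make_texture(L, 0.0, seed=0), dt=0.05)
    sim = TissueSim(grid, frame_stride_ms=10.0, probe_stride_ms=2.0)
    sim.advance(400.0, stimuli_to_array([s1_stimulus(L)], L))
    V = sim.recording().V
    # front reaches the far edge...
    assert (V[:, :, -1] > 0).any()
    # ...and the medium returns to rest (single wave, no re-excitation)
    assert V[-1].max() < -70.0


def test_conduction_velocity_under_grid_refinement():
    """CV from dx = 0.25 mm and dx = 0.125 mm agree within 10%."""
    res = {}
    for dx, L in ((0.25, 40), (0.125, 80)):
        grid = TissueGrid(texture=make_texture(L, 0.0, seed=0), dx=dx, dt=0.02)
        sim = TissueSim(grid, frame_stride_ms=2.0, probe_stride_ms=2.0)
        sim.advance(60.0, stimuli_to_array([s1_stimulus(L)], L))
        rec = sim.recording()
        # arrival times at 1/4 and 3/4 of the physical width
        cols = [int(0.25 * L), int(0.75 * L)]
        times = []
        for c in cols:
            k = np.argmax((rec.V[:, :, c] > 0).any(axis=1))
            times.append(rec.t_frames[k])
        dist_mm = (cols[1] - cols[0]) * dx
        res[dx] = dist_mm / (times[1] - times[0])
    assert abs(res[0.25] - res[0.125]) / res[0.125] < 0.10
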