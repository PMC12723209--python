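"""Encoding operator, CG-SENSE and motion-corrected reconstruction."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cardiomap.phantom import make_coil_sensitivities
from cardiomap.pipeline import static_motion_model
from cardiomap.recon import (
    KSpaceDataset,
    MotionCorrectedOperator,
    bin_and_correct,
    binned_masks,
    cg_normal,
    fft3,
    ifft3,
    motion_corrected_recon,
    recon_binned,
    translational_phase_ramp,
)
from cardiomap.trajectory import generate_vdcaspr

SHAPE = (16, 16, 8)


def _smooth_image(seed=0, shape=SHAPE):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=shape), 1.5) + 1j * gaussian_filter(
        rng.normal(size=shape), 1.5
    )
    return img


def _dataset_from_image(img, traj, sens, n_echoes=2):
    """Sample FFT(S * img) at trajectory points (test-local forward model)."""
    n_coils = sens.shape[0]
    nx = img.shape[0]
    k = np.stack([fft3(sens[c] * img) for c in range(n_coils)])
    samples = np.zeros(
        (traj.n_heartbeats, traj.n_segments, n_echoes, n_coils, nx), dtype=complex
    )
    for hb in range(traj.n_heartbeats):
        lines = k[:, :, traj.ky[hb], traj.kz[hb]]
        for e in range(n_echoes):
            samples[hb, :, e] = lines.transpose(2, 0, 1)
    return KSpaceDataset(
        samples=samples, trajectory=traj, coil_sensitivities=sens
    )


@pytest.fixture(scope="module")
def full_traj():
    return generate_vdcaspr(16, 8, 1.0, 16, seed=0, n_contrasts=1)


def test_fully_sampled_uniform_coil_recon_is_inverse_fft(full_traj):
    img = _smooth_image()
    sens = np.ones((1,) + SHAPE, dtype=complex)
    ds = _dataset_from_image(img, full_traj, sens)
    k, mask = ds.grid_contrast(0, 0)
    assert mask.all()
    np.testing.assert_allclose(ifft3(k[0]), img, atol=1e-12)
    recon = recon_binned(ds, full_traj.heartbeats_of(0), n_iterations=10)
    assert np.linalg.norm(recon - img) / np.linalg.norm(img) < 1e-6


def test_operator_adjoint_without_warps():
    rng = np.random.default_rng(0)
    sens = make_coil_sensitivities(SHAPE, 4, seed=0)
    mask = rng.uniform(size=(16, 8)) < 0.4
    op = MotionCorrectedOperator(sens, mask[None])
    x = rng.normal(size=SHAPE) + 1j * rng.normal(size=SHAPE)
    y = rng.normal(size=(4,) + SHAPE) + 1j * rng.normal(size=(4,) + SHAPE)
    lhs = np.vdot(y, op.forward(x))
    rhs = np.vdot(op.adjoint(y), x)
    assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-6


def test_operator_adjoint_with_warps():
    rng = np.random.default_rng(1)
    sens = make_coil_sensitivities(SHAPE, 3, seed=1)
    masks = np.zeros((2, 16, 8), dtype=bool)
    masks[0, :8] = True
    masks[1, 8:] = rng.uniform(size=(8, 8)) < 0.5
    fields = rng.normal(scale=1.0, size=(2, 3) + SHAPE)
    op = MotionCorrectedOperator(sens, masks, fields)
    x = rng.normal(size=SHAPE) + 1j * rng.normal(size=SHAPE)
    y = rng.normal(size=(3,) + SHAPE) + 1j * rng.normal(size=(3,) + SHAPE)
    lhs = np.vdot(y, op.forward(x))
    rhs = np.vdot(op.adjoint(y), x)
    assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-5


def test_operator_linearity():
    rng = np.random.default_rng(2)
    sens = make_coil_sensitivities(SHAPE, 3, seed=2)
    masks = (rng.uniform(size=(1, 16, 8)) < 0.5)
    fields = rng.normal(scale=0.7, size=(1, 3) + SHAPE)
    op = MotionCorrectedOperator(sens, masks, fields)
    x, y = _smooth_image(3), _smooth_image(4)
    a, b = 1.7 - 0.3j, -0.8 + 2.1j
    np.testing.assert_allclose(
        op.forward(a * x + b * y),
        a * op.forward(x) + b * op.forward(y),
        atol=1e-12,
    )


def test_cg_residual_monotone_and_undersampled_beats_zero_fill():
    rng = np.random.default_rng(3)
    img = np.abs(_smooth_image(5))
    sens = make_coil_sensitivities(SHAPE, 8, seed=3)
    traj = generate_vdcaspr(16, 8, 4.0, 16, seed=3, n_contrasts=1)
    ds = _dataset_from_image(img.astype(complex), traj, sens)
    k, mask = ds.grid_contrast(0, 0)
    op = MotionCorrectedOperator(sens, mask[None])
    x, history = cg_normal(op, k * mask[None, None], n_iterations=3)
    assert np.all(np.diff(history) <= 1e-9)
    zero_fill = np.sum(
        np.conj(sens) * np.stack([ifft3(k[c] * mask[None]) for c in range(8)]),
        axis=0,
    )
    nrmse = lambda a: np.linalg.norm(a - img) / np.linalg.norm(img)
    assert nrmse(x) < nrmse(zero_fill)


def test_binned_masks_reassemble_full_mask():
    traj = generate_vdcaspr(16, 8, 2.0, 16, seed=4, n_contrasts=2)
    n_hb = traj.n_heartbeats
    rng = np.random.default_rng(4)
    tr = np.column_stack([np.sort(rng.normal(size=n_hb)), np.zeros(n_hb)])
    sens = make_coil_sensitivities(SHAPE, 2, seed=4)
    samples = np.zeros((n_hb, 16, 2, 2, 16), dtype=complex)
    ds = KSpaceDataset(samples=samples, trajectory=traj, coil_sensitivities=sens)
    _, motion = bin_and_correct(ds, tr, n_bins=3)
    for c in range(2):
        masks = binned_masks(ds, motion, c)
        # disjoint and reassembling
        assert np.all(masks.sum(axis=0) <= 1)
        np.testing.assert_array_equal(masks.any(axis=0), traj.mask(c))


def test_phase_ramp_round_trip_point_object():
    """Shifted point object realigns to < 0.2 voxel after bin correction."""
    img = np.zeros(SHAPE, dtype=complex)
    img[8, 8, 4] = 1.0
    sens = np.ones((1,) + SHAPE, dtype=complex)
    traj = generate_vdcaspr(16, 8, 1.0, 16, seed=5, n_contrasts=1)
    ds = _dataset_from_image(img, traj, sens)
    # impose known per-heartbeat shifts in k-space (as breathing would)
    shifts = np.linspace(-3.0, 0.0, traj.n_heartbeats)  # FH mm, 2 mm voxels
    samples = ds.samples.copy()
    for hb in range(traj.n_heartbeats):
        ramp = translational_phase_ramp(
            (0.0, shifts[hb] / 2.0), traj.ky[hb], traj.kz[hb], traj.grid_shape
        )
        samples[hb] *= ramp[:, None, None, None]
    moved = KSpaceDataset(
        samples=samples, trajectory=traj, coil_sensitivities=sens
    )
    tr = np.column_stack([shifts, np.zeros_like(shifts)])
    corrected, motion = bin_and_correct(moved, tr, n_bins=2)
    for b in range(2):
        hbs = [h for h in range(traj.n_heartbeats) if motion.bin_of_hb[h] == b]
        k, mask = corrected.grid_contrast(0, 0, heartbeats=hbs)
        rec = ifft3(k[0])
        peak = np.unravel_index(np.argmax(np.abs(rec)), SHAPE)
        expected_z = 4 + motion.bin_medians_mm[b, 0] / 2.0
        assert abs(peak[2] - expected_z) <= 0.5  # integer peak within half voxel
        # subvoxel check via centre of mass around the peak
        zprof = np.abs(rec[8, 8, :])
        com = np.sum(np.arange(8) * zprof) / np.sum(zprof)
        assert abs(com - expected_z) < 0.2


def test_zero_motion_equals_pooled_sense():
    img = _smooth_image(6)
    sens = make_coil_sensitivities(SHAPE, 4, seed=6)
    traj = generate_vdcaspr(16, 8, 2.0, 16, seed=6, n_contrasts=4)
    ds = _dataset_from_image(img, traj, sens)
    n_hb = traj.n_heartbeats
    pooled = motion_corrected_recon(
        ds, static_motion_model(n_hb), n_iterations=4, contrasts=[0], echoes=[0]
    )[0, 0]
    # five bins, zero displacement everywhere, zero fields
    _, motion = bin_and_correct(ds, np.zeros((n_hb, 2)), n_bins=5)
    motion.fields = motion.identity_fields(SHAPE)
    binned = motion_corrected_recon(
        ds, motion, n_iterations=4, contrasts=[0], echoes=[0]
    )[0, 0]
    np.testing.assert_allclose(binned, pooled, atol=1e-8)


def test_empty_bin_and_zero_sensitivities_rejected(full_traj):
    img = _smooth_image(7)
    sens = np.ones((1,) + SHAPE, dtype=complex)
    ds = _dataset_from_image(img, full_traj, sens)
    with pytest.raises(ValueError):
        recon_binned(ds, np.array([], dtype=int))
    ds_bad = KSpaceDataset(
        samples=ds.samples, trajectory=full_traj,
        coil_sensitivities=np.zeros_like(sens),
    )
    with pytest.raises(ValueError):
        recon_binned(ds_bad, full_traj.heartbeats_of(0))
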