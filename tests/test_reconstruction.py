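"""Cumulant reconstruction chain, RL deconvolution, FRC."""

import numpy as np
import pytest
from scipy import fft as sfft

from axisim.optics import OpticalConfig, MirrorConfig, PSFVolume, \
    detection_psf
from axisim.phantoms import AcquisitionPlan, NoiseModel, acquire_stack, \
    make_beads
from axisim.preprocess import subtract_offset
from axisim.reconstruction import (
    FRCResult, ReconConfig, brightness_linearize, dsi_weight,
    fourier_interpolate, frc_resolution, reconstruct_layer,
    reconstruct_volume, reweight_linearize, rl_deconvolve,
    select_rl_iterations, temporal_cumulant, z_flatten,
)


# ---------------------------------------------------------------------------
# elementary operations


def test_rl_delta_kernel_identity(rng):
    img = rng.random((32, 32)) * 100.0
    psf = np.zeros((32, 32))
    psf[16, 16] = 1.0
    out = rl_deconvolve(img, psf, 10)
    assert np.abs(out - img).max() < 1e-9 * img.max()


def test_rl_nonnegative_and_batched(rng):
    imgs = rng.random((3, 16, 16))
    psf = np.abs(rng.random((16, 16)))
    out = rl_deconvolve(imgs, psf, 5)
    assert out.shape == imgs.shape
    assert np.all(out >= 0)
    single = rl_deconvolve(imgs[1], psf, 5)
    assert np.allclose(out[1], single)


def test_rl_sharpens_blurred_point():
    psf = np.zeros((32, 32))
    yy, xx = np.mgrid[-16:16, -16:16]
    psf = np.exp(-(yy**2 + xx**2) / 8.0)
    psf /= psf.sum()
    truth = np.zeros((32, 32))
    truth[16, 16] = 1.0
    H = sfft.fft2(np.fft.ifftshift(psf))
    blurred = np.real(sfft.ifft2(sfft.fft2(truth) * H))
    dec = rl_deconvolve(blurred, psf, 50)
    assert dec.max() > 2.0 * blurred.max()


def test_rl_validates_iterations(rng):
    with pytest.raises(ValueError):
        rl_deconvolve(rng.random((8, 8)), np.ones((8, 8)), 0)


def test_dsi_weight_examples():
    frames = np.full((5, 4, 4), 3.0)
    assert np.allclose(dsi_weight(frames), 3.0)
    series = np.array([0.0, 0.0, 3.0])[:, None, None]
    assert np.allclose(dsi_weight(series), np.sqrt(3.0))


def test_dsi_weight_sectioning_like_contrast():
    # higher temporal fluctuation -> larger W at equal mean
    steady = np.full((50, 1, 1), 1.0)
    flicker = np.zeros((50, 1, 1))
    flicker[::2] = 2.0                      # mean 1, fluctuating
    assert dsi_weight(flicker)[0, 0] > dsi_weight(steady)[0, 0]


def test_reweight_linearize_sqrt():
    frames = np.full((2, 3, 3), 4.0)
    w = np.full((3, 3), 9.0)
    assert np.allclose(reweight_linearize(frames, w), 6.0)
    with pytest.raises(ValueError):
        reweight_linearize(frames, np.ones((2, 2)))


def test_fourier_interpolate_preserves_samples(rng):
    a = rng.random((16, 16))
    up = fourier_interpolate(a, 2)
    assert up.shape == (32, 32)
    assert np.abs(up[::2, ::2] - a).max() < 1e-12
    assert np.isclose(up.mean(), a.mean())


def test_fourier_interpolate_batch_and_identity(rng):
    a = rng.random((3, 8, 8))
    assert np.array_equal(fourier_interpolate(a, 1), a)
    up = fourier_interpolate(a, 2)
    assert up.shape == (3, 16, 16)


def test_temporal_cumulant_matches_brute_force(rng):
    f = rng.random((9, 4, 4))
    for order, lag in [(2, 0), (2, 1), (3, 0), (3, 2)]:
        d = f - f.mean(axis=0)
        n = f.shape[0] - (order - 1) * lag
        if order == 2:
            brute = np.mean([d[t] * d[t + lag] for t in range(n)], axis=0)
        else:
            brute = np.mean([d[t] * d[t + lag] * d[t + 2 * lag]
                             for t in range(n)], axis=0)
        assert np.abs(temporal_cumulant(f, order, lag) - brute).max() < 1e-10


def test_temporal_cumulant_worked_example():
    series = np.array([0.0, 0.0, 3.0])[:, None]
    assert np.allclose(temporal_cumulant(series, 2), 2.0)   # var of {-1,-1,2}
    assert np.allclose(temporal_cumulant(series, 3), 2.0)   # third moment
    with pytest.raises(ValueError):
        temporal_cumulant(series, 3, lag=2)                 # span too long
    with pytest.raises(ValueError):
        temporal_cumulant(series, 4)


def test_brightness_linearize_constant_fixed_point():
    zz, yy, xx = np.mgrid[-4:4, -4:4, -4:4].astype(float)
    psf = np.exp(-(zz**2 + yy**2 + xx**2) / 4.0)
    psf /= psf.sum()
    out = brightness_linearize(np.full((8, 8, 8), 8.0), psf, 3, 5)
    assert np.abs(out - 2.0).max() < 1e-6


def test_brightness_linearize_order_one_is_rl_reconvolve(rng):
    zz, yy, xx = np.mgrid[-4:4, -4:4, -4:4].astype(float)
    psf = np.exp(-(zz**2 + yy**2 + xx**2) / 4.0)
    psf /= psf.sum()
    vol = rng.random((8, 8, 8))
    out1 = brightness_linearize(vol, psf, 1, 3)
    dec = rl_deconvolve(vol, psf, 3)
    H = sfft.fftn(np.fft.ifftshift(psf))
    recon = np.clip(sfft.ifftn(sfft.fftn(dec) * H).real, 0, None)
    assert np.allclose(out1, recon, atol=1e-12)
    assert np.all(out1 >= 0)
    with pytest.raises(ValueError):
        brightness_linearize(vol, psf, 0, 3)


def test_z_flatten_equalizes_scaled_slices(rng):
    pattern = rng.random((6, 6)) + 0.2
    gains = np.array([1.0, 2.0, 4.0])
    vol = gains[:, None, None] * pattern[None]
    flat = z_flatten(vol)
    assert np.allclose(flat[0], flat[1], rtol=1e-9)
    assert np.allclose(flat[1], flat[2], rtol=1e-9)
    assert np.isclose(flat.max(), vol.max())
    with pytest.raises(ValueError):
        z_flatten(vol[:2])


# ---------------------------------------------------------------------------
# FRC


def test_frc_matches_analytic_crossing(rng):
    ny = nx = 256
    fy = sfft.fftfreq(ny)[:, None]
    fx = sfft.fftfreq(nx)[None, :]
    r = np.hypot(fy, fx)
    for fc, sn in [(0.15, 0.5), (0.25, 0.5)]:
        G = np.exp(-((r / fc) ** 2))
        shared = sfft.ifft2(sfft.fft2(rng.standard_normal((ny, nx))) * G).real
        a = shared + sn * rng.standard_normal((ny, nx))
        b = shared + sn * rng.standard_normal((ny, nx))
        # true FRC(f) = G^2/(G^2 + sn^2); 1/7 crossing where G^2 = sn^2/6
        f_star = fc * np.sqrt(np.log(6.0 / sn**2) / 2.0)
        expected = 1.0 / f_star
        got = frc_resolution(a, b, 1.0)
        assert got.flag == "ok"
        assert abs(got.resolution - expected) / expected < 0.15


def test_frc_identical_images_unresolved_flag(rng):
    img = rng.random((128, 128))
    res = frc_resolution(img, img + 1e-12 * rng.random((128, 128)), 1.0)
    assert res.flag == "unresolved-at-Nyquist"
    assert np.isclose(res.resolution, 2.0)


def test_frc_pure_noise_uncorrelated_flag(rng):
    a = rng.standard_normal((256, 256))
    b = rng.standard_normal((256, 256))
    res = frc_resolution(a, b, 1.0)
    assert res.flag == "uncorrelated"
    # beyond the first rings the noise floor stays well below threshold
    assert np.abs(res.curve[3:]).max() < 0.1


def test_frc_validates_shapes(rng):
    with pytest.raises(ValueError):
        frc_resolution(rng.random((8, 8)), rng.random((8, 9)), 1.0)


# ---------------------------------------------------------------------------
# layer / volume reconstruction


def _tiny_acquisition(seed=31, frames=6, layers=4, noise=True):
    grid = (24, 32, 32)
    opt = OpticalConfig(grid_shape=grid, lateral_spacing=40.0,
                        axial_spacing=25.0)
    ph = make_beads(2, 100.0, grid, 40.0, 25.0, seed=3, margin_nm=0.0)
    plan = AcquisitionPlan(frames_per_layer=frames, z_step=25.0,
                           n_layers=layers)
    nm = NoiseModel() if noise else None
    raw = acquire_stack(ph, plan, opt, MirrorConfig(), nm, seed=seed)
    if nm is not None:
        raw = subtract_offset(raw, nm.offset)
    det = detection_psf(OpticalConfig(
        grid_shape=(layers + 1, grid[1], grid[2]), lateral_spacing=40.0,
        axial_spacing=25.0))
    return raw, det


def test_reconstruct_layer_shapes_and_nonnegativity():
    raw, det = _tiny_acquisition()
    cfg = ReconConfig(order=3, rl_iters_3d=2)
    cum, dl, info = reconstruct_layer(raw.data[:, 0], det, cfg)
    assert cum.shape == (64, 64)           # upsampled x2
    assert dl.shape == (32, 32)
    assert np.all(cum >= 0) and np.all(dl >= 0)
    assert 0.0 <= info["negative_cumulant_fraction"] <= 1.0


def test_reconstruct_volume_provenance_and_determinism():
    raw, det = _tiny_acquisition()
    cfg = ReconConfig(order=3, rl_iters_3d=3, z_flatten=False,
                      linearize_brightness=False)
    r1, dl1 = reconstruct_volume(raw, det, cfg)
    r2, dl2 = reconstruct_volume(raw, det, cfg)
    assert np.array_equal(r1.data, r2.data)
    assert np.array_equal(dl1.data, dl2.data)
    assert r1.data.shape == (4, 64, 64)
    assert r1.lateral_spacing == 20.0
    for key in ("config_digest", "rl_iters_3d", "clipped_fraction",
                "negative_cumulant_fraction", "master_seed"):
        assert key in r1.provenance
    assert r1.provenance["rl_iters_3d"] == 3
    assert r1.provenance["master_seed"] == 31


def test_reconstruct_volume_rejects_psf_spacing_mismatch():
    raw, _ = _tiny_acquisition()
    det = detection_psf(OpticalConfig(grid_shape=(5, 32, 32),
                                      lateral_spacing=40.0,
                                      axial_spacing=20.0))
    with pytest.raises(ValueError, match="z-scan step"):
        reconstruct_volume(raw, det, ReconConfig(rl_iters_3d=2))


def test_recon_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(order=4)
    with pytest.raises(ValueError):
        ReconConfig(rl_iters_3d="sometimes")
    with pytest.raises(ValueError):
        ReconConfig(upsample_factor=0)
    a = ReconConfig()
    assert a.digest() == ReconConfig().digest()
    assert a.digest() != ReconConfig(order=2).digest()


def test_select_rl_iterations_noise_free_runs_to_max():
    raw, det = _tiny_acquisition(noise=False)
    cfg = ReconConfig(order=2)
    chosen = select_rl_iterations(raw, det, cfg, max_iters=6)
    assert chosen == 6


def test_select_rl_iterations_needs_four_frames():
    raw, det = _tiny_acquisition(frames=3)
    with pytest.raises(ValueError):
        select_rl_iterations(raw, det, ReconConfig(), 4)
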