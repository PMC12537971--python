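"""Speckle synthesis, detection PSF, autocorrelations, FWHM."""

import math

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from axisim.optics import (
    MirrorConfig, OpticalConfig, autocorrelation_3d,
    autocorrelation_axis_profile, detection_psf, effective_psf_profiles,
    effective_speckle_psf, fwhm, sample_pupil, synthesize_speckle,
)


# ---------------------------------------------------------------------------
# configuration invariants


def test_optical_config_rejects_undersampling():
    with pytest.raises(ValueError, match="undersamples"):
        OpticalConfig(lateral_spacing=200.0)


def test_optical_config_rejects_na_above_immersion():
    with pytest.raises(ValueError):
        OpticalConfig(numerical_aperture=1.6, n_immersion=1.518)


def test_mirror_config_bounds():
    with pytest.raises(ValueError):
        MirrorConfig(reflectance=1.5)
    with pytest.raises(ValueError):
        MirrorConfig(tilt_deg=20.0)
    with pytest.raises(ValueError):
        MirrorConfig(gap_distance=-1.0)


# ---------------------------------------------------------------------------
# pupil sampling


def test_pupil_seeding_deterministic(small_optics):
    a = sample_pupil(small_optics, 7)
    b = sample_pupil(small_optics, 7)
    assert np.array_equal(a.amplitude, b.amplitude)


def test_pupils_decorrelated_across_seeds():
    opt = OpticalConfig(grid_shape=(4, 256, 256))
    a = sample_pupil(opt, 7).amplitude.ravel()
    b = sample_pupil(opt, 8).amplitude.ravel()
    m = (a != 0) & (b != 0)
    assert m.sum() >= 1000
    rho = np.corrcoef(a[m].real, b[m].real)[0, 1]
    assert abs(rho) < 0.1


def test_pupil_support_matches_brute_force(small_optics):
    pupil = sample_pupil(small_optics, 3)
    k_na = small_optics.numerical_aperture * small_optics.k0_exc
    count = 0
    for ky in pupil.ky:
        for kx in pupil.kx:
            if math.hypot(ky, kx) <= k_na:
                count += 1
    assert int(np.count_nonzero(pupil.amplitude)) == count


def test_pupil_single_sample_is_dc():
    # the DC sample always lies inside the NA disk, so the smallest
    # possible support is one sample (the degenerate plane-wave limit)
    opt = OpticalConfig(numerical_aperture=0.01, lateral_spacing=100.0,
                        grid_shape=(8, 4, 4))
    pupil = sample_pupil(opt, 0)
    assert int(np.count_nonzero(pupil.amplitude)) == 1
    assert pupil.amplitude[0, 0] != 0


# ---------------------------------------------------------------------------
# speckle synthesis


def test_plane_wave_limit_constant_magnitude():
    # NA so small that the pupil disk is one sample -> a single plane wave
    opt = OpticalConfig(numerical_aperture=0.01, lateral_spacing=100.0,
                        axial_spacing=10.0, grid_shape=(64, 8, 8))
    pupil = sample_pupil(opt, 3)
    assert int(np.count_nonzero(pupil.amplitude)) == 1
    sp = synthesize_speckle(pupil, opt, None)
    assert np.ptp(sp.data) < 1e-9 * sp.data.max()


def test_standing_wave_period_matches_half_wavelength_in_medium():
    opt = OpticalConfig(numerical_aperture=0.01, lateral_spacing=100.0,
                        axial_spacing=10.0, grid_shape=(256, 8, 8))
    pupil = sample_pupil(opt, 3)
    sp = synthesize_speckle(pupil, opt, MirrorConfig(reflectance=1.0))
    prof = sp.data[:, 0, 0]
    prof = prof - prof.mean()
    z = np.arange(len(prof)) * opt.axial_spacing
    k0 = np.argmax(np.abs(np.fft.rfft(prof))[1:]) + 1
    f0 = k0 / (len(prof) * opt.axial_spacing)
    popt, _ = curve_fit(lambda z, a, f, p: a * np.cos(2 * np.pi * f * z + p),
                        z, prof, p0=[prof.std() * np.sqrt(2), f0, 0.0])
    period = 1.0 / popt[1]
    expected = opt.wavelength_exc / (2.0 * opt.n_sample)   # 183.5 nm
    assert abs(period - expected) < 1.0


def test_mirror_off_equals_zero_reflectance_bitwise(small_optics):
    pupil = sample_pupil(small_optics, 11)
    off = synthesize_speckle(pupil, small_optics, None)
    r0 = synthesize_speckle(pupil, small_optics,
                            MirrorConfig(reflectance=0.0))
    disabled = synthesize_speckle(pupil, small_optics,
                                  MirrorConfig(enabled=False))
    assert np.array_equal(off.data, r0.data)
    assert np.array_equal(off.data, disabled.data)


def test_mirror_changes_field(small_optics, mirror):
    pupil = sample_pupil(small_optics, 11)
    on = synthesize_speckle(pupil, small_optics, mirror)
    off = synthesize_speckle(pupil, small_optics, None)
    assert not np.allclose(on.data, off.data)


def test_evanescent_components_dropped(small_optics):
    # NA 1.49 exceeds n_sample 1.33: some pupil samples are evanescent
    pupil = sample_pupil(small_optics, 5)
    sp = synthesize_speckle(pupil, small_optics, None)
    k_perp = pupil.k_perp
    expected = int(np.count_nonzero(
        (pupil.amplitude != 0) & (k_perp > small_optics.k_sample)))
    assert expected > 0
    assert sp.n_evanescent_dropped == expected


def test_speckle_nonnegative_finite(small_optics, mirror):
    sp = synthesize_speckle(sample_pupil(small_optics, 1), small_optics,
                            mirror)
    assert np.all(np.isfinite(sp.data))
    assert np.all(sp.data >= 0)


def test_speckle_contrast_fully_developed(small_optics):
    # fully developed speckle: std/mean of intensity ~ 1 (without mirror)
    sp = synthesize_speckle(sample_pupil(small_optics, 2), small_optics,
                            None)
    contrast = sp.data.std() / sp.data.mean()
    assert 0.8 < contrast < 1.2


def test_bad_apodization_rejected(small_optics):
    pupil = sample_pupil(small_optics, 1)
    with pytest.raises(ValueError, match="apodization"):
        synthesize_speckle(pupil, small_optics, None, apodization="foo")


# ---------------------------------------------------------------------------
# detection PSF


def test_detection_psf_lateral_fwhm_near_theory(small_optics, small_det_psf):
    c = small_det_psf.center
    prof = small_det_psf.data[c[0], c[1], :]
    w = fwhm(prof, small_optics.lateral_spacing)
    theory = 0.514 * small_optics.wavelength_em / small_optics.numerical_aperture
    assert abs(w - theory) / theory < 0.05


def test_detection_psf_normalized_and_symmetric(small_det_psf):
    assert np.isclose(small_det_psf.data.sum(), 1.0)
    d = small_det_psf.data
    c = small_det_psf.center
    assert np.allclose(d[c[0], c[1], :], d[c[0], :, c[2]], atol=1e-10)


# ---------------------------------------------------------------------------
# autocorrelations


def test_autocorrelation_3d_matches_direct_lag_sums(rng):
    v = rng.random((4, 5, 3))
    ac = autocorrelation_3d(v)
    nz, ny, nx = v.shape
    for lag in [(0, 0, 0), (1, 0, 0), (0, 2, 1), (-1, 1, -1), (2, -3, 2)]:
        s = 0.0
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    z2, y2, x2 = z + lag[0], y + lag[1], x + lag[2]
                    if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                        s += v[z, y, x] * v[z2, y2, x2]
        center = tuple((np.array(ac.shape) - 1) // 2)
        got = ac[center[0] + lag[0], center[1] + lag[1], center[2] + lag[2]]
        assert abs(got - s) < 1e-10 * max(1.0, abs(s))


def test_axis_profile_equals_central_line(rng):
    v = rng.random((5, 4, 6))
    full = autocorrelation_3d(v)
    c = tuple((np.array(full.shape) - 1) // 2)
    for axis in range(3):
        prof = autocorrelation_axis_profile(v, axis)
        sl = [c[0], c[1], c[2]]
        sl[axis] = slice(None)
        assert np.allclose(prof, full[tuple(sl)], atol=1e-10)


def test_effective_psf_profiles_match_full_autocorrelation(small_optics,
                                                           small_det_psf,
                                                           mirror):
    sp = synthesize_speckle(sample_pupil(small_optics, 4), small_optics,
                            mirror)
    eff = effective_speckle_psf(sp, small_det_psf)
    ax, lat = effective_psf_profiles(sp, small_det_psf)
    c = eff.center
    cz, cy, cx = ((np.array(eff.data.shape) - 1) // 2)
    assert np.allclose(ax, eff.data[:, cy, cx] / eff.data[:, cy, cx].max(),
                       atol=1e-9)
    assert np.allclose(lat, eff.data[cz, cy, :] / eff.data[cz, cy, :].max(),
                       atol=1e-9)


def test_mirror_confines_effective_psf(small_optics, small_det_psf, mirror):
    pupil = sample_pupil(small_optics, 9)
    ax_on, _ = effective_psf_profiles(
        synthesize_speckle(pupil, small_optics, mirror), small_det_psf)
    ax_off, _ = effective_psf_profiles(
        synthesize_speckle(pupil, small_optics, None), small_det_psf)
    w_on = fwhm(ax_on, small_optics.axial_spacing)
    w_off = fwhm(ax_off, small_optics.axial_spacing)
    # small grid truncates the mirror-off profile; still a clear confinement
    assert w_off / w_on > 2.0


# ---------------------------------------------------------------------------
# FWHM


def test_fwhm_gaussian_analytic():
    x = np.arange(-600, 601, 1.0)
    sigma = 100.0
    w = fwhm(np.exp(-x**2 / (2 * sigma**2)), 1.0)
    assert abs(w - 2.3548 * sigma) < 0.2


def test_fwhm_triangle_exact():
    x = np.arange(-600, 601, 1.0)
    w = fwhm(np.clip(1.0 - np.abs(x) / 300.0, 0, None), 1.0)
    assert abs(w - 300.0) < 1e-9


def test_fwhm_fringe_uses_local_baseline():
    # cos^2 fringe under a triangular envelope: the relevant width is the
    # central fringe's, measured against the flanking minima
    x = np.arange(-300, 301, 1.0)
    p = (1.0 - np.abs(x) / 400.0) * np.cos(np.pi * x / 200.0) ** 2
    w = fwhm(p, 1.0)
    # analytic half crossing of (1 - x/400) cos^2(pi x / 200): x = 45.87
    assert abs(w - 91.73) < 1.0


def test_fwhm_global_baseline_robust_to_flank_notch():
    x = np.arange(-600, 601, 1.0)
    p = np.exp(-x**2 / (2 * 100.0**2))
    p[660] *= 0.9       # small notch at x = +60 on the flank
    w_global = fwhm(p, 1.0, baseline="global")
    assert abs(w_global - 235.48) < 1.5
    # the local rule mistakes the notch for a fringe minimum and cannot
    # cross the resulting high baseline — the motivation for "global"
    with pytest.raises(ValueError, match="never crossed"):
        fwhm(p, 1.0)


def test_fwhm_errors():
    with pytest.raises(ValueError, match="endpoint"):
        fwhm(np.array([3.0, 2.0, 1.0]), 1.0)
    with pytest.raises(ValueError, match="not unique"):
        fwhm(np.array([0.0, 1.0, 1.0, 0.0]), 1.0)
    with pytest.raises(ValueError, match="baseline"):
        fwhm(np.array([0.0, 1.0, 0.0]), 1.0, baseline="bogus")
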