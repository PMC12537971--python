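"""Coherent speckle-field synthesis and point-spread-function models.

A rotating ground-glass diffuser produces a random coherent field whose
angular spectrum fills the objective's back aperture.  Placing a mirror a
short distance above the sample adds a counter-propagating copy of every
plane-wave component; the interference of the two branches imprints fine
axial structure (period ~ lambda / 2n) on the speckle, which axially
confines the *effective speckle PSF* -- the autocorrelation of the product
of the illumination intensity and the detection PSF.  That kernel sets the
resolution of fluctuation-based (cumulant) reconstruction.

The field model is scalar angular-spectrum superposition: each pupil
component A(kx, ky) propagates with kz = sqrt((n k0)^2 - k_perp^2);
evanescent components (k_perp > n k0) are dropped.  The mirror branch is
A(k) * r * exp(i kz (2d - z)), with an optional tilt implemented as a
transverse frequency shift of the reflected pupil.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal
from scipy.special import j0

logger = logging.getLogger(__name__)

__all__ = [
    "OpticalConfig",
    "MirrorConfig",
    "PupilField",
    "SpeckleVolume",
    "PSFVolume",
    "sample_pupil",
    "synthesize_speckle",
    "detection_psf",
    "autocorrelation_3d",
    "autocorrelation_axis_profile",
    "effective_speckle_psf",
    "effective_psf_profiles",
    "fwhm",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Physical description of the excitation/detection optics and grid.

    Lengths are in nanometres.  ``grid_shape`` is (nz, ny, nx).
    """

    wavelength_exc: float = 488.0
    wavelength_em: float = 520.0
    numerical_aperture: float = 1.49
    n_immersion: float = 1.518
    n_sample: float = 1.33
    lateral_spacing: float = 40.0
    axial_spacing: float = 20.0
    grid_shape: tuple[int, int, int] = (96, 128, 128)

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0:
            raise ValueError("numerical_aperture must be positive")
        if self.numerical_aperture > self.n_immersion:
            raise ValueError("numerical_aperture cannot exceed n_immersion")
        if self.lateral_spacing <= 0 or self.axial_spacing <= 0:
            raise ValueError("voxel spacings must be positive")
        nyquist = self.wavelength_exc / (2.0 * self.numerical_aperture)
        if self.lateral_spacing > nyquist:
            raise ValueError(
                f"lateral_spacing {self.lateral_spacing} nm undersamples the "
                f"speckle (Nyquist limit {nyquist:.1f} nm)"
            )
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")

    @property
    def k0_exc(self) -> float:
        """Vacuum angular wavenumber of the excitation, rad/nm."""
        return 2.0 * math.pi / self.wavelength_exc

    @property
    def k_sample(self) -> float:
        """Excitation wavenumber inside the sample medium, rad/nm."""
        return self.n_sample * self.k0_exc


@dataclass(frozen=True)
class MirrorConfig:
    """Back-reflecting mirror above the sample.

    ``gap_distance`` is the height of the mirror plane above z = 0 (nm);
    ``reflectance`` is a scalar amplitude coefficient (0.97 ~ protected
    silver); ``tilt_deg`` tips the reflected branch in the x direction.
    """

    enabled: bool = True
    gap_distance: float = 100_000.0
    reflectance: float = 0.97
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_distance < 0:
            raise ValueError("gap_distance must be >= 0")
        if not 0.0 <= self.reflectance <= 1.0:
            raise ValueError("reflectance must lie in [0, 1]")
        if abs(self.tilt_deg) > 15.0:
            raise ValueError("tilt_deg must be within +/-15 degrees")


@dataclass
class PupilField:
    """Complex pupil amplitudes on the (ky, kx) frequency grid (rad/nm)."""

    amplitude: np.ndarray          # complex (ny, nx), fftfreq ordering
    kx: np.ndarray                 # (nx,) rad/nm
    ky: np.ndarray                 # (ny,) rad/nm
    seed: int

    @property
    def k_perp(self) -> np.ndarray:
        return np.hypot(self.ky[:, None], self.kx[None, :])


@dataclass
class SpeckleVolume:
    """Non-negative 3-D excitation intensity on the optics grid."""

    data: np.ndarray               # (nz, ny, nx) float64, >= 0
    lateral_spacing: float
    axial_spacing: float
    n_evanescent_dropped: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("speckle intensity must be finite")
        if np.any(self.data < 0):
            raise ValueError("speckle intensity must be non-negative")


@dataclass
class PSFVolume:
    """Non-negative 3-D PSF with its grid spacings and normalization mode."""

    data: np.ndarray
    lateral_spacing: float
    axial_spacing: float
    normalization: str = "unit-sum"   # or "unit-peak"

    @property
    def center(self) -> tuple[int, ...]:
        return tuple(s // 2 for s in self.data.shape)


def sample_pupil(optics: OpticalConfig, seed: int) -> PupilField:
    """Draw a random diffuser pupil: circular-Gaussian amplitudes on the NA disk.

    Fully developed speckle corresponds to i.i.d. complex-normal pupil
    samples inside k_perp <= NA * k0 and zero outside.  Identical seeds
    give bitwise-identical pupils.
    """
    nz, ny, nx = optics.grid_shape
    dk = 2.0 * math.pi
    kx = dk * sfft.fftfreq(nx, d=optics.lateral_spacing)
    ky = dk * sfft.fftfreq(ny, d=optics.lateral_spacing)
    k_perp = np.hypot(ky[:, None], kx[None, :])
    k_na = optics.numerical_aperture * optics.k0_exc
    mask = k_perp <= k_na
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError(
            "NA disk contains no frequency samples on this grid; enlarge the "
            "grid or the NA"
        )
    rng = np.random.default_rng(seed)
    amp = np.zeros((ny, nx), dtype=np.complex128)
    # draw in a fixed (row-major) order for reproducibility
    re = rng.standard_normal(n_in)
    im = rng.standard_normal(n_in)
    amp[mask] = (re + 1j * im) / math.sqrt(2.0)
    return PupilField(amplitude=amp, kx=kx, ky=ky, seed=seed)


def _shift_pupil(amp: np.ndarray, kx: np.ndarray, shift_rad_per_nm: float) -> np.ndarray:
    """Shift a pupil along kx by the nearest whole frequency bin (no wrap)."""
    if shift_rad_per_nm == 0.0:
        return amp
    dk = abs(kx[1] - kx[0]) if len(kx) > 1 else None
    if dk is None or dk == 0.0:
        return amp
    nbins = int(round(shift_rad_per_nm / dk))
    if nbins == 0:
        return amp
    # shift on the fftshifted axis so it is a plain translation; columns
    # pushed off the edge are unphysical and must not wrap around
    amp_s = np.fft.fftshift(amp, axes=1)
    out_s = np.zeros_like(amp_s)
    if nbins > 0:
        out_s[:, nbins:] = amp_s[:, :-nbins]
    else:
        out_s[:, :nbins] = amp_s[:, -nbins:]
    return np.fft.ifftshift(out_s, axes=1)


def synthesize_speckle(
    pupil: PupilField,
    optics: OpticalConfig,
    mirror: MirrorConfig | None = None,
    apodization: str = "aplanatic",
) -> SpeckleVolume:
    """Propagate a pupil through the sample volume, optionally adding the
    mirror-reflected branch, and return the 3-D excitation intensity.

    Per z-plane the field is the inverse transform of

        A(k) e^{i kz z}  +  r A_tilt(k) e^{i kz (2 d - z)}

    with kz = sqrt((n k0)^2 - k_perp^2).  Components with k_perp > n k0 are
    evanescent in the sample and are excluded (their count is logged).
    A mirror tilt shifts the reflected pupil transversely by 2 n k0 sin(tilt).

    ``apodization="aplanatic"`` (default) weights each plane wave by
    sqrt(cos theta) = sqrt(kz / (n k0)), the energy-conserving sine-condition
    factor for illumination through a high-NA objective; ``"none"`` uses the
    raw pupil amplitudes.
    """
    if apodization not in ("aplanatic", "none"):
        raise ValueError("apodization must be 'aplanatic' or 'none'")
    nz, ny, nx = optics.grid_shape
    if pupil.amplitude.shape != (ny, nx):
        raise ValueError("pupil grid does not match the optics grid")
    ks = optics.k_sample
    k_perp = pupil.k_perp
    prop = k_perp <= ks
    n_dropped = int(np.count_nonzero((pupil.amplitude != 0) & ~prop))
    if n_dropped:
        logger.info("dropping %d evanescent pupil components", n_dropped)
    amp = np.where(prop, pupil.amplitude, 0.0)
    kz = np.sqrt(np.maximum(ks**2 - k_perp**2, 0.0))
    if apodization == "aplanatic":
        amp = amp * np.sqrt(kz / ks)

    z = np.arange(nz, dtype=np.float64) * optics.axial_spacing
    # direct branch: A e^{i kz z}
    spec = amp[None, :, :] * np.exp(1j * kz[None, :, :] * z[:, None, None])

    use_mirror = mirror is not None and mirror.enabled and mirror.reflectance > 0.0
    if use_mirror:
        tilt_shift = 2.0 * ks * math.sin(math.radians(mirror.tilt_deg))
        amp_r = _shift_pupil(amp, pupil.kx, tilt_shift)
        amp_r = np.where(prop, amp_r, 0.0)
        phase_r = np.exp(1j * kz[None, :, :] * (2.0 * mirror.gap_distance - z)[:, None, None])
        spec = spec + mirror.reflectance * amp_r[None, :, :] * phase_r

    field = sfft.ifft2(spec, axes=(-2, -1), workers=-1)
    intensity = np.abs(field) ** 2
    return SpeckleVolume(
        data=intensity,
        lateral_spacing=optics.lateral_spacing,
        axial_spacing=optics.axial_spacing,
        n_evanescent_dropped=n_dropped,
    )


def detection_psf(
    optics: OpticalConfig,
    shape: tuple[int, int, int] | None = None,
    n_rho: int = 201,
) -> PSFVolume:
    """Scalar widefield detection PSF (Born-Wolf diffraction integral).

    h(r, z) = | int_0^1 J0(k NA rho r) exp(-i k rho^2 z NA^2 / (2 n_i)) rho drho |^2

    evaluated at the emission wavelength, unit-sum normalized, centered at
    the (nz//2, ny//2, nx//2) voxel.
    """
    if shape is None:
        shape = optics.grid_shape
    nz, ny, nx = shape
    if min(nz, ny, nx) < 3:
        raise ValueError("PSF grid must be at least 3 voxels along each axis")
    k = 2.0 * math.pi / optics.wavelength_em
    na = optics.numerical_aperture
    ni = optics.n_immersion

    y = (np.arange(ny) - ny // 2) * optics.lateral_spacing
    x = (np.arange(nx) - nx // 2) * optics.lateral_spacing
    r = np.hypot(y[:, None], x[None, :]).ravel()
    z = (np.arange(nz) - nz // 2) * optics.axial_spacing

    rho = np.linspace(0.0, 1.0, n_rho)
    w = np.full(n_rho, 1.0)
    # composite Simpson weights (n_rho must be odd)
    if n_rho % 2 == 0:
        raise ValueError("n_rho must be odd for Simpson integration")
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (rho[1] - rho[0]) / 3.0

    bessel = j0(np.outer(rho, k * na * r))              # (n_rho, npix)
    bessel *= (w * rho)[:, None]
    defocus = np.exp(-0.5j * k * (na**2 / ni) * np.outer(z, rho**2))  # (nz, n_rho)
    u = defocus @ bessel                                # (nz, npix)
    psf = (u.real**2 + u.imag**2).reshape(nz, ny, nx)
    psf /= psf.sum()
    return PSFVolume(
        data=psf,
        lateral_spacing=optics.lateral_spacing,
        axial_spacing=optics.axial_spacing,
        normalization="unit-sum",
    )


def autocorrelation_3d(volume: np.ndarray) -> np.ndarray:
    """Full (zero-padded) 3-D autocorrelation, zero lag at the center voxel.

    Output shape is (2 nz - 1, 2 ny - 1, 2 nx - 1); exact inversion symmetry
    ac(d) = ac(-d) is enforced by symmetrization.
    """
    v = np.asarray(volume, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError("autocorrelation_3d expects a 3-D array")
    if not np.all(np.isfinite(v)):
        raise ValueError("input must be finite")
    ac = signal.fftconvolve(v, v[::-1, ::-1, ::-1], mode="full")
    ac = 0.5 * (ac + ac[::-1, ::-1, ::-1])
    return ac


def autocorrelation_axis_profile(volume: np.ndarray, axis: int) -> np.ndarray:
    """Central line of the full 3-D autocorrelation along one axis.

    Equals ``autocorrelation_3d(volume)`` sampled along ``axis`` through the
    zero-lag voxel, but computed with 1-D transforms only (the other two
    lags are zero, so the lag sum separates into per-line autocorrelations
    summed over all lines).  Length is ``2 * n - 1``.
    """
    v = np.asarray(volume, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError("expected a 3-D array")
    v = np.moveaxis(v, axis, 0)
    n = v.shape[0]
    nfft = sfft.next_fast_len(2 * n - 1)
    spec = sfft.rfft(v, n=nfft, axis=0, workers=-1)
    power = (spec.real**2 + spec.imag**2).sum(axis=(1, 2))
    ac = sfft.irfft(power, n=nfft)
    ac = np.concatenate([ac[-(n - 1):], ac[:n]])
    return 0.5 * (ac + ac[::-1])


def effective_psf_profiles(
    speckle: SpeckleVolume, det_psf: PSFVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Axial and lateral central-line profiles of the effective speckle PSF,
    each peak-normalized.  Exact slices of :func:`effective_speckle_psf`
    without forming the full 3-D autocorrelation."""
    if speckle.data.shape != det_psf.data.shape:
        raise ValueError("speckle and detection PSF grids differ")
    prod = speckle.data * det_psf.data
    axial = autocorrelation_axis_profile(prod, axis=0)
    lateral = autocorrelation_axis_profile(prod, axis=2)
    return axial / axial.max(), lateral / lateral.max()


def effective_speckle_psf(speckle: SpeckleVolume, det_psf: PSFVolume) -> PSFVolume:
    """Resolution kernel of fluctuation imaging: the autocorrelation of
    (illumination intensity x detection PSF), peak-normalized."""
    if speckle.data.shape != det_psf.data.shape:
        raise ValueError("speckle and detection PSF grids differ")
    if (speckle.lateral_spacing != det_psf.lateral_spacing
            or speckle.axial_spacing != det_psf.axial_spacing):
        raise ValueError("speckle and detection PSF spacings differ")
    ac = autocorrelation_3d(speckle.data * det_psf.data)
    ac /= ac.max()
    return PSFVolume(
        data=ac,
        lateral_spacing=speckle.lateral_spacing,
        axial_spacing=speckle.axial_spacing,
        normalization="unit-peak",
    )


def _descend(profile: np.ndarray, peak: int, step: int, rise_frac: float = 0.01):
    """Walk outward from ``peak`` until the profile turns up by more than
    ``rise_frac`` of the drop so far (or the end is reached).

    Returns (index_of_running_minimum, value).  The hysteresis makes the
    stop robust to small noise on an otherwise monotone flank.
    """
    pk = profile[peak]
    i = peak
    run_min = pk
    run_idx = peak
    j = peak + step
    n = len(profile)
    while 0 <= j < n:
        if profile[j] < run_min:
            run_min = profile[j]
            run_idx = j
        elif profile[j] > run_min + rise_frac * (pk - run_min) and run_min < pk:
            break
        j += step
    return run_idx, run_min


def fwhm(profile: np.ndarray, spacing: float, rise_frac: float = 0.01,
         baseline: str = "local") -> float:
    """Full width at half maximum of a 1-D peak, in physical units.

    ``baseline="local"``: the baseline is the minimum of the profile
    between the nearest local minima flanking the peak (handles
    oscillatory sidelobes, e.g. the axial fringes of the mirror-assisted
    effective speckle PSF).  ``baseline="global"``: the baseline is the
    profile minimum and the crossings are the first samples below half
    level scanning outward from the peak — robust for noisy measured
    profiles without sidelobe structure (e.g. bead images).  Half-level
    crossings are located by linear interpolation.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    if baseline not in ("local", "global"):
        raise ValueError("baseline must be 'local' or 'global'")
    peak = int(np.argmax(p))
    if peak == 0 or peak == len(p) - 1:
        raise ValueError("profile maximum lies at an endpoint")
    if np.count_nonzero(p == p[peak]) > 1:
        raise ValueError("profile maximum is not unique")

    if baseline == "global":
        li, ri = 0, len(p) - 1
        base = float(p.min())
    else:
        li, lmin = _descend(p, peak, -1, rise_frac)
        ri, rmin = _descend(p, peak, +1, rise_frac)
        base = min(lmin, rmin)
    half = base + 0.5 * (p[peak] - base)

    def _cross(start: int, stop: int, step: int, side: str) -> float:
        prev = start
        j = start + step
        while step * (stop - j) >= 0:
            if p[j] <= half:
                # linear interpolation between prev and j
                frac = (p[prev] - half) / (p[prev] - p[j])
                return prev + step * frac
            prev = j
            j += step
        raise ValueError(f"half level never crossed on the {side} side")

    xl = _cross(peak, li, -1, "left")
    xr = _cross(peak, ri, +1, "right")
    return float((xr - xl) * spacing)
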