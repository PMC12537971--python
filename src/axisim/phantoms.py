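"""Synthetic fluorophore phantoms and speckle-illuminated camera acquisition.

This module is the stand-in for the microscope: it builds fluorophore
density volumes (beads, filaments, hollow shells, moving particles),
illuminates them with per-frame speckle realizations (a rotating diffuser
decorrelates the pattern between exposures), blurs with the detection PSF,
and applies an EMCCD-like noise model.  The output is a 4-D (t, z, y, x)
raw stack in camera counts -- the input the reconstruction chain expects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .optics import (
    MirrorConfig,
    OpticalConfig,
    PSFVolume,
    SpeckleVolume,
    sample_pupil,
    synthesize_speckle,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Phantom",
    "MovingPhantom",
    "AcquisitionPlan",
    "NoiseModel",
    "RawStack",
    "make_beads",
    "make_filaments",
    "make_hollow_shells",
    "make_moving_particles",
    "render_frame",
    "acquire_stack",
    "apply_noise",
]


@dataclass
class Phantom:
    """Fluorophore density on the simulation grid (nz, ny, nx), plus the
    nominal emitter positions in nm (z, y, x) when the object is discrete."""

    density: np.ndarray
    lateral_spacing: float
    axial_spacing: float
    emitters: np.ndarray | None = None   # (n, 3) nm

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("phantom density must be non-negative")

    @property
    def bounds_nm(self) -> tuple[float, float, float]:
        nz, ny, nx = self.density.shape
        return (nz * self.axial_spacing, ny * self.lateral_spacing,
                nx * self.lateral_spacing)


@dataclass
class MovingPhantom:
    """Point emitters with per-frame positions (n_frames, n, 3) in nm."""

    tracks: np.ndarray
    grid_shape: tuple[int, int, int]
    lateral_spacing: float
    axial_spacing: float
    brightness: float = 1.0
    frame_interval: float = 1.0

    def density_at(self, frame: int) -> Phantom:
        """Rasterize the emitters of one frame with trilinear deposition."""
        nz, ny, nx = self.grid_shape
        dens = np.zeros(self.grid_shape)
        pos = self.tracks[frame]
        vox = pos / np.array([self.axial_spacing, self.lateral_spacing,
                              self.lateral_spacing])
        for p in vox:
            i0 = np.floor(p).astype(int)
            f = p - i0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        w = ((f[0] if dz else 1 - f[0])
                             * (f[1] if dy else 1 - f[1])
                             * (f[2] if dx else 1 - f[2]))
                        idx = (i0[0] + dz, i0[1] + dy, i0[2] + dx)
                        if (0 <= idx[0] < nz and 0 <= idx[1] < ny
                                and 0 <= idx[2] < nx):
                            dens[idx] += self.brightness * w
        return Phantom(dens, self.lateral_spacing, self.axial_spacing,
                       emitters=pos.copy())


@dataclass(frozen=True)
class AcquisitionPlan:
    """Frame/z-scan schedule.  Defaults follow a fixed-sample protocol:
    50 speckle frames per layer (100 for live samples), 25 nm z-steps for
    bead studies, 50 fps."""

    frames_per_layer: int = 50
    z_step: float = 25.0
    n_layers: int = 1
    frame_interval: float = 0.02
    drift_per_frame: tuple[float, float] | None = None   # (dy, dx) nm/frame

    def __post_init__(self) -> None:
        if self.frames_per_layer < 2:
            raise ValueError("frames_per_layer must be >= 2")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """EMCCD-style camera: Poisson shot noise, electron-multiplying gain
    (optionally with the multiplicative excess-noise factor, which doubles
    the variance), Gaussian read noise, and a fixed offset."""

    photons_at_peak: float = 500.0
    em_gain: float = 30.0
    read_noise_sd: float = 2.0
    offset: float = 100.0
    excess_noise: bool = True

    def __post_init__(self) -> None:
        if self.photons_at_peak <= 0:
            raise ValueError("photons_at_peak must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class RawStack:
    """4-D acquisition in camera counts, axis order (t, z, y, x); t runs
    fastest within a z-layer."""

    data: np.ndarray
    lateral_spacing: float
    axial_spacing: float
    z_step: float
    frame_interval: float
    focal_indices: np.ndarray | None = None
    seed_registry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("RawStack data must be 4-D (t, z, y, x)")
        if np.any(self.data < 0):
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# phantom constructors


def _sphere_template(radius_vox_lat: float, radius_vox_ax: float) -> np.ndarray:
    """Anti-aliased solid ellipsoid (sphere in physical units) stencil."""
    rl = max(radius_vox_lat, 0.5)
    ra = max(radius_vox_ax, 0.5)
    nl = int(math.ceil(rl)) + 1
    na = int(math.ceil(ra)) + 1
    z, y, x = np.mgrid[-na:na + 1, -nl:nl + 1, -nl:nl + 1].astype(float)
    r = np.sqrt((z / ra) ** 2 + (y / rl) ** 2 + (x / rl) ** 2)
    # half-voxel linear edge softening keeps the rasterized mass stable
    edge = 0.5 / max(rl, ra)
    return np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)


def make_beads(
    n: int,
    diameter: float,
    grid_shape: tuple[int, int, int],
    lateral_spacing: float,
    axial_spacing: float,
    seed: int,
    min_spacing: float | None = None,
    brightness: float = 1.0,
    margin_nm: float = 0.0,
    z_band_nm: tuple[float, float] | None = None,
) -> Phantom:
    """Uniform-density spheres (e.g. 100 nm fluorescent beads) at random
    positions, each stamped from one shared stencil so per-bead mass is
    identical.  ``min_spacing`` (nm, center-to-center) defaults to twice
    the diameter; ``margin_nm`` keeps centers away from the volume faces
    (useful when widths will be measured around each bead).
    ``z_band_nm`` restricts bead centers to an axial band (lo, hi) in nm,
    e.g. to keep a single-layer acquisition's beads near its focal
    plane."""
    nz, ny, nx = grid_shape
    dens = np.zeros(grid_shape)
    if n == 0:
        return Phantom(dens, lateral_spacing, axial_spacing,
                       emitters=np.zeros((0, 3)))
    if min_spacing is None:
        min_spacing = 2.0 * diameter
    tmpl = _sphere_template(diameter / 2 / lateral_spacing,
                            diameter / 2 / axial_spacing) * brightness
    tz, ty, tx = tmpl.shape
    mz = tz // 2 + 1 + int(math.ceil(margin_nm / axial_spacing))
    my = ty // 2 + 1 + int(math.ceil(margin_nm / lateral_spacing))
    mx = tx // 2 + 1 + int(math.ceil(margin_nm / lateral_spacing))
    if nz - 2 * mz < 1 or ny - 2 * my < 1 or nx - 2 * mx < 1:
        raise ValueError("grid too small for beads of this diameter")
    z_lo, z_hi = mz, nz - mz
    if z_band_nm is not None:
        z_lo = max(z_lo, int(math.ceil(z_band_nm[0] / axial_spacing)))
        z_hi = min(z_hi, int(math.floor(z_band_nm[1] / axial_spacing)) + 1)
        if z_hi <= z_lo:
            raise ValueError("z_band_nm leaves no valid bead positions")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    spacing = np.array([axial_spacing, lateral_spacing, lateral_spacing])
    tries = 0
    while len(centers) < n:
        c = np.array([rng.integers(z_lo, z_hi),
                      rng.integers(my, ny - my),
                      rng.integers(mx, nx - mx)])
        pos_nm = c * spacing
        if all(np.linalg.norm(pos_nm - p) >= min_spacing
               for p in (np.asarray(centers) * spacing if centers else [])):
            centers.append(c)
        tries += 1
        if tries > 1000 * n:
            raise ValueError(
                "could not place beads with the requested minimum spacing"
            )
    for c in centers:
        sl = tuple(slice(ci - s // 2, ci - s // 2 + s)
                   for ci, s in zip(c, tmpl.shape))
        dens[sl] += tmpl
    emitters = np.asarray(centers, dtype=float) * spacing
    return Phantom(dens, lateral_spacing, axial_spacing, emitters=emitters)


def make_filaments(
    n: int,
    thickness: float,
    grid_shape: tuple[int, int, int],
    lateral_spacing: float,
    axial_spacing: float,
    seed: int,
    curvature: float = 0.1,
    step_nm: float | None = None,
) -> Phantom:
    """Smooth random-walk tubes with a Gaussian cross-section, emulating
    microtubule-like filaments.  ``curvature`` is the RMS direction change
    (radians) per step; 0 gives straight tubes.  Mass is deposited at a
    constant rate per unit arc length, then blurred to ``thickness`` FWHM.
    """
    nz, ny, nx = grid_shape
    if step_nm is None:
        step_nm = 0.5 * lateral_spacing
    spacing = np.array([axial_spacing, lateral_spacing, lateral_spacing])
    extent = np.array(grid_shape) * spacing
    rng = np.random.default_rng(seed)
    deltas = np.zeros(grid_shape)
    for _ in range(n):
        pos = extent * (0.25 + 0.5 * rng.random(3))
        theta = rng.uniform(0, 2 * math.pi)
        direction = np.array([0.0, math.sin(theta), math.cos(theta)])
        n_steps = int(2.0 * max(extent) / step_nm)
        for _ in range(n_steps):
            vox = np.round(pos / spacing).astype(int)
            if np.all(vox >= 0) and np.all(vox < grid_shape):
                deltas[tuple(vox)] += 1.0
            if curvature > 0:
                kick = rng.normal(0.0, curvature, size=3)
                kick[0] *= 0.3   # walks stay mostly in-plane
                direction = direction + kick * step_nm / lateral_spacing
                direction /= np.linalg.norm(direction)
            pos = pos + direction * step_nm
            if np.any(pos < 0) or np.any(pos >= extent):
                break
    sigma_vox = (thickness / 2.355) / spacing
    dens = ndimage.gaussian_filter(deltas, sigma=sigma_vox, mode="constant")
    return Phantom(dens, lateral_spacing, axial_spacing)


def make_hollow_shells(
    n: int,
    outer_diameter: float,
    shell_thickness: float,
    grid_shape: tuple[int, int, int],
    lateral_spacing: float,
    axial_spacing: float,
    seed: int,
) -> Phantom:
    """Spherical shells with an empty lumen (lysosome-like membrane-bound
    organelles, typically 100-500 nm across)."""
    if not shell_thickness < outer_diameter / 2:
        raise ValueError("shell_thickness must be below outer radius")
    nz, ny, nx = grid_shape
    spacing = np.array([axial_spacing, lateral_spacing, lateral_spacing])
    r_out = outer_diameter / 2
    r_in = r_out - shell_thickness
    margin_vox = np.ceil(r_out / spacing).astype(int) + 1
    if np.any(np.array(grid_shape) - 2 * margin_vox < 1):
        raise ValueError("grid too small for shells of this diameter")
    rng = np.random.default_rng(seed)
    dens = np.zeros(grid_shape)
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * spacing[0],
        np.arange(ny) * spacing[1],
        np.arange(nx) * spacing[2],
        indexing="ij",
    )
    centers = []
    h = float(min(spacing))   # anti-alias edge width, nm
    for _ in range(n):
        c = np.array([rng.integers(m, s - m) for m, s
                      in zip(margin_vox, grid_shape)]) * spacing
        centers.append(c)
        r = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        outer = np.clip((r_out - r) / h + 0.5, 0.0, 1.0)
        inner = np.clip((r_in - r) / h + 0.5, 0.0, 1.0)
        dens += outer - inner
    return Phantom(dens, lateral_spacing, axial_spacing,
                   emitters=np.asarray(centers))


def make_moving_particles(
    n: int,
    speed: float,
    frame_interval: float,
    n_frames: int,
    grid_shape: tuple[int, int, int],
    lateral_spacing: float,
    axial_spacing: float,
    seed: int,
    brightness: float = 1.0,
) -> MovingPhantom:
    """Constant-velocity point emitters, reflected at the volume boundary.

    The default speeds used in the bundled demos sit near measured
    lysosome transport velocities (~80 nm/s).
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    rng = np.random.default_rng(seed)
    spacing = np.array([axial_spacing, lateral_spacing, lateral_spacing])
    extent = np.array(grid_shape, dtype=float) * spacing
    lo = 0.15 * extent
    hi = 0.85 * extent
    pos = lo + (hi - lo) * rng.random((n, 3))
    theta = rng.uniform(0, 2 * math.pi, size=n)
    vel = speed * np.stack(
        [np.zeros(n), np.sin(theta), np.cos(theta)], axis=1
    )  # in-plane motion; z column zero
    tracks = np.empty((n_frames, n, 3))
    n_reflections = 0
    for t in range(n_frames):
        tracks[t] = pos
        pos = pos + vel * frame_interval
        for ax in range(3):
            below = pos[:, ax] < lo[ax]
            above = pos[:, ax] > hi[ax]
            if below.any() or above.any():
                n_reflections += int(below.sum() + above.sum())
                pos[below, ax] = 2 * lo[ax] - pos[below, ax]
                pos[above, ax] = 2 * hi[ax] - pos[above, ax]
                vel[below | above, ax] *= -1.0
    if n_reflections:
        logger.info("moving particles reflected %d times at the boundary",
                    n_reflections)
    return MovingPhantom(tracks=tracks, grid_shape=grid_shape,
                         lateral_spacing=lateral_spacing,
                         axial_spacing=axial_spacing,
                         brightness=brightness,
                         frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# forward model


def _lateral_otfs(psf: PSFVolume) -> np.ndarray:
    """Per-plane 2-D OTFs of a centered PSF (cached on the PSF object)."""
    cached = getattr(psf, "_otf_cache", None)
    if cached is not None and cached.shape[0] == psf.data.shape[0]:
        return cached
    otf = sfft.fft2(np.fft.ifftshift(psf.data, axes=(1, 2)), axes=(1, 2),
                    workers=-1)
    psf._otf_cache = otf
    return otf


def render_frame(
    phantom: Phantom,
    speckle: SpeckleVolume,
    det_psf: PSFVolume,
    focal_index: int,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    photon_scale: float = 1.0,
) -> np.ndarray:
    """One camera exposure: (phantom x illumination), blurred in 3-D by the
    detection PSF, sampled at the focal plane, then optionally passed
    through the camera noise model.

    The noise-free signal is linear in the phantom density; out-of-focus
    planes contribute through the PSF's defocused sections (essential for
    optical-sectioning behaviour).
    """
    nz = phantom.density.shape[0]
    if speckle.data.shape != phantom.density.shape:
        raise ValueError("speckle grid does not match the phantom grid")
    if not 0 <= focal_index < nz:
        raise ValueError(f"focal_index {focal_index} outside [0, {nz})")
    prod = phantom.density * speckle.data
    otf = _lateral_otfs(det_psf)
    cz = det_psf.data.shape[0] // 2
    nz_psf = det_psf.data.shape[0]
    spec = sfft.fft2(prod, axes=(1, 2), workers=-1)
    acc = np.zeros(spec.shape[1:], dtype=complex)
    for zp in range(nz):
        zi = focal_index - zp + cz
        if 0 <= zi < nz_psf:
            acc += spec[zp] * otf[zi]
    frame = sfft.ifft2(acc, workers=-1).real
    np.clip(frame, 0.0, None, out=frame)
    frame = frame * photon_scale
    if noise is None:
        return frame
    return apply_noise(frame, noise, seed if seed is not None else 0)


def apply_noise(expected: np.ndarray, noise: NoiseModel, seed: int) -> np.ndarray:
    """EMCCD readout: counts = gain * Poisson(expected photons) [+ excess
    noise doubling the multiplied variance] + read noise + offset, >= 0."""
    if np.any(expected < 0):
        raise ValueError("expected photon image must be non-negative")
    rng = np.random.default_rng(seed)
    counts = noise.em_gain * rng.poisson(expected).astype(np.float64)
    if noise.excess_noise:
        counts += rng.normal(0.0, noise.em_gain * np.sqrt(expected))
    if noise.read_noise_sd > 0:
        counts += rng.normal(0.0, noise.read_noise_sd, size=expected.shape)
    counts += noise.offset
    np.clip(counts, 0.0, None, out=counts)
    return counts


def acquire_stack(
    phantom: Phantom,
    plan: AcquisitionPlan,
    optics: OpticalConfig,
    mirror: MirrorConfig | None,
    noise: NoiseModel | None,
    seed: int,
    apodization: str = "aplanatic",
    det_psf: PSFVolume | None = None,
) -> RawStack:
    """Simulate a full z-scan: for each layer, ``frames_per_layer``
    statistically independent speckle realizations (rotating-diffuser
    model) are rendered at that focal depth.  Optional linear (dy, dx)
    drift accumulates over the global frame counter.  All child seeds are
    derived from ``seed`` and recorded in the stack's registry.
    """
    from .optics import detection_psf  # local import avoids cycle at module load

    nz, ny, nx = phantom.density.shape
    if optics.grid_shape != (nz, ny, nx):
        raise ValueError("optics.grid_shape must match the phantom grid")
    step_vox = plan.z_step / optics.axial_spacing
    if abs(step_vox - round(step_vox)) > 1e-9:
        raise ValueError("z_step must be an integer multiple of axial_spacing")
    step_vox = int(round(step_vox))
    focal0 = (nz - 1 - (plan.n_layers - 1) * step_vox) // 2
    focal_indices = focal0 + step_vox * np.arange(plan.n_layers)
    if focal_indices[0] < 0 or focal_indices[-1] >= nz:
        raise ValueError("z-scan range exceeds the phantom grid")

    if det_psf is None:
        det_psf = detection_psf(optics)

    # photon normalization: peak of the mean-illumination (speckle-free)
    # image over the scanned layers maps to photons_at_peak
    uniform = SpeckleVolume(np.ones_like(phantom.density),
                            optics.lateral_spacing, optics.axial_spacing)
    ref_peak = max(
        render_frame(phantom, uniform, det_psf, int(fi)).max()
        for fi in focal_indices
    )
    if ref_peak <= 0:
        raise ValueError("phantom renders to zero signal; nothing to acquire")
    photon_scale = (noise.photons_at_peak / ref_peak) if noise else 1.0 / ref_peak

    ss = np.random.SeedSequence(seed)
    n_frames_total = plan.n_layers * plan.frames_per_layer
    child = ss.generate_state(2 * n_frames_total, dtype=np.uint32) & 0x7FFFFFFF
    registry: dict = {"master_seed": seed, "children": {}}

    data = np.empty((plan.frames_per_layer, plan.n_layers, ny, nx),
                    dtype=np.float32)
    g = 0
    for li, fi in enumerate(focal_indices):
        for t in range(plan.frames_per_layer):
            pupil_seed = int(child[2 * g])
            noise_seed = int(child[2 * g + 1])
            registry["children"][(t, li)] = (pupil_seed, noise_seed)
            pupil = sample_pupil(optics, pupil_seed)
            speckle = synthesize_speckle(pupil, optics, mirror,
                                         apodization=apodization)
            speckle.data /= speckle.data.mean()
            frame = render_frame(phantom, speckle, det_psf, int(fi),
                                 noise=None, photon_scale=photon_scale)
            if plan.drift_per_frame is not None:
                dy, dx = plan.drift_per_frame
                shift_px = (g * dy / optics.lateral_spacing,
                            g * dx / optics.lateral_spacing)
                frame = np.real(sfft.ifft2(ndimage.fourier_shift(
                    sfft.fft2(frame), shift_px)))
                np.clip(frame, 0.0, None, out=frame)
            if noise is not None:
                frame = apply_noise(frame, noise, noise_seed)
            data[t, li] = frame
            g += 1
    return RawStack(
        data=data,
        lateral_spacing=optics.lateral_spacing,
        axial_spacing=optics.axial_spacing,
        z_step=plan.z_step,
        frame_interval=plan.frame_interval,
        focal_indices=focal_indices,
        seed_registry=registry,
    )
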