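# Methods

This document records the physical model, the reconstruction chain, and the
non-obvious algorithmic decisions in `axisim`.

## 1. Illumination model (scalar angular spectrum)

A rotating diffuser produces coherent speckle. The pupil is sampled on the
lateral frequency grid of the simulation volume: each sample inside the NA
disk (`k_perp <= NA * k0`, with `k0 = 2*pi/lambda` in vacuum and propagation
constants taken in the sample medium `n_sample`) receives unit amplitude and
an i.i.d. uniform random phase. The field at depth `z` is the 2-D inverse FFT
of

```
A(k) * exp(i kz z)   +   r * A_tilt(k) * exp(i kz (2d - z))
```

where `kz = sqrt((n k0)^2 - k_perp^2)`, `d` is the mirror gap and `r` its
amplitude reflectance. The second term is the mirror image of the field
propagated to the mirror and back: the reflected plane-wave components
counter-propagate, so the direct and reflected fields interfere with an axial
beat at `lambda / (2 n)`. Intensity `|E|^2` is the illumination pattern.

Decisions:

- **Evanescent components** (`k_perp > n_sample * k0`, possible because
  NA 1.49 > n 1.33 for TIRF objectives) carry no propagating power deep in the
  sample and are dropped; the count is recorded on the result
  (`n_evanescent_dropped`).
- **Apodization**: an aplanatic `sqrt(kz / (n k0))` pupil weighting is the
  default (`apodization="aplanatic"`); `"none"` gives the flat scalar pupil.
  The choice shifts the speckle grain statistics slightly but none of the
  qualitative results.
- **Mirror tilt** is modeled as a lateral displacement of the reflected
  pupil by `2 n k0 sin(theta)`, implemented as an integer-bin translation on
  the fftshifted frequency axes without wraparound (components shifted outside
  the grid are dropped). Tilt = 0 leaves the reflected pupil centered, and
  `MirrorConfig(enabled=False)`, `reflectance=0` and `mirror=None` are
  bitwise-identical by construction.
- **Plane-wave limit**: with NA small enough that the pupil disk contains a
  single sample (the DC sample is always inside, so the disk is never empty),
  the mirror produces a pure standing wave; the fitted fringe period matches
  `lambda / (2 n)` = 183.5 nm to better than 1 nm, an analytic oracle used in
  the tests.

## 2. Detection PSF and effective speckle PSF

The widefield detection PSF is a scalar Born–Wolf-style model: the emission
pupil (NA disk at `lambda_em`) defocused by `exp(i kz z)` per plane, intensity
normalized to unit sum. Its lateral FWHM matches `0.514 lambda / NA` within
5%.

The resolution-bearing kernel of fluctuation imaging is the **effective
speckle PSF**: the 3-D autocorrelation of the product of the illumination
intensity and the detection PSF. With the mirror off, its axial extent is set
by the detection PSF (~700-800 nm); with the mirror on, the axial
interference compresses it by a factor >= 4 (median over seeds). Matched
comparisons share the same pupil realization between the mirror-on and
mirror-off branches.

## 3. Forward imaging and noise

A frame at focal plane `f` is the plane-wise 2-D convolution sum

```
I(y,x) = sum_z [ density(z) * speckle(z) ]  conv  PSF(z - f)
```

computed in the Fourier domain (circular boundary). The EMCCD model applies
per-pixel Poisson shot noise scaled to `photons_at_peak`, the EM excess-noise
factor (variance doubling, modeled as gamma-distributed gain), Gaussian read
noise, and a camera offset of 100 counts. Each frame draws an independent
speckle realization (the rotating diffuser); all child seeds derive from the
master seed through labeled `SeedSequence` streams, so acquisitions are
bitwise reproducible.

## 4. Reconstruction chain

Per z-layer, from `T` frames:

1. subtract the camera offset (clip at zero);
2. optional drift registration (phase correlation to the layer mean);
3. per-frame 2-D Richardson–Lucy (10 iterations) with the in-focus PSF slice;
4. DSI weight `W = RMS_t` of the deconvolved frames — `W` itself is the
   diffraction-limited, optically sectioned baseline ("DL");
5. reweight `F' = F_RL * W` and take `sqrt(F')` to linearize the effective
   squaring introduced by the weighting;
6. Fourier interpolation x2 (zero-padded spectrum; original samples are
   preserved exactly);
7. temporal cumulant across frames (order 3, lag 0 by default; order 2
   available), negative values clipped to zero with the clipped fraction
   logged;
8. stack layers, then 3-D Richardson–Lucy with the matched detection PSF.
   The iteration count is selected automatically by splitting the frames into
   two halves, reconstructing each, and maximizing the FRC resolution of the
   half-reconstructions (ties broken toward the smaller count by comparing
   tail means), capped at 40.

Two optional post-steps:

- **Brightness linearization** (`linearize_brightness`): n-th root after
  deconvolution followed by reconvolution with the detection PSF, undoing the
  cumulant's brightness nonlinearity (a constant volume is an exact fixed
  point: cumulant of order n followed by the n-th root returns the standard
  deviation-like amplitude). The reconvolution necessarily returns the image
  to the detection band limit, so it is a *photometric* correction: it is on
  by default for visual/photometric use but **off when measuring resolution**
  (widths measured after reconvolution can only reflect the detection PSF).
- **z-flattening** (`z_flatten`): per-slice gain equalization against the
  axial intensity envelope. Useful for dense samples; off for sparse bead
  phantoms, where most slices are empty and the per-slice gains amplify
  noise.

## 5. Resolution estimation

- **FRC**: ring-wise spectral correlation of two half-data reconstructions,
  fixed 1/7 threshold, ring width chosen as `max(16, N/16)` rings so small
  images keep enough samples per ring. Flags distinguish `ok`,
  `unresolved-at-Nyquist` (never drops below threshold) and `uncorrelated`
  (below threshold from the first ring). Validated against an analytic
  construction: two noisy copies of a Gaussian-band-limited image have
  `FRC(f) = G(f)^2 / (G(f)^2 + sn^2)`, whose 1/7 crossing is
  `f* = fc * sqrt(ln(6/sn^2)/2)`; the estimator lands within a few percent.
  (A brick-wall band-limit construction is *not* a good oracle: ring
  discretization biases the crossing by >20% on small images.)
- **Decorrelation analysis** (reference-free): local maxima of the
  normalized spectral self-correlation under progressive low-pass masking and
  a family of Gaussian high-pass filters; the largest peak position is the
  cutoff. Axial resolution uses an xz slice restricted to a +/-11.25 deg
  sector about the kz axis. Validated within 20% on constructed band limits.
- **FWHM** (`axisim.optics.fwhm`) has two baseline rules:
  - `"local"` (default): fringe-aware — the baseline is the mean of the
    flanking local minima found by hysteresis descent from the peak. Correct
    for effective-PSF profiles, where mirror interference puts side fringes
    next to the central peak and the half level must be referenced to the
    fringe minima.
  - `"global"`: baseline is the profile minimum; crossings are the first
    half-level crossings scanning outward. Robust for noisy measured bead
    profiles, where small noise dips would otherwise be mistaken for fringe
    minima. Bead measurements additionally average a 3-line band through the
    peak (`profile_width=3`).

## 6. Acceptance studies (`axisim.experiments`)

- **Confinement** (t2): 50 seeds, grid 192 x 128 x 128 at 20-nm axial
  sampling (a 3.84-µm window keeps the wide mirror-off profile untruncated);
  median mirror-off/mirror-on axial FWHM ratio of the effective speckle PSF.
- **Bead sharpening** (t3): five 100-nm beads, 50 frames/layer, 48 layers at
  25-nm z-step; third-order reconstruction
  (`linearize_brightness=False, z_flatten=False`, see section 4) vs the DSI
  baseline; median per-bead axial-FWHM reduction. Bead centers keep a 700-nm
  margin from the volume faces and >=600 nm mutual spacing so every DL
  profile is complete and peaks are unambiguous.
- **Frame budget** (t4): fixed bead phantom, one z-layer, 500 frames; SSIM of
  the 50-frame DSI against the 500-frame DSI, median over 5 seeds.
- **Tilt robustness**: 10-degree mirror tilt changes the median axial FWHM by
  well under 25% (5-seed medians; single seeds can produce envelope-walking
  outliers of the local FWHM rule, which the median absorbs).

## 7. Limitations

- Scalar (not vectorial) diffraction: no polarization effects, no
  high-NA vectorial corrections; the TIRF-objective evanescent components are
  dropped rather than modeled as near-field.
- Circular (FFT) boundary conditions in the forward model and deconvolution.
- The EMCCD model uses the standard variance-doubling approximation of the
  EM register rather than the full cascade distribution.
- The mirror is modeled as a perfect plane with scalar reflectance; no
  surface roughness or dispersion.
- Reconstruction assumes a shift-invariant detection PSF across the field and
  depth range.
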