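"""Forward model: phantoms, multislice exit waves, imaging and detection.

Generates synthetic tilt-series datasets mimicking the two acquisition
protocols used for electron Fourier ptychography: one axial image plus
six tilted images at equally spaced azimuths for radiation-robust
samples, and four tilted images with no axial exposure for low-fluence
work on beam-sensitive specimens. The chain per image is

    phantom -> multislice exit wave (tilted plane-wave illumination)
            -> image wave via the axial WTF -> |.|^2 intensity
            -> fluence-budgeted Poisson detection with a Gaussian MTF.

The detector is a parametric stand-in: Poisson shot noise plus a
Gaussian modulation-transfer kernel of configurable width, not a model
of any particular camera.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import FrequencyGrid, OpticalSystem, OpticsError, Tilt, axial_wtf


class ForwardError(ValueError):
    """Invalid forward-model input."""


# ---------------------------------------------------------------------------
# Phantoms


@dataclass
class Phantom:
    """Synthetic specimen as a stack of thin slices.

    ``slices`` holds per-slice phase shifts in radians, shape
    (n_slices, ny, nx); ``amplitudes`` optional per-slice attenuation in
    (0, 1] (``None`` means a pure phase object). A single zero-thickness
    slice is equivalent to the 2-D transmission function
    ``O(r) = a(r) exp(i phi(r))``.
    """

    kind: str
    slices: np.ndarray
    pixel_size: float
    slice_thickness: float = 0.0
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.slices.ndim == 2:
            self.slices = self.slices[None]
        if not np.all(np.isfinite(self.slices)):
            raise ForwardError("phantom phase must be finite")
        if self.amplitudes is not None:
            if self.amplitudes.ndim == 2:
                self.amplitudes = self.amplitudes[None]
            if np.any(self.amplitudes <= 0) or np.any(self.amplitudes > 1):
                raise ForwardError("slice amplitudes must lie in (0, 1]")
        if self.slice_thickness < 0:
            raise ForwardError("slice thickness must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def transmission(self, s: int = 0) -> np.ndarray:
        """Complex transmission of slice ``s``."""
        amp = 1.0 if self.amplitudes is None else self.amplitudes[s]
        return amp * np.exp(1j * self.slices[s])

    def total_phase(self) -> np.ndarray:
        """Projected phase (sum over slices), the ground truth for PSNR."""
        return self.slices.sum(axis=0)


def make_phantom(
    kind: str,
    shape: tuple[int, int],
    pixel_size: float,
    params: dict | None = None,
    seed: int = 0,
) -> Phantom:
    """Build a deterministic synthetic phantom.

    kinds
    -----
    ``lattice``: Gaussian phase bumps on a square lattice (params:
    ``spacing_nm``, ``peak_phase``, ``sigma_nm``) — a crystalline,
    radiation-robust test object.
    ``blobs``: randomly placed Gaussian blobs (params: ``count``,
    ``radius_range_nm``, ``peak_phase``) — isolated-particle contrast.
    ``ice``: zero-mean band-passed Gaussian-noise phase of unit amplitude
    (params: ``band_invnm`` = (k_lo, k_hi), ``rms_phase``) — the
    Fourier-filtered-noise model of amorphous ice.
    ``composite``: blobs embedded in ice (params of both).

    Phantoms are pure phase objects; identical seed and params give a
    bit-identical result. A peak |phase| above pi/2 triggers a warning
    because downstream weak-phase checks assume small phase.
    """
    ny, nx = shape
    if ny < 64 or nx < 64:
        raise ForwardError("phantom grid must be at least 64x64")
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "lattice":
        phase = _lattice_phase(shape, pixel_size, params)
    elif kind == "blobs":
        phase = _blobs_phase(shape, pixel_size, params, rng)
    elif kind == "ice":
        phase = _ice_phase(shape, pixel_size, params, rng)
    elif kind == "composite":
        phase = _blobs_phase(shape, pixel_size, params, rng) + _ice_phase(
            shape, pixel_size, params, rng
        )
    else:
        raise ForwardError(f"unknown phantom kind {kind!r}")

    if np.abs(phase).max() > np.pi / 2:
        warnings.warn(
            "phantom peak phase exceeds pi/2; weak-phase assumptions may fail",
            stacklevel=2,
        )
    return Phantom(kind=kind, slices=phase[None], pixel_size=pixel_size)


def _lattice_phase(shape, pixel_size, params):
    spacing = params.get("spacing_nm", 0.235)
    peak = params.get("peak_phase", 0.05)
    sigma = params.get("sigma_nm", spacing / 4.0)
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx] * pixel_size
    phase = np.zeros(shape)
    # periodic Gaussian bumps: accumulate over lattice sites
    n_x = int(np.floor(nx * pixel_size / spacing))
    n_y = int(np.floor(ny * pixel_size / spacing))
    for iy in range(n_y):
        for ix in range(n_x):
            cy, cx = (iy + 0.5) * spacing, (ix + 0.5) * spacing
            phase += np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * sigma**2))
    return peak * phase


def _blobs_phase(shape, pixel_size, params, rng):
    count = params.get("count", 12)
    r_lo, r_hi = params.get("radius_range_nm", (0.5, 1.5))
    peak = params.get("peak_phase", 0.05)
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx] * pixel_size
    phase = np.zeros(shape)
    for _ in range(count):
        cy = rng.uniform(0, ny * pixel_size)
        cx = rng.uniform(0, nx * pixel_size)
        r = rng.uniform(r_lo, r_hi)
        phase += np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * r**2))
    m = np.abs(phase).max()
    return peak * phase / m if m > 0 else phase


def _ice_phase(shape, pixel_size, params, rng):
    k_lo, k_hi = params.get("band_invnm", (0.5, 3.0))
    rms = params.get("rms_phase", 0.05)
    grid = FrequencyGrid(shape, pixel_size)
    noise = rng.standard_normal(shape)
    kmag = grid.kmag()
    band = (kmag >= k_lo) & (kmag <= k_hi)
    spec = np.fft.fft2(noise) * band
    phase = np.fft.ifft2(spec).real
    phase -= phase.mean()
    s = phase.std()
    return rms * phase / s if s > 0 else phase


# ---------------------------------------------------------------------------
# Wave propagation and imaging


def snap_tilt_to_grid(tilt: Tilt, grid: FrequencyGrid, wavelength_nm: float) -> np.ndarray:
    """k_tau rounded to the nearest grid frequency sample (kx, ky), nm^-1.

    Plane waves on a periodic grid must be grid-commensurate; the
    rounding error is at most half a frequency step.
    """
    kt = tilt.k_tau(wavelength_nm)
    d_ky, d_kx = grid.step
    return np.array([np.round(kt[0] / d_kx) * d_kx, np.round(kt[1] / d_ky) * d_ky])


def fresnel_propagator(grid: FrequencyGrid, wavelength_nm: float, dz: float) -> np.ndarray:
    """Fourier-space Fresnel propagator exp(-i pi lam dz |k|^2)."""
    return np.exp(-1j * np.pi * wavelength_nm * dz * grid.kmag() ** 2)


def multislice_exit_wave(
    phantom: Phantom, tilt: Tilt, system: OpticalSystem
) -> np.ndarray:
    """Exit wave for tilted plane-wave illumination of a sliced specimen.

    Starts from the incident wave exp(2 pi i k_tau . r) (k_tau snapped to
    the grid), then alternates slice transmission and Fresnel propagation
    over the slice thickness. For a single slice of zero thickness the
    result is exactly ``O(r) exp(2 pi i k_tau . r)``.
    """
    grid = FrequencyGrid(phantom.shape, phantom.pixel_size)
    lam = system.wavelength_nm
    kt = snap_tilt_to_grid(tilt, grid, lam)
    x, y = grid.coords()
    psi = np.exp(2j * np.pi * (kt[0] * x + kt[1] * y))
    prop = None
    if phantom.slice_thickness > 0:
        prop = fresnel_propagator(grid, lam, phantom.slice_thickness)
    for s in range(phantom.n_slices):
        psi = psi * phantom.transmission(s)
        if prop is not None and s < phantom.n_slices - 1:
            psi = np.fft.ifft2(np.fft.fft2(psi) * prop)
    return psi


def image_from_exit_wave(
    exit_wave: np.ndarray,
    grid: FrequencyGrid,
    system: OpticalSystem,
) -> np.ndarray:
    """Image intensity |F^-1[ F[psi_ex](k) w(k) ]|^2 with the axial WTF.

    The beam tilt is carried by the exit wave itself (its spectrum is
    shifted to k_tau), so the transfer function applied here is always
    the axial one.
    """
    if exit_wave.shape != grid.shape:
        raise ForwardError("exit wave and grid shapes differ")
    w = axial_wtf(grid, system)
    psi_im = np.fft.ifft2(np.fft.fft2(exit_wave) * w)
    return np.abs(psi_im) ** 2


# ---------------------------------------------------------------------------
# Detector


@dataclass(frozen=True)
class DetectorModel:
    """Parametric detector: Poisson counting plus a Gaussian MTF.

    ``mtf_sigma`` is the standard deviation (cycles/pixel) of the Gaussian
    modulation-transfer function; ``None`` disables the blur. The kernel
    is unit-sum (MTF(0) = 1) so the expected total count is preserved.
    """

    mtf_sigma: float | None = 0.35
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ForwardError("detector gain must be positive")


def _apply_mtf(counts: np.ndarray, mtf_sigma: float) -> np.ndarray:
    # Gaussian MTF of std sigma_f cycles/px <-> real-space Gaussian of
    # std 1/(2 pi sigma_f) px; gaussian_filter preserves the mean (unit-sum).
    sigma_px = 1.0 / (2.0 * np.pi * mtf_sigma)
    return gaussian_filter(counts, sigma_px, mode="wrap")


def apply_detector(
    expected_image: np.ndarray,
    fluence: float,
    pixel_size: float,
    detector: DetectorModel,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> np.ndarray:
    """Convert a normalized intensity into detector counts.

    ``expected_image`` must be nonnegative with mean ~1 (unit incident
    flux); expected counts per pixel are ``fluence * pixel_size^2 *
    intensity``. With ``noiseless=True`` (the infinite-fluence mode) the
    scaled expectation is returned exactly; otherwise Poisson counts are
    drawn and blurred by the MTF kernel.
    """
    img = np.asarray(expected_image, dtype=float)
    if np.any(img < 0):
        raise ForwardError("expected image must be nonnegative")
    if fluence <= 0:
        raise ForwardError("fluence must be positive")
    expected = fluence * pixel_size**2 * img * detector.gain
    if noiseless:
        return expected
    if rng is None:
        rng = np.random.default_rng(detector.seed)
    counts = rng.poisson(expected / detector.gain).astype(float) * detector.gain
    if detector.mtf_sigma:
        counts = _apply_mtf(counts, detector.mtf_sigma)
    return counts


# ---------------------------------------------------------------------------
# Tilt series


@dataclass(frozen=True)
class TiltProtocol:
    """Acquisition protocol: tilt magnitude, azimuth count, axial image or not.

    Azimuths are equally spaced at 2 pi j / n. The two presets mirror
    the standard designs: ``robust()`` = 1 axial + 6 tilts,
    ``low_fluence()`` = 4 tilts, no axial exposure.
    """

    tilt_mrad: float
    n_azimuths: int
    include_axial: bool

    def __post_init__(self) -> None:
        if self.n_azimuths <= 0 and not self.include_axial:
            raise ForwardError("protocol requests zero images")

    @classmethod
    def robust(cls, tilt_mrad: float = 10.0) -> "TiltProtocol":
        return cls(tilt_mrad=tilt_mrad, n_azimuths=6, include_axial=True)

    @classmethod
    def low_fluence(cls, tilt_mrad: float = 5.0) -> "TiltProtocol":
        return cls(tilt_mrad=tilt_mrad, n_azimuths=4, include_axial=False)

    def tilts(self) -> list[Tilt]:
        out: list[Tilt] = []
        if self.include_axial:
            out.append(Tilt(0.0))
        out.extend(
            Tilt(self.tilt_mrad * 1e-3, 2.0 * np.pi * j / self.n_azimuths)
            for j in range(self.n_azimuths)
        )
        return out


@dataclass
class TiltSeries:
    """A stack of intensity images with one beam tilt each.

    The unit of I/O between simulation, preprocessing and reconstruction.
    """

    images: np.ndarray
    tilts: list[Tilt]
    pixel_size: float
    fluence_per_image: float
    optics: OpticalSystem
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ForwardError("images must be a 3-D stack")
        if len(self.tilts) != self.images.shape[0]:
            raise ForwardError(
                f"{self.images.shape[0]} images but {len(self.tilts)} tilts"
            )
        if np.any(self.images < 0):
            raise ForwardError("image intensities must be nonnegative")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def total_fluence(self) -> float:
        return self.fluence_per_image * self.n_images

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.images.shape[1:], self.pixel_size)


def simulate_tilt_series(
    phantom: Phantom,
    protocol: TiltProtocol,
    system: OpticalSystem,
    detector: DetectorModel,
    total_fluence: float,
    noiseless: bool = False,
) -> TiltSeries:
    """Simulate a complete tilt series under a total fluence budget.

    The budget is split equally across images (uniform exposure). Each
    image runs multislice_exit_wave -> image_from_exit_wave ->
    apply_detector; the intensity is normalized to unit mean before
    detection so the counts respect the per-image fluence. Per-image RNG
    streams derive from the detector seed and image index, making the
    whole series bit-reproducible.
    """
    tilts = protocol.tilts()
    n = len(tilts)
    if n == 0:
        raise ForwardError("protocol yields zero images")
    fluence = total_fluence / n
    grid = FrequencyGrid(phantom.shape, phantom.pixel_size)
    images = np.empty((n,) + phantom.shape)
    for j, tilt in enumerate(tilts):
        psi = multislice_exit_wave(phantom, tilt, system)
        intensity = image_from_exit_wave(psi, grid, system)
        intensity = intensity / intensity.mean()
        rng = np.random.default_rng([detector.seed, j])
        images[j] = apply_detector(
            intensity, fluence, phantom.pixel_size, detector, rng=rng, noiseless=noiseless
        )
    return TiltSeries(
        images=images,
        tilts=tilts,
        pixel_size=phantom.pixel_size,
        fluence_per_image=fluence,
        optics=system,
        provenance={
            "phantom": phantom.kind,
            "seed": detector.seed,
            "noiseless": bool(noiseless),
            "protocol": {
                "tilt_mrad": protocol.tilt_mrad,
                "n_azimuths": protocol.n_azimuths,
                "include_axial": protocol.include_axial,
            },
        },
    )
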