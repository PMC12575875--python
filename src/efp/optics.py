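"""Electron-optical model for tilted-illumination TEM.

Wavelength, the aberration phase :math:`\\chi(k)` (defocus ``C1`` and
spherical aberration ``C3`` only, Saxton sign convention with overfocus
positive), the axial and tilted-illumination wave transfer functions with
partial-coherence envelopes, and the closed-form beam-tilt relations used
to plan a Fourier-ptychography experiment: the optimal ``C1``/``C3``
coupling, the tilt-induced image shift, and the tilt-induced defocus
change.

Units are nanometres, inverse nanometres and radians throughout; the
constructors accept the conventional experimental units (kV, mm for
``C3``, mrad) and convert once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants


class OpticsError(ValueError):
    """Invalid optical parameter or geometry."""


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron de Broglie wavelength in nm.

    lambda = h c / sqrt(E (E + 2 m0 c^2)) with E the kinetic energy.

    Parameters
    ----------
    voltage_kv:
        Accelerating voltage in kilovolts; must be positive.
    """
    if voltage_kv <= 0:
        raise OpticsError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    e_joule = voltage_kv * 1e3 * constants.e
    rest = constants.m_e * constants.c**2
    lam_m = constants.h * constants.c / np.sqrt(e_joule * (e_joule + 2.0 * rest))
    return lam_m * 1e9


@dataclass(frozen=True)
class OpticalSystem:
    """Imaging-system parameters of a (possibly aberration-corrected) TEM.

    Parameters
    ----------
    voltage_kv:
        Accelerating voltage (kV).
    c1_nm:
        Defocus C1 in nm; positive values are overfocus.
    c3_mm:
        Spherical aberration C3 in mm (converted to nm internally).
    focal_spread_nm:
        Focal spread Delta (nm), the width of the defocus distribution
        driving the partial temporal coherence envelope.
    illum_semiangle_mrad:
        RMS illumination semi-angle beta (mrad), driving the partial
        spatial coherence envelope.
    aperture_kmax_invnm:
        Optional hard objective-aperture cutoff (nm^-1); ``None`` means
        no aperture.
    transfer_threshold:
        Information-transfer fraction defining the usable passband
        (default 0.10, i.e. the conventional 10% transfer limit).
    """

    voltage_kv: float = 300.0
    c1_nm: float = 0.0
    c3_mm: float = 0.0
    focal_spread_nm: float = 0.0
    illum_semiangle_mrad: float = 0.0
    aperture_kmax_invnm: float | None = None
    transfer_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise OpticsError("voltage must be positive")
        if self.focal_spread_nm < 0:
            raise OpticsError("focal spread must be nonnegative")
        if self.illum_semiangle_mrad < 0:
            raise OpticsError("illumination semi-angle must be nonnegative")
        if not (0.0 < self.transfer_threshold <= 1.0):
            raise OpticsError("transfer_threshold must be in (0, 1]")

    @property
    def wavelength_nm(self) -> float:
        """Electron wavelength (nm), always recomputed from the voltage."""
        return electron_wavelength(self.voltage_kv)

    @property
    def c3_nm(self) -> float:
        return self.c3_mm * 1e6

    @property
    def illum_semiangle_rad(self) -> float:
        return self.illum_semiangle_mrad * 1e-3


@dataclass(frozen=True)
class Tilt:
    """Beam tilt: magnitude tau and azimuth, both in radians.

    Magnitude zero denotes axial illumination. The illumination
    wavevector is ``k_tau = (tau/lambda) (cos az, sin az)``.
    """

    magnitude: float
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise OpticsError("tilt magnitude must be nonnegative")

    @classmethod
    def from_mrad(cls, magnitude_mrad: float, azimuth_deg: float = 0.0) -> "Tilt":
        return cls(magnitude_mrad * 1e-3, np.deg2rad(azimuth_deg))

    @property
    def magnitude_mrad(self) -> float:
        return self.magnitude * 1e3

    @property
    def azimuth_deg(self) -> float:
        return float(np.rad2deg(self.azimuth))

    def unit_vector(self) -> np.ndarray:
        """(x, y) unit vector along the tilt azimuth."""
        return np.array([np.cos(self.azimuth), np.sin(self.azimuth)])

    def k_tau(self, wavelength_nm: float) -> np.ndarray:
        """Illumination wavevector (kx, ky) in nm^-1: tau/lambda along azimuth."""
        return (self.magnitude / wavelength_nm) * self.unit_vector()


@dataclass
class FrequencyGrid:
    """Spatial-frequency sampling of an image in FFT layout.

    Zero frequency sits at index [0, 0] (numpy ``fftfreq`` convention);
    frequencies span +-1/(2 px) with step 1/(n px) along each axis.
    Arrays are indexed [row, col] with ``kx`` varying along columns and
    ``ky`` along rows.
    """

    shape: tuple[int, int]
    pixel_size: float
    kx: np.ndarray = field(init=False, repr=False)
    ky: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise OpticsError("pixel size must be positive")
        ny, nx = self.shape
        fx = np.fft.fftfreq(nx, d=self.pixel_size)
        fy = np.fft.fftfreq(ny, d=self.pixel_size)
        self.kx, self.ky = np.meshgrid(fx, fy)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size)

    @property
    def step(self) -> tuple[float, float]:
        """Frequency step (d_ky, d_kx) = 1 / extent."""
        ny, nx = self.shape
        return 1.0 / (ny * self.pixel_size), 1.0 / (nx * self.pixel_size)

    def kmag(self) -> np.ndarray:
        return np.hypot(self.kx, self.ky)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Real-space coordinate fields (x, y) in nm, origin at pixel [0, 0]."""
        ny, nx = self.shape
        x = np.arange(nx) * self.pixel_size
        y = np.arange(ny) * self.pixel_size
        return np.meshgrid(x, y)


# ---------------------------------------------------------------------------
# Aberration phase and its gradient


def aberration_phase(kmag, system: OpticalSystem):
    """Aberration phase chi(k) = pi lam C1 k^2 + (pi/2) lam^3 C3 k^4 (radians).

    ``kmag`` is |k| in nm^-1 (scalar or array). Only defocus and spherical
    aberration are modelled; overfocus (C1 > 0) gives chi > 0.
    """
    k2 = np.asarray(kmag, dtype=float) ** 2
    lam = system.wavelength_nm
    return np.pi * lam * system.c1_nm * k2 + 0.5 * np.pi * lam**3 * system.c3_nm * k2**2


def aberration_phase_gradient(kmag, system: OpticalSystem):
    """|d chi / dk| magnitude: 2 pi lam (C1 k + lam^2 C3 k^3)."""
    k = np.asarray(kmag, dtype=float)
    lam = system.wavelength_nm
    return 2.0 * np.pi * lam * (system.c1_nm * k + lam**2 * system.c3_nm * k**3)


# ---------------------------------------------------------------------------
# Transfer functions


def _temporal_envelope(arg_k2, system: OpticalSystem):
    """exp(-[(pi lam Delta / 2) * arg]^2) with arg an effective |k|^2 term."""
    lam = system.wavelength_nm
    c = np.pi * lam * system.focal_spread_nm / 2.0
    return np.exp(-((c * np.asarray(arg_k2, dtype=float)) ** 2))


def _spatial_envelope(kmag, system: OpticalSystem):
    """exp(-(beta/lam)^2 |grad chi|^2 / 2), Gaussian source of RMS semi-angle beta."""
    beta = system.illum_semiangle_rad
    if beta == 0.0:
        return np.ones_like(np.asarray(kmag, dtype=float))
    g = aberration_phase_gradient(kmag, system)
    return np.exp(-0.5 * (beta / system.wavelength_nm) ** 2 * g**2)


def _aperture(kmag, system: OpticalSystem):
    if system.aperture_kmax_invnm is None:
        return np.ones_like(np.asarray(kmag, dtype=float))
    return (np.asarray(kmag) <= system.aperture_kmax_invnm).astype(float)


def axial_wtf(grid: FrequencyGrid, system: OpticalSystem) -> np.ndarray:
    """Axial wave transfer function w(k) = A(k) exp(-i chi(k)) Et(k) Es(k).

    This is the complex multiplier applied to the exit-wave spectrum to
    form the image wave; |w| <= 1 everywhere.
    """
    kmag = grid.kmag()
    chi = aberration_phase(kmag, system)
    return (
        _aperture(kmag, system)
        * np.exp(-1j * chi)
        * _temporal_envelope(kmag**2, system)
        * _spatial_envelope(kmag, system)
    )


def effective_wtf(
    grid: FrequencyGrid,
    system: OpticalSystem,
    tilt: Tilt,
    include_spatial: bool = True,
    include_temporal: bool = True,
) -> np.ndarray:
    """Effective wave transfer function w'(q, k_tau) for tilted illumination.

    Valid under the weak-phase-object approximation, where the beam tilt
    can be folded into the transfer function acting on the *untilted*
    object spectrum at frequency q:

        w'(q) = A(q + kt) exp(-i [chi(q + kt) - chi(kt)]) Et'(q) Es'(q)

    with the achromatic temporal envelope
    ``Et' = exp(-[(pi lam Delta/2)(|q+kt|^2 - |kt|^2)]^2)`` (maximal on the
    circle |q+kt| = |kt|, producing annular transfer at large tilt) and the
    spatial envelope evaluated at the shifted frequency. The linear phase
    ramp (pure image shift) is excluded; shift compensation is a
    preprocessing step.
    """
    lam = system.wavelength_nm
    kt = tilt.k_tau(lam)
    kt_mag = float(np.hypot(*kt))
    # passband must intersect the sampled frequencies
    if kt_mag > 0 and kt_mag - grid.kmag().max() > (
        system.aperture_kmax_invnm or grid.nyquist
    ):
        raise OpticsError("tilt passband lies entirely outside the frequency grid")
    qx = grid.kx + kt[0]
    qy = grid.ky + kt[1]
    qmag = np.hypot(qx, qy)
    chi_shift = aberration_phase(qmag, system) - aberration_phase(kt_mag, system)
    w = _aperture(qmag, system) * np.exp(-1j * chi_shift)
    if include_temporal:
        w = w * _temporal_envelope(qmag**2 - kt_mag**2, system)
    if include_spatial:
        w = w * _spatial_envelope(qmag, system)
    return w


# ---------------------------------------------------------------------------
# Closed-form tilt relations


def central_transfer_loss(system: OpticalSystem, tau: float) -> float:
    """Fractional information-transfer loss at the centre of the tilted passband.

    1 - Et' at q = -k_tau, i.e. 1 - exp(-[(pi lam Delta / 2) |k_tau|^2]^2)
    with |k_tau| = tau/lambda. Zero for axial illumination or a perfectly
    monochromatic/stable instrument (Delta = 0); grows steeply with tilt.
    """
    if tau < 0:
        raise OpticsError("tilt magnitude must be nonnegative")
    kt2 = (tau / system.wavelength_nm) ** 2
    return float(1.0 - _temporal_envelope(kt2, system))


def optimal_tilt(c1_nm: float, c3_mm: float) -> float:
    """Optimal-coupling tilt magnitude (radians): C1 = -C3 tau^2.

    Balancing defocus against spherical aberration symmetrises the
    spatial-coherence envelope of the tilted transfer function. Requires
    C1 and C3 of opposite sign (underfocus with positive C3); C1 = 0
    gives tau = 0.
    """
    if c1_nm == 0.0:
        return 0.0
    c3_nm = c3_mm * 1e6
    if c3_nm == 0.0 or c1_nm / c3_nm > 0:
        raise OpticsError(
            "optimal coupling requires C1 and C3 of opposite sign and C3 != 0"
        )
    return float(np.sqrt(-c1_nm / c3_nm))


def tilt_defocus_offset(system: OpticalSystem, tau: float) -> tuple[float, float]:
    """Defocus change introduced by a beam tilt: (Delta C1 in nm, |Delta C1 / C1|).

    Tilting by tau shifts the effective defocus by 2 C3 tau^2. The
    relative offset is undefined for C1 = 0 (raised) unless the change
    itself is zero.
    """
    delta_c1 = 2.0 * system.c3_nm * tau**2
    if delta_c1 == 0.0:
        return 0.0, 0.0
    if system.c1_nm == 0.0:
        raise OpticsError("relative defocus offset undefined for C1 = 0")
    return float(delta_c1), float(abs(delta_c1) / abs(system.c1_nm))


def tilt_induced_shift(system: OpticalSystem, tilt: Tilt) -> np.ndarray:
    """Image shift (x, y) in nm caused by aberrations under beam tilt.

    s = (C1 tau + C3 tau^3) along the tilt azimuth — the gradient of the
    aberration phase at k_tau divided by 2 pi. This displacement adds to
    stage drift and must be compensated before reconstruction.
    """
    tau = tilt.magnitude
    s = system.c1_nm * tau + system.c3_nm * tau**3
    return s * tilt.unit_vector()


def extended_resolution(axial_limit_nm: float, tau: float, voltage_kv: float) -> float:
    """Resolution (nm) reachable by tilting: 1 / (1/d_axial + tau/lambda).

    The tilt shifts the passband by |k_tau| = tau/lambda, extending the
    maximum transferred frequency along the tilt direction by that amount.
    """
    if axial_limit_nm <= 0:
        raise OpticsError("axial resolution limit must be positive")
    k_ext = 1.0 / axial_limit_nm + tau / electron_wavelength(voltage_kv)
    return 1.0 / k_ext
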