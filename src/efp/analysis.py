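"""Quantitative evaluation of Fourier-ptychographic reconstructions.

Synthetic-aperture redundancy maps (how many independent illuminations
cover each spatial frequency), PSNR of reconstructed phase against a
ground truth, circularly averaged power spectra, and the I/sigma
detectability score for Bragg reflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import FrequencyGrid, OpticalSystem, Tilt, effective_wtf

PSNR_CAP_DB = 300.0


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Synthetic-aperture redundancy


@dataclass
class RedundancyMap:
    """Per-frequency count of independent measurements on a frequency grid.

    A frequency is covered by an illumination when the magnitude of its
    effective transfer there is at least ``threshold`` (the 10%
    information-transfer convention by default). Only frequencies with
    count >= 2 carry enough information to reconstruct the complex
    wave — they define the usable synthetic aperture.
    """

    counts: np.ndarray
    threshold: float
    tilts: list[Tilt]
    grid: FrequencyGrid

    def mask(self, min_count: int = 2) -> np.ndarray:
        return self.counts >= min_count

    def aperture_limits(self, min_count: int = 2, n_azimuth_bins: int = 360):
        """(best, worst) resolution in nm of the redundancy boundary.

        ``best`` is 1/max|q| over the masked support (highest frequency
        reached in any direction); ``worst`` is 1/min over azimuthal bins
        of the directional maximum frequency — the aperture radius in its
        weakest direction.
        """
        m = self.mask(min_count)
        if not m.any():
            return np.inf, np.inf
        kmag = self.grid.kmag()[m]
        az = np.arctan2(self.grid.ky[m], self.grid.kx[m])
        kmax_all = kmag.max()
        bins = ((az + np.pi) / (2 * np.pi) * n_azimuth_bins).astype(int) % n_azimuth_bins
        per_bin = np.zeros(n_azimuth_bins)
        np.maximum.at(per_bin, bins, kmag)
        occupied = per_bin > 0
        kmin_dir = per_bin[occupied].min() if occupied.any() else kmax_all
        return 1.0 / kmax_all, 1.0 / kmin_dir


def redundancy_map(
    system: OpticalSystem,
    tilts: list[Tilt],
    grid: FrequencyGrid,
    threshold: float | None = None,
    binary_disc_radius: float | None = None,
) -> RedundancyMap:
    """Count, per object frequency q, the illuminations that measure it.

    With ``binary_disc_radius`` set, coverage is purely geometric:
    |q + k_tau| <= radius (hard discs, no envelopes) — useful for exact
    geometric checks. Otherwise coverage means |w'(q, k_tau)| >=
    threshold with the full coherence envelopes.
    """
    if not tilts:
        raise AnalysisError("tilt list is empty")
    thr = system.transfer_threshold if threshold is None else threshold
    if not (0.0 < thr <= 1.0):
        raise AnalysisError("threshold must be in (0, 1]")
    counts = np.zeros(grid.shape, dtype=int)
    lam = system.wavelength_nm
    for tilt in tilts:
        if binary_disc_radius is not None:
            kt = tilt.k_tau(lam)
            counts += (
                np.hypot(grid.kx + kt[0], grid.ky + kt[1]) <= binary_disc_radius
            ).astype(int)
        else:
            counts += (np.abs(effective_wtf(grid, system, tilt)) >= thr).astype(int)
    return RedundancyMap(counts=counts, threshold=thr, tilts=list(tilts), grid=grid)


# ---------------------------------------------------------------------------
# PSNR


def psnr(reconstructed_phase: np.ndarray, truth_phase: np.ndarray) -> float:
    """Peak signal-to-noise ratio (dB) of a phase map against ground truth.

    10 log10(P^2 / MSE) with P the dynamic range (max - min) of the
    truth. The mean difference between the fields is removed first:
    phase retrieval carries a global phase (constant offset) gauge
    freedom that must not count as error. Identical fields return the
    cap sentinel (300 dB).
    """
    rec = np.asarray(reconstructed_phase, dtype=float)
    tru = np.asarray(truth_phase, dtype=float)
    if rec.shape != tru.shape:
        raise AnalysisError("shape mismatch")
    peak = tru.max() - tru.min()
    if peak == 0:
        raise AnalysisError("truth phase has zero dynamic range")
    diff = rec - tru
    diff = diff - diff.mean()
    mse = np.mean(diff**2)
    if mse == 0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(peak**2 / mse), PSNR_CAP_DB))


# ---------------------------------------------------------------------------
# Radial profiles


@dataclass
class RadialProfile:
    """Circularly averaged profile: bin centres (nm^-1), means, counts."""

    k: np.ndarray
    value: np.ndarray
    count: np.ndarray

    def normalized_to(self, k_peak: float) -> "RadialProfile":
        """Profile divided by its value in the bin nearest ``k_peak``."""
        i = int(np.argmin(np.abs(self.k - k_peak)))
        ref = self.value[i]
        if ref == 0:
            raise AnalysisError("normalization bin has zero value")
        return RadialProfile(self.k, self.value / ref, self.count)


def circular_average(field2d: np.ndarray, grid: FrequencyGrid) -> RadialProfile:
    """Mean of a 2-D field over annular frequency bins one step wide."""
    if field2d.shape != grid.shape:
        raise AnalysisError("field and grid shapes differ")
    dk = min(grid.step)
    idx = np.round(grid.kmag() / dk).astype(int).ravel()
    vals = np.asarray(field2d, dtype=float).ravel()
    count = np.bincount(idx)
    total = np.bincount(idx, weights=vals)
    nz = count > 0
    mean = np.zeros_like(total)
    mean[nz] = total[nz] / count[nz]
    k = np.arange(len(count)) * dk
    return RadialProfile(k=k[nz], value=mean[nz], count=count[nz])


def display_weighted(power_spectrum: np.ndarray, exponent: float = 0.2) -> np.ndarray:
    """Power spectrum compressed as intensity**exponent for display only."""
    return np.asarray(power_spectrum, dtype=float) ** exponent


# ---------------------------------------------------------------------------
# Reflection I/sigma


@dataclass
class ReflectionScore:
    """Detectability of one reflection in a power spectrum."""

    peak_position: tuple[float, float]
    intensity: float
    background_sigma: float
    i_over_sigma: float


def reflection_i_over_sigma(
    spectrum: np.ndarray,
    grid: FrequencyGrid,
    peak: tuple[float, float],
    peak_radius: float,
    bg_radii: tuple[float, float],
) -> ReflectionScore:
    """Background-subtracted mean peak intensity over local background sigma.

    ``peak`` is the reflection position (kx, ky) in nm^-1; the peak is
    integrated over a disc of ``peak_radius`` and the background is
    taken from the annulus ``bg_radii`` = (inner, outer), which must
    enclose and exclude the peak disc.
    """
    inner, outer = bg_radii
    if not (inner >= peak_radius and outer > inner):
        raise AnalysisError("background annulus must enclose and exclude the peak disc")
    dist = np.hypot(grid.kx - peak[0], grid.ky - peak[1])
    peak_mask = dist <= peak_radius
    bg_mask = (dist > inner) & (dist <= outer)
    if not peak_mask.any() or not bg_mask.any():
        raise AnalysisError("peak or background region contains no grid points")
    spec = np.asarray(spectrum, dtype=float)
    bg = spec[bg_mask]
    sigma = bg.std()
    intensity = spec[peak_mask].mean() - bg.mean()
    if sigma == 0:
        raise AnalysisError("zero-variance background; I/sigma undefined")
    return ReflectionScore(
        peak_position=tuple(peak),
        intensity=float(intensity),
        background_sigma=float(sigma),
        i_over_sigma=float(intensity / sigma),
    )
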