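"""Pre-reconstruction steps: defocus estimation, registration, shift compensation.

Three steps run between acquisition and reconstruction:

1. ``estimate_defocus`` — cross-correlate the rotationally averaged,
   background-subtracted amplitude spectrum against |sin chi| CTF
   templates over a defocus grid, optionally per patch with 3x-MAD
   outlier rejection.
2. ``register_images`` — phase-correlation drift measurement against a
   reference image, with subpixel refinement.
3. ``compensate_tilt_shift`` — remove the measured displacement, which
   combines stage drift with the image shift (C1 tau + C3 tau^3) that
   beam tilt induces through the residual axial aberrations. The two
   contributions cannot be separated by registration alone; the report
   records the measured, predicted (tilt-induced) and applied vectors so
   the drift remainder is auditable.

Shift vectors are (row, col) pixels throughout, matching numpy indexing;
an optical shift (x, y) in nm maps to (y/p, x/p) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import fourier_shift, median_filter
from skimage.registration import phase_cross_correlation

from .analysis import circular_average
from .optics import (
    FrequencyGrid,
    OpticalSystem,
    Tilt,
    aberration_phase,
    tilt_induced_shift,
)


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Defocus estimation


@dataclass
class DefocusEstimate:
    """Defocus C1 (nm) with standard error and diagnostic flags."""

    c1_nm: float
    se_nm: float
    n_patches_used: int
    sign_ambiguous: bool = False
    low_confidence: bool = False


def _radial_amplitude_spectrum(image: np.ndarray, pixel_size: float):
    """Rotationally averaged, background-subtracted amplitude spectrum.

    A Hann window suppresses edge streaks; the smooth spectral background
    is removed with a running median over a window 1/20 of Nyquist wide,
    leaving the CTF oscillation.
    """
    img = image - image.mean()
    win = np.hanning(img.shape[0])[:, None] * np.hanning(img.shape[1])[None, :]
    amp = np.abs(np.fft.fft2(img * win))
    grid = FrequencyGrid(image.shape, pixel_size)
    prof = circular_average(amp, grid)
    window_bins = max(3, int(round(len(prof.k) / 20)))
    background = median_filter(prof.value, size=window_bins, mode="nearest")
    return prof.k, prof.value - background


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    return float(np.sum(a * b) / denom) if denom > 0 else 0.0


def _ctf_scores(k, spectrum, system, c1_grid, fit_band):
    lo, hi = fit_band
    band = (k >= lo) & (k <= hi)
    kb, sb = k[band], spectrum[band]
    scores = np.empty(len(c1_grid))
    for i, c1 in enumerate(c1_grid):
        trial = OpticalSystem(
            voltage_kv=system.voltage_kv,
            c1_nm=float(c1),
            c3_mm=system.c3_mm,
            focal_spread_nm=system.focal_spread_nm,
            illum_semiangle_mrad=system.illum_semiangle_mrad,
        )
        template = np.abs(np.sin(aberration_phase(kb, trial)))
        scores[i] = _zncc(sb, template)
    return scores


def _parabolic_refine(grid_vals, scores, i):
    if i == 0 or i == len(scores) - 1:
        return float(grid_vals[i])
    y0, y1, y2 = scores[i - 1], scores[i], scores[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(grid_vals[i])
    frac = 0.5 * (y0 - y2) / denom
    step = grid_vals[i + 1] - grid_vals[i]
    return float(grid_vals[i] + np.clip(frac, -1, 1) * step)


def _single_estimate(patch, pixel_size, system, c1_grid, fit_band):
    k, spec = _radial_amplitude_spectrum(patch, pixel_size)
    scores = _ctf_scores(k, spec, system, c1_grid, fit_band)
    i = int(np.argmax(scores))
    return _parabolic_refine(c1_grid, scores, i), scores[i]


def estimate_defocus(
    image: np.ndarray,
    pixel_size: float,
    system: OpticalSystem,
    c1_grid,
    patches: tuple[int, int] | None = (4, 4),
    fit_band: tuple[float, float] | None = None,
    min_correlation: float = 0.2,
) -> DefocusEstimate:
    """Estimate defocus C1 from the CTF oscillation of an image spectrum.

    Each patch (default 4 x 4 tiling; ``None`` = whole image) yields an
    argmax over ``c1_grid`` (a monotone list of trial defoci, nm) with
    parabolic refinement. Patch estimates farther than three times the
    median absolute deviation from the median are rejected; the mean and
    standard error of the survivors are returned. The fit band defaults
    to 1/10 .. 9/10 of Nyquist, excluding the structure-dominated low
    frequencies. When C3 is negligible |sin chi| is even in C1, so the
    defocus sign is flagged ambiguous; a best correlation below
    ``min_correlation`` sets the low-confidence flag.
    """
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 128:
        raise PreprocessError("image must be at least 128 pixels on each side")
    c1_grid = np.asarray(c1_grid, dtype=float)
    if len(c1_grid) < 3 or np.any(np.diff(c1_grid) <= 0):
        raise PreprocessError("c1_grid must be monotone increasing, length >= 3")
    nyq = 1.0 / (2.0 * pixel_size)
    if fit_band is None:
        fit_band = (nyq / 10.0, 0.9 * nyq)

    if patches is None:
        c1, score = _single_estimate(image, pixel_size, system, c1_grid, fit_band)
        return DefocusEstimate(
            c1_nm=c1,
            se_nm=0.0,
            n_patches_used=1,
            sign_ambiguous=_sign_blind(system),
            low_confidence=score < min_correlation,
        )

    pr, pc = patches
    ny, nx = image.shape
    hy, hx = ny // pr, nx // pc
    estimates, scores = [], []
    for r in range(pr):
        for c in range(pc):
            patch = image[r * hy : (r + 1) * hy, c * hx : (c + 1) * hx]
            c1, s = _single_estimate(patch, pixel_size, system, c1_grid, fit_band)
            estimates.append(c1)
            scores.append(s)
    estimates = np.array(estimates)
    med = np.median(estimates)
    mad = np.median(np.abs(estimates - med))
    keep = (
        np.abs(estimates - med) <= 3.0 * mad
        if mad > 0
        else np.abs(estimates - med) <= np.finfo(float).eps * max(1.0, abs(med))
    )
    survivors = estimates[keep]
    if survivors.size == 0:
        raise PreprocessError("all patch estimates rejected as outliers")
    se = (
        float(survivors.std(ddof=1) / np.sqrt(survivors.size))
        if survivors.size > 1
        else 0.0
    )
    return DefocusEstimate(
        c1_nm=float(survivors.mean()),
        se_nm=se,
        n_patches_used=int(survivors.size),
        sign_ambiguous=_sign_blind(system),
        low_confidence=float(np.median(scores)) < min_correlation,
    )


def _sign_blind(system: OpticalSystem) -> bool:
    # with C3 ~ 0 the CTF magnitude is invariant under C1 -> -C1
    return abs(system.c3_nm) < 1.0


def effective_to_axial_defocus(c1_effective_nm: float, c3_mm: float, tau: float) -> float:
    """Axial C1 from the effective defocus measured on a tilted image.

    Beam tilt adds 2 C3 tau^2 to the effective defocus; subtracting it
    recovers the axial value (the procedure used when no axial image is
    collected).
    """
    return c1_effective_nm - 2.0 * c3_mm * 1e6 * tau**2


# ---------------------------------------------------------------------------
# Registration


def register_images(
    stack: np.ndarray,
    reference_index: int = 0,
    upsample_factor: int = 50,
    band_invnm: tuple[float, float] | None = None,
    pixel_size: float | None = None,
) -> np.ndarray:
    """Per-image displacement (row, col) pixels relative to the reference.

    Phase correlation: unit-normalized cross-power spectrum, inverse
    transform, peak, subpixel refinement. The sign convention is fixed by
    ``np.roll``: an image equal to the reference rolled by (dy, dx)
    reports displacement (dy, dx). Integer circular shifts are exact;
    displacements are inverse-consistent (shift(A->B) = -shift(B->A)).

    ``band_invnm`` (with ``pixel_size``) restricts the correlation to a
    frequency band — registering tilted against axial images is biased
    by their differing contrast transfer beyond the first CTF zero, so
    the band is best kept below it.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise PreprocessError("need a stack of at least two images")
    if band_invnm is not None:
        if pixel_size is None:
            raise PreprocessError("band_invnm requires pixel_size")
        grid = FrequencyGrid(stack.shape[1:], pixel_size)
        kmag = grid.kmag()
        band = (kmag >= band_invnm[0]) & (kmag <= band_invnm[1])
        stack = np.stack(
            [np.fft.ifft2(np.fft.fft2(im) * band).real for im in stack]
        )
    ref = stack[reference_index]
    if ref.std() == 0:
        raise PreprocessError("reference image has zero variance; shift undefined")
    shifts = np.zeros((stack.shape[0], 2))
    for j, img in enumerate(stack):
        if j == reference_index:
            continue
        if img.std() == 0:
            raise PreprocessError(f"image {j} has zero variance; shift undefined")
        # skimage returns the shift that registers the moving image onto
        # the reference, i.e. minus the displacement
        shift, _, _ = phase_cross_correlation(
            ref, img, upsample_factor=upsample_factor, normalization="phase"
        )
        shifts[j] = -shift
    return shifts


def _fourier_translate(image: np.ndarray, shift_rowcol) -> np.ndarray:
    """Translate an image by a (possibly subpixel) (row, col) vector."""
    return np.fft.ifft2(fourier_shift(np.fft.fft2(image), shift_rowcol)).real


# ---------------------------------------------------------------------------
# Tilt-shift compensation


@dataclass
class PreprocessReport:
    """Audit trail of the shift pipeline, one entry per image."""

    measured_shift_px: np.ndarray
    predicted_shift_px: np.ndarray
    applied_shift_px: np.ndarray
    drift_px: np.ndarray
    c1_estimate: DefocusEstimate | None = None
    notes: list[str] = dc_field(default_factory=list)


def predicted_tilt_shift_px(
    system: OpticalSystem,
    tilt: Tilt,
    pixel_size: float,
    grid: FrequencyGrid | None = None,
) -> np.ndarray:
    """Tilt-induced image displacement in (row, col) pixels.

    With a ``grid``, the tilt wavevector is first snapped to the nearest
    grid frequency sample — the granularity at which both the simulator
    and the reconstruction realize beam tilts — so predictions stay
    consistent with what the data actually contain.
    """
    if grid is not None:
        from .forward import snap_tilt_to_grid  # local import avoids a cycle

        lam = system.wavelength_nm
        kt = snap_tilt_to_grid(tilt, grid, lam)
        kt_mag = float(np.hypot(*kt))
        if kt_mag == 0.0:
            return np.zeros(2)
        tau = kt_mag * lam
        u = kt / kt_mag
        s = (system.c1_nm * tau + system.c3_nm * tau**3) * u
    else:
        s = tilt_induced_shift(system, tilt)
    sx, sy = s
    return np.array([sy / pixel_size, sx / pixel_size])


def compensate_tilt_shift(
    stack: np.ndarray,
    shifts: np.ndarray,
    system: OpticalSystem,
    tilts: list[Tilt],
    pixel_size: float,
    reference_index: int = 0,
    snap_to_grid: bool = True,
) -> tuple[np.ndarray, PreprocessReport]:
    """Remove stage drift while preserving the optical tilt shift.

    ``shifts`` are the measured displacements from ``register_images``;
    each combines stage drift with the optical displacement
    (C1 tau + C3 tau^3)/pixel that beam tilt induces through the
    aberrations. That optical shift is part of the imaging model (the
    aberration phase applied around each tilted carrier), so blindly
    aligning the images would corrupt the reconstruction. Drift is
    therefore isolated as measured minus predicted tilt shift and only
    the drift is removed, by Fourier-domain subpixel translation: drift
    correction first, then the predicted tilt displacement is left
    compensated-for rather than flattened away.
    """
    stack = np.asarray(stack, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if not (stack.shape[0] == shifts.shape[0] == len(tilts)):
        raise PreprocessError("stack, shifts and tilts lengths differ")
    grid = FrequencyGrid(stack.shape[1:], pixel_size) if snap_to_grid else None
    predicted = np.array(
        [predicted_tilt_shift_px(system, t, pixel_size, grid=grid) for t in tilts]
    )
    # measured shifts are relative to the reference image, so the
    # predicted optical displacements must be referenced the same way
    rel_predicted = predicted - predicted[reference_index]
    applied = rel_predicted - shifts  # = -(measured drift)
    corrected = np.empty_like(stack)
    for j in range(stack.shape[0]):
        if np.allclose(applied[j], 0.0):
            corrected[j] = stack[j]
        else:
            corrected[j] = _fourier_translate(stack[j], applied[j])
    report = PreprocessReport(
        measured_shift_px=shifts,
        predicted_shift_px=predicted,
        applied_shift_px=applied,
        drift_px=shifts - rel_predicted,
        notes=["drift corrected, then tilt-induced shift compensated"],
    )
    return corrected, report
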