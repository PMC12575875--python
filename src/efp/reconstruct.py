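"""Modified Ptychographic Iterative Engine for tilted-illumination data.

The object spectrum lives on an upsampled Fourier canvas whose frequency
step equals the measurement step (the canvas is the super-resolved field
of view). For each illumination j, the shifted crop of the canvas at
-k_tau_j is the exit-wave spectrum seen through the axial transfer
function w(k): Psi_im = O_hat(k - k_tau_j) w(k). Each PIE visit replaces
the *amplitude* of the modelled image wave in real space by the measured
one and writes the resulting correction back into the canvas in Fourier
space — the reverse of the update spaces of conventional real-space PIE.

The update weighting is ePIE-style, conj(w) / ((1 + eps) max|w|^2), with
a small regularizer where the coherence envelopes vanish. The step size
follows a geometric decay schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .forward import TiltSeries
from .optics import FrequencyGrid, OpticalSystem, axial_wtf


class ReconstructionError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReconConfig:
    """PIE hyperparameters.

    Defaults follow standard practice for this geometry: initial step
    0.1 decayed by 0.5 every 10 iterations, 50 iterations, canvas
    upsampling factor 2 (enough whenever |k_tau| does not exceed the
    measurement Nyquist).
    """

    iterations: int = 50
    step0: float = 0.1
    decay_factor: float = 0.5
    decay_every: int = 10
    upsample: int = 2
    epsilon: float = 1e-3
    order: str = "fixed"  # "fixed" | "shuffled"
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ReconstructionError("iterations must be >= 0")
        if not (0.0 < self.step0 <= 1.0):
            raise ReconstructionError("step0 must be in (0, 1]")
        if not (0.0 < self.decay_factor <= 1.0):
            raise ReconstructionError("decay_factor must be in (0, 1]")
        if self.upsample < 1:
            raise ReconstructionError("upsample must be >= 1")
        if self.order not in ("fixed", "shuffled"):
            raise ReconstructionError("order must be 'fixed' or 'shuffled'")

    def step_at(self, iteration: int) -> float:
        """Step size at a zero-based iteration index."""
        return self.step0 * self.decay_factor ** (iteration // self.decay_every)


@dataclass
class ExitWaveEstimate:
    """Object spectrum on the upsampled Fourier canvas.

    The spectrum uses the measurement-grid FFT scale: an N x N crop of
    the canvas, inverse-transformed on the measurement grid, yields the
    exit wave band-limited to that passband. ``history`` records the
    normalized amplitude data error per iteration.
    """

    spectrum: np.ndarray
    pixel_size: float  # canvas real-space pixel (nm) = measurement pixel / upsample
    upsample: int
    history: list[float] = dc_field(default_factory=list)

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return self.spectrum.shape

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.canvas_shape, self.pixel_size)

    def exit_wave(self) -> np.ndarray:
        """Complex exit wave on the upsampled real-space grid."""
        return np.fft.ifft2(self.spectrum) * self.upsample**2

    def phase(self) -> np.ndarray:
        return np.angle(self.exit_wave())

    def amplitude(self) -> np.ndarray:
        return np.abs(self.exit_wave())


def initialize_estimate(
    shape: tuple[int, int], pixel_size: float, upsample: int = 2
) -> ExitWaveEstimate:
    """Unity-amplitude, zero-phase starting estimate.

    The canvas is ``upsample`` times the measurement shape; all spectral
    energy sits at zero frequency and the real-space wave is the
    constant 1.
    """
    if upsample < 1:
        raise ReconstructionError("upsample must be >= 1")
    ny, nx = shape
    canvas = np.zeros((upsample * ny, upsample * nx), dtype=complex)
    canvas[0, 0] = ny * nx  # measurement-grid FFT scale for the constant-1 field
    return ExitWaveEstimate(
        spectrum=canvas, pixel_size=pixel_size / upsample, upsample=upsample
    )


# ---------------------------------------------------------------------------
# Canvas indexing


def _canvas_indices(series: TiltSeries, upsample: int):
    """Per-tilt index arrays mapping the measurement grid into the canvas.

    Canvas and measurement share the frequency step 1/(N p); tilt j
    shifts the measurement passband by k_tau_j, rounded to the nearest
    canvas sample. Returns a list of (row_idx, col_idx) open-mesh pairs.
    """
    ny, nx = series.images.shape[1:]
    cy, cx = upsample * ny, upsample * nx
    lam = series.optics.wavelength_nm
    iy = (np.fft.fftfreq(ny) * ny).astype(int)
    ix = (np.fft.fftfreq(nx) * nx).astype(int)
    out = []
    for tilt in series.tilts:
        kt = tilt.k_tau(lam)
        oy = int(np.round(kt[1] * ny * series.pixel_size))
        ox = int(np.round(kt[0] * nx * series.pixel_size))
        if abs(oy) + ny // 2 > cy // 2 or abs(ox) + nx // 2 > cx // 2:
            raise ReconstructionError(
                f"tilt passband (offset {oy},{ox}) exceeds the canvas; "
                "increase the upsample factor"
            )
        # Psi_im(k) = O_hat(k - k_tau) w(k): measurement index i reads canvas i - o
        rows = (iy - oy) % cy
        cols = (ix - ox) % cx
        out.append(np.ix_(rows, cols))
    return out


# ---------------------------------------------------------------------------
# PIE loop


def pie_reconstruct(
    series: TiltSeries,
    system: OpticalSystem | None = None,
    config: ReconConfig | None = None,
) -> ExitWaveEstimate:
    """Reconstruct the complex exit wave from a preprocessed tilt series.

    Per visit of tilt j: crop the shifted sub-spectrum, apply the axial
    WTF, inverse-transform, replace the real-space amplitude with
    sqrt(I_j / mean I_j), transform back, and add the weighted spectral
    correction into the canvas.

    Exposure gauge: measured counts fix only the *relative* intensity of
    an image (per-image exposure and the envelope damping of the carrier
    are entangled), so each normalized measured amplitude is rescaled to
    the current model's RMS amplitude before replacement. With this
    gauge the true object is an exact fixed point of the iteration on
    noiseless data.
    """
    system = series.optics if system is None else system
    config = ReconConfig() if config is None else config
    est = initialize_estimate(series.images.shape[1:], series.pixel_size, config.upsample)
    if config.iterations == 0:
        return est

    grid = series.grid
    w = axial_wtf(grid, system)
    w_conj = np.conj(w)
    wmax2 = np.abs(w).max() ** 2
    denom = wmax2 * (1.0 + config.epsilon)
    indices = _canvas_indices(series, config.upsample)
    amplitudes = [
        np.sqrt(img / img.mean()) for img in series.images
    ]  # measured real-space amplitude targets
    order = np.arange(series.n_images)
    rng = np.random.default_rng(config.shuffle_seed)
    tiny = 1e-12

    for it in range(config.iterations):
        alpha = config.step_at(it)
        if config.order == "shuffled":
            order = rng.permutation(series.n_images)
        err_num = 0.0
        err_den = 0.0
        for j in order:
            sub = est.spectrum[indices[j]]
            psi_im_hat = sub * w
            psi_im = np.fft.ifft2(psi_im_hat)
            a_model = np.abs(psi_im)
            a_meas = amplitudes[j] * np.sqrt(np.mean(a_model**2))
            err_num += float(np.sum((a_model - a_meas) ** 2))
            err_den += float(np.sum(a_meas**2))
            psi_new = a_meas * psi_im / (a_model + tiny)
            delta = np.fft.fft2(psi_new) - psi_im_hat
            sub += alpha * (w_conj / denom) * delta
            est.spectrum[indices[j]] = sub
        err = err_num / err_den
        if not np.isfinite(err):
            raise ReconstructionError(f"non-finite update at iteration {it}")
        est.history.append(err)
    return est


def data_error(
    estimate: ExitWaveEstimate,
    series: TiltSeries,
    system: OpticalSystem | None = None,
) -> float:
    """Normalized amplitude misfit of an estimate against a tilt series.

    sum_j sum_r (|psi_im,j(r)| - a_j(r))^2 / sum_j sum_r a_j(r)^2 with
    a_j = sqrt(I_j/<I_j>) rescaled to the model's RMS amplitude (the
    same exposure gauge as the reconstruction). Invariant under a global
    phase of the estimate (amplitudes only).
    """
    system = series.optics if system is None else system
    grid = series.grid
    w = axial_wtf(grid, system)
    indices = _canvas_indices(series, estimate.upsample)
    num = 0.0
    den = 0.0
    for j in range(series.n_images):
        psi_im = np.fft.ifft2(estimate.spectrum[indices[j]] * w)
        a_model = np.abs(psi_im)
        a_meas = np.sqrt(series.images[j] / series.images[j].mean())
        a_meas = a_meas * np.sqrt(np.mean(a_model**2))
        num += float(np.sum((a_model - a_meas) ** 2))
        den += float(np.sum(a_meas**2))
    return num / den
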