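"""File formats, run configuration and the four-stage pipeline.

Tilt series are stored as 32-bit float TIFF stacks (one page per
illumination) with a JSON sidecar of the same basename carrying the
per-image tilt metadata, fluence, optics block and seed. YAML run
configs drive the ``simulate -> preprocess -> reconstruct -> analyze``
pipeline; every stage seed derives from the global seed plus the stage
name, and a ``manifest.json`` with config/input hashes makes runs
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import analysis, forward, preprocess, reconstruct
from .forward import DetectorModel, TiltProtocol, TiltSeries, make_phantom
from .optics import FrequencyGrid, OpticalSystem, Tilt

logger = logging.getLogger("efp")


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# Optics config block


_OPTICS_KEYS = {
    "voltage_kv",
    "c1_nm",
    "c3_mm",
    "focal_spread_nm",
    "illum_semiangle_mrad",
    "aperture_kmax_invnm",
    "transfer_threshold",
}


def optics_from_config(block: dict) -> OpticalSystem:
    """Build an OpticalSystem from an ``optics`` config block."""
    unknown = set(block) - _OPTICS_KEYS
    if unknown:
        raise IOError_(f"unknown optics key(s): {sorted(unknown)}")
    return OpticalSystem(**block)


def optics_to_config(system: OpticalSystem) -> dict:
    return {
        "voltage_kv": system.voltage_kv,
        "c1_nm": system.c1_nm,
        "c3_mm": system.c3_mm,
        "focal_spread_nm": system.focal_spread_nm,
        "illum_semiangle_mrad": system.illum_semiangle_mrad,
        "aperture_kmax_invnm": system.aperture_kmax_invnm,
        "transfer_threshold": system.transfer_threshold,
    }


# ---------------------------------------------------------------------------
# Tilt-series container I/O


def write_tilt_series(series: TiltSeries, path: str | Path) -> Path:
    """Write a float32 TIFF stack plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, series.images.astype(np.float32), photometric="minisblack")
    sidecar = {
        "pixel_size_nm": series.pixel_size,
        "fluence_per_image": series.fluence_per_image,
        "tilts": [
            {"magnitude_mrad": t.magnitude_mrad, "azimuth_deg": t.azimuth_deg}
            for t in series.tilts
        ],
        "optics": optics_to_config(series.optics),
        "provenance": series.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_tilt_series(path: str | Path) -> TiltSeries:
    """Read a TIFF stack with its JSON sidecar back into a TiltSeries."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise IOError_(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    if len(meta["tilts"]) != images.shape[0]:
        raise IOError_(
            f"sidecar lists {len(meta['tilts'])} tilts for a "
            f"{images.shape[0]}-section stack"
        )
    pixel_size = float(meta["pixel_size_nm"])
    if pixel_size <= 0:
        raise IOError_("nonpositive pixel size in sidecar")
    tiff_px = _tiff_pixel_size(path)
    if tiff_px is not None and abs(tiff_px - pixel_size) > 1e-3 * pixel_size:
        logger.warning(
            "TIFF header pixel size %.6g nm differs from sidecar %.6g nm by >0.1%%",
            tiff_px,
            pixel_size,
        )
    tilts = [
        Tilt.from_mrad(t["magnitude_mrad"], t["azimuth_deg"]) for t in meta["tilts"]
    ]
    return TiltSeries(
        images=np.asarray(images, dtype=float),
        tilts=tilts,
        pixel_size=pixel_size,
        fluence_per_image=float(meta["fluence_per_image"]),
        optics=optics_from_config(meta["optics"]),
        provenance=meta.get("provenance", {}),
    )


def _tiff_pixel_size(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            res = tf.pages[0].tags.get("XResolution")
            if res is None:
                return None
            num, den = res.value
            return den / num if num else None
    except Exception:  # pragma: no cover - header quirks are nonfatal
        return None


def write_field(field2d: np.ndarray, path: str | Path) -> Path:
    """Write a single 2-D float field (e.g. ground-truth phase) as TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(field2d, dtype=np.float32), photometric="minisblack")
    return path


def read_field(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


# ---------------------------------------------------------------------------
# Run configuration


_KNOWN_BLOCKS = {"optics", "simulate", "preprocess", "reconstruct", "analyze",
                 "seed", "out_dir", "log_level"}
_SIMULATE_KEYS = {"phantom", "phantom_params", "shape", "pixel_size_nm",
                  "tilt_mrad", "n_azimuths", "include_axial", "total_fluence",
                  "mtf_sigma", "noiseless"}
_PREPROCESS_KEYS = {"c1_grid_nm", "patches", "reference_index", "skip_defocus"}
_RECONSTRUCT_KEYS = {"iterations", "step0", "decay_factor", "decay_every",
                     "upsample", "epsilon", "order"}
_ANALYZE_KEYS = {"redundancy_min_count", "threshold"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    optics: OpticalSystem
    simulate: dict
    preprocess: dict
    reconstruct: dict
    analyze: dict
    seed: int = 0
    out_dir: str = "efp_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_BLOCKS
        if unknown:
            raise IOError_(f"unknown config key(s): {sorted(unknown)}")
        for block, keys in (
            ("simulate", _SIMULATE_KEYS),
            ("preprocess", _PREPROCESS_KEYS),
            ("reconstruct", _RECONSTRUCT_KEYS),
            ("analyze", _ANALYZE_KEYS),
        ):
            bad = set(raw.get(block, {}) or {}) - keys
            if bad:
                raise IOError_(f"unknown {block} key(s): {sorted(bad)}")
        return cls(
            optics=optics_from_config(raw.get("optics", {}) or {}),
            simulate=dict(raw.get("simulate", {}) or {}),
            preprocess=dict(raw.get("preprocess", {}) or {}),
            reconstruct=dict(raw.get("reconstruct", {}) or {}),
            analyze=dict(raw.get("analyze", {}) or {}),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "efp_run")),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Pipeline


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run a contiguous subset of simulate/preprocess/reconstruct/analyze.

    Writes each stage's outputs under ``config.out_dir`` and a
    ``manifest.json`` with input hashes, the config hash and all seeds.
    Returns a dict of artifact paths. A stage failure raises with the
    stage name; outputs of completed stages are left on disk.
    """
    all_stages = ["simulate", "preprocess", "reconstruct", "analyze"]
    stages = stages or all_stages
    pos = [all_stages.index(s) for s in stages]
    if pos != sorted(pos) or pos != list(range(pos[0], pos[-1] + 1)):
        raise IOError_("stages must be a contiguous subset in pipeline order")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(
                {**asdict(config), "optics": optics_to_config(config.optics)},
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
        "stages": stages,
        "inputs": {},
    }

    series = None
    truth_phase = None
    estimate = None
    for stage in stages:
        try:
            if stage == "simulate":
                series, truth_phase = _stage_simulate(config, out, artifacts)
            elif stage == "preprocess":
                if series is None:
                    series = read_tilt_series(out / "series.tif")
                    manifest["inputs"]["series"] = _hash_file(out / "series.tif")
                series = _stage_preprocess(config, series, out, artifacts)
            elif stage == "reconstruct":
                if series is None:
                    src = out / "series_corr.tif"
                    if not src.exists():
                        src = out / "series.tif"
                    series = read_tilt_series(src)
                    manifest["inputs"]["series"] = _hash_file(src)
                estimate = _stage_reconstruct(config, series, out, artifacts)
            elif stage == "analyze":
                if estimate is None or series is None:
                    raise IOError_("analyze requires reconstruct outputs in memory")
                if truth_phase is None and (out / "phantom_phase.tif").exists():
                    truth_phase = read_field(out / "phantom_phase.tif")
                _stage_analyze(config, series, estimate, truth_phase, out, artifacts)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["artifacts"] = artifacts
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


def _stage_simulate(config: RunConfig, out: Path, artifacts: dict):
    sim = config.simulate
    seed = stage_seed(config.seed, "simulate")
    phantom = make_phantom(
        sim.get("phantom", "ice"),
        tuple(sim.get("shape", (256, 256))),
        sim.get("pixel_size_nm", 0.05),
        sim.get("phantom_params", {}),
        seed=seed,
    )
    protocol = TiltProtocol(
        tilt_mrad=sim.get("tilt_mrad", 5.0),
        n_azimuths=sim.get("n_azimuths", 4),
        include_axial=sim.get("include_axial", False),
    )
    detector = DetectorModel(mtf_sigma=sim.get("mtf_sigma", 0.35), seed=seed)
    series = forward.simulate_tilt_series(
        phantom,
        protocol,
        config.optics,
        detector,
        total_fluence=sim.get("total_fluence", 1e3),
        noiseless=sim.get("noiseless", False),
    )
    artifacts["series"] = str(write_tilt_series(series, out / "series.tif"))
    artifacts["phantom_phase"] = str(
        write_field(phantom.total_phase(), out / "phantom_phase.tif")
    )
    return series, phantom.total_phase()


def _stage_preprocess(config: RunConfig, series: TiltSeries, out: Path, artifacts: dict):
    pp = config.preprocess
    report: dict = {}
    if not pp.get("skip_defocus", False) and pp.get("c1_grid_nm") is not None:
        est = preprocess.estimate_defocus(
            series.images[0],
            series.pixel_size,
            series.optics,
            pp["c1_grid_nm"],
            patches=tuple(pp["patches"]) if pp.get("patches") else None,
        )
        report["c1_estimate_nm"] = est.c1_nm
        report["c1_se_nm"] = est.se_nm
        report["sign_ambiguous"] = est.sign_ambiguous
    shifts = preprocess.register_images(
        series.images, reference_index=pp.get("reference_index", 0)
    )
    corrected, shift_report = preprocess.compensate_tilt_shift(
        series.images,
        shifts,
        series.optics,
        series.tilts,
        series.pixel_size,
        reference_index=pp.get("reference_index", 0),
    )
    series = TiltSeries(
        images=np.clip(corrected, 0.0, None),
        tilts=series.tilts,
        pixel_size=series.pixel_size,
        fluence_per_image=series.fluence_per_image,
        optics=series.optics,
        provenance={**series.provenance, "preprocessed": True},
    )
    report["measured_shift_px"] = shift_report.measured_shift_px.tolist()
    report["predicted_shift_px"] = shift_report.predicted_shift_px.tolist()
    report["applied_shift_px"] = shift_report.applied_shift_px.tolist()
    artifacts["series_corr"] = str(write_tilt_series(series, out / "series_corr.tif"))
    (out / "preprocess_report.json").write_text(json.dumps(report, indent=2))
    artifacts["preprocess_report"] = str(out / "preprocess_report.json")
    return series


def _stage_reconstruct(config: RunConfig, series: TiltSeries, out: Path, artifacts: dict):
    rc = config.reconstruct
    recon_config = reconstruct.ReconConfig(
        iterations=rc.get("iterations", 50),
        step0=rc.get("step0", 0.1),
        decay_factor=rc.get("decay_factor", 0.5),
        decay_every=rc.get("decay_every", 10),
        upsample=rc.get("upsample", 2),
        epsilon=rc.get("epsilon", 1e-3),
        order=rc.get("order", "fixed"),
        shuffle_seed=stage_seed(config.seed, "reconstruct"),
    )
    estimate = reconstruct.pie_reconstruct(series, config.optics, recon_config)
    wave = estimate.exit_wave()
    tifffile.imwrite(
        out / "exitwave.tif",
        np.stack([np.angle(wave), np.abs(wave)]).astype(np.float32),
        photometric="minisblack",
    )
    artifacts["exitwave"] = str(out / "exitwave.tif")
    (out / "recon_report.json").write_text(
        json.dumps(
            {
                "config": {k: getattr(recon_config, k) for k in (
                    "iterations", "step0", "decay_factor", "decay_every",
                    "upsample", "epsilon", "order", "shuffle_seed")},
                "data_error": estimate.history,
            },
            indent=2,
        )
    )
    artifacts["recon_report"] = str(out / "recon_report.json")
    return estimate


def _stage_analyze(config, series, estimate, truth_phase, out: Path, artifacts: dict):
    an = config.analyze
    canvas_grid = estimate.grid
    redmap = analysis.redundancy_map(
        config.optics, series.tilts, canvas_grid, threshold=an.get("threshold")
    )
    min_count = an.get("redundancy_min_count", 2)
    best, worst = redmap.aperture_limits(min_count)
    report = {
        "aperture_limit_best_nm": best,
        "aperture_limit_worst_nm": worst,
        "redundancy_min_count": min_count,
    }
    phase = estimate.phase()
    if truth_phase is not None:
        truth_up = _upsample_field(truth_phase, estimate.upsample)
        mask = redmap.mask(min_count)
        report["psnr_db"] = analysis.psnr(
            _bandlimit(phase, mask), _bandlimit(truth_up, mask)
        )
    power = np.abs(np.fft.fft2(phase)) ** 2
    prof = analysis.circular_average(power, canvas_grid)
    csv = "k_invnm,value,count\n" + "\n".join(
        f"{k:.6g},{v:.6g},{c}" for k, v, c in zip(prof.k, prof.value, prof.count)
    )
    (out / "radial_profile.csv").write_text(csv)
    artifacts["radial_profile"] = str(out / "radial_profile.csv")
    tifffile.imwrite(out / "redundancy.tif", redmap.counts.astype(np.float32), photometric="minisblack")
    artifacts["redundancy_map"] = str(out / "redundancy.tif")
    try:
        from matplotlib import image as mpl_image

        mpl_image.imsave(
            out / "redundancy.png",
            np.fft.fftshift(redmap.counts),
            cmap="viridis",
        )
        artifacts["redundancy_png"] = str(out / "redundancy.png")
    except Exception:  # pragma: no cover - display-only artifact
        pass
    (out / "analysis_report.json").write_text(json.dumps(report, indent=2))
    artifacts["analysis_report"] = str(out / "analysis_report.json")
    return report


def _upsample_field(field2d: np.ndarray, factor: int) -> np.ndarray:
    """Fourier zero-padding interpolation onto the canvas grid."""
    if factor == 1:
        return np.asarray(field2d, dtype=float)
    ny, nx = field2d.shape
    spec = np.fft.fftshift(np.fft.fft2(field2d))
    cy, cx = factor * ny, factor * nx
    big = np.zeros((cy, cx), dtype=complex)
    y0, x0 = (cy - ny) // 2, (cx - nx) // 2
    big[y0 : y0 + ny, x0 : x0 + nx] = spec
    return np.fft.ifft2(np.fft.ifftshift(big)).real * factor**2


def _bandlimit(field2d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(field2d) * mask).real
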