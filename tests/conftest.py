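import numpy as np
import pytest

from efp import (
    DetectorModel,
    OpticalSystem,
    TiltProtocol,
    make_phantom,
    simulate_tilt_series,
)

# Optics of the two simulation protocols: a nearly aberration-corrected
# column for radiation-robust crystalline samples, and an uncorrected
# cryo column at large underfocus for beam-sensitive work.


@pytest.fixture(scope="session")
def gold_system():
    return OpticalSystem(
        voltage_kv=300.0,
        c1_nm=2.5,
        c3_mm=-1.9e-5,
        focal_spread_nm=4.3,
        illum_semiangle_mrad=0.02,
    )


@pytest.fixture(scope="session")
def cryo_system():
    return OpticalSystem(
        voltage_kv=300.0,
        c1_nm=-2000.0,
        c3_mm=2.7,
        focal_spread_nm=8.5,
        illum_semiangle_mrad=0.02,
    )


@pytest.fixture(scope="session")
def lattice_phantom():
    # crystalline test object: Gaussian bumps with 0.235 nm spacing
    return make_phantom(
        "lattice",
        (256, 256),
        0.013,
        {"spacing_nm": 0.235, "peak_phase": 0.05},
        seed=2,
    )


@pytest.fixture(scope="session")
def gold_series(gold_system, lattice_phantom):
    """Noiseless 1-axial + 6-tilt series at 10 mrad (robust-sample protocol)."""
    return simulate_tilt_series(
        lattice_phantom,
        TiltProtocol.robust(10.0),
        gold_system,
        DetectorModel(seed=0),
        total_fluence=4.6e5,
        noiseless=True,
    )


@pytest.fixture(scope="session")
def blob_series_small(gold_system):
    """Small noiseless blob series for fast forward-model checks."""
    phantom = make_phantom(
        "blobs",
        (128, 128),
        0.02,
        {"count": 8, "peak_phase": 0.05, "radius_range_nm": (0.2, 0.6)},
        seed=1,
    )
    series = simulate_tilt_series(
        phantom,
        TiltProtocol.robust(10.0),
        gold_system,
        DetectorModel(seed=0),
        total_fluence=4.6e5,
        noiseless=True,
    )
    return phantom, series


def upsampled(field2d: np.ndarray, factor: int) -> np.ndarray:
    """Fourier-interpolate a field onto the canvas grid (test helper)."""
    from efp.io import _upsample_field

    return _upsample_field(field2d, factor)


def bandlimited(field2d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    from efp.io import _bandlimit

    return _bandlimit(field2d, mask)
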