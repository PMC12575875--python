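import numpy as np
import pytest

from efp import (
    DetectorModel,
    FrequencyGrid,
    OpticalSystem,
    Tilt,
    TiltProtocol,
    apply_detector,
    axial_wtf,
    image_from_exit_wave,
    make_phantom,
    multislice_exit_wave,
    simulate_tilt_series,
)
from efp.forward import ForwardError, Phantom, snap_tilt_to_grid


class TestPhantoms:
    def test_ice_is_pure_phase_with_requested_rms(self):
        ph = make_phantom("ice", (128, 128), 0.1, {"rms_phase": 0.04}, seed=3)
        assert ph.amplitudes is None
        assert np.abs(ph.transmission(0)).max() == pytest.approx(1.0)
        assert ph.total_phase().std() == pytest.approx(0.04, rel=1e-6)
        assert ph.total_phase().mean() == pytest.approx(0.0, abs=1e-12)

    def test_lattice_spectrum_peaks_at_reciprocal_spacing(self):
        d = 0.235
        ph = make_phantom(
            "lattice", (256, 256), 0.013, {"spacing_nm": d, "peak_phase": 0.05}, seed=0
        )
        grid = FrequencyGrid((256, 256), 0.013)
        power = np.abs(np.fft.fft2(ph.total_phase())) ** 2
        power[0, 0] = 0.0
        kpeak = grid.kmag().ravel()[np.argmax(power)]
        assert kpeak == pytest.approx(1.0 / d, rel=0.05)

    def test_same_seed_bit_identical(self):
        a = make_phantom("blobs", (64, 64), 0.1, {"count": 5}, seed=11)
        b = make_phantom("blobs", (64, 64), 0.1, {"count": 5}, seed=11)
        assert np.array_equal(a.slices, b.slices)

    def test_unknown_kind_and_small_grid_rejected(self):
        with pytest.raises(ForwardError):
            make_phantom("gold_atoms", (128, 128), 0.1, {}, seed=0)
        with pytest.raises(ForwardError):
            make_phantom("ice", (32, 32), 0.1, {}, seed=0)

    def test_strong_phase_warns(self):
        with pytest.warns(UserWarning, match="pi/2"):
            make_phantom("lattice", (64, 64), 0.1, {"peak_phase": 2.0}, seed=0)


class TestExitWave:
    def test_empty_phantom_passes_tilted_plane_wave(self):
        ph = Phantom(kind="blobs", slices=np.zeros((128, 128)), pixel_size=0.05)
        sys_ = OpticalSystem(voltage_kv=300)
        tilt = Tilt.from_mrad(10.0, 40.0)
        psi = multislice_exit_wave(ph, tilt, sys_)
        assert np.allclose(np.abs(psi), 1.0)
        grid = FrequencyGrid((128, 128), 0.05)
        kt = snap_tilt_to_grid(tilt, grid, sys_.wavelength_nm)
        x, y = grid.coords()
        expected = np.exp(2j * np.pi * (kt[0] * x + kt[1] * y))
        assert np.allclose(psi, expected)

    def test_single_slice_zero_thickness_is_exact_product(self, gold_system):
        ph = make_phantom("blobs", (128, 128), 0.05, {"count": 6}, seed=5)
        tilt = Tilt.from_mrad(5.0, 10.0)
        psi = multislice_exit_wave(ph, tilt, gold_system)
        grid = FrequencyGrid((128, 128), 0.05)
        kt = snap_tilt_to_grid(tilt, grid, gold_system.wavelength_nm)
        x, y = grid.coords()
        expected = ph.transmission(0) * np.exp(2j * np.pi * (kt[0] * x + kt[1] * y))
        assert np.allclose(psi, expected)

    def test_phase_only_multislice_conserves_intensity(self, gold_system):
        slices = np.stack(
            [
                make_phantom("ice", (64, 64), 0.1, {"rms_phase": 0.1}, seed=s).slices[0]
                for s in range(4)
            ]
        )
        ph = Phantom(kind="ice", slices=slices, pixel_size=0.1, slice_thickness=5.0)
        psi = multislice_exit_wave(ph, Tilt.from_mrad(5.0), gold_system)
        total = np.sum(np.abs(psi) ** 2)
        assert total == pytest.approx(64 * 64, rel=1e-10)


class TestImaging:
    def test_identity_transfer_returns_intensity(self):
        sys_ = OpticalSystem(voltage_kv=300)  # no aberrations or envelopes: w = 1
        ph = make_phantom("blobs", (64, 64), 0.1, {"count": 4}, seed=2)
        psi = multislice_exit_wave(ph, Tilt(0.0), sys_)
        grid = FrequencyGrid((64, 64), 0.1)
        img = image_from_exit_wave(psi, grid, sys_)
        assert np.allclose(img, np.abs(psi) ** 2, atol=1e-12)

    def test_weak_phase_contrast_spectrum_is_2_sin_chi(self):
        # axial, no envelopes: F[I - 1](k) = 2 sin(chi) F[phi](k)
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=-300.0)
        ph = make_phantom(
            "ice", (256, 256), 0.05, {"rms_phase": 0.01, "band_invnm": (0.5, 6.0)},
            seed=7,
        )
        grid = FrequencyGrid((256, 256), 0.05)
        psi = multislice_exit_wave(ph, Tilt(0.0), sys_)
        img = image_from_exit_wave(psi, grid, sys_)
        contrast = np.fft.fft2(img - 1.0)
        from efp.optics import aberration_phase

        predicted = 2.0 * np.sin(aberration_phase(grid.kmag(), sys_)) * np.fft.fft2(
            ph.total_phase()
        )
        sel = np.abs(predicted) > 0.05 * np.abs(predicted).max()
        rel = np.abs(contrast[sel] - predicted[sel]) / np.abs(predicted[sel])
        assert np.median(rel) < 0.01

    def test_tilted_unscattered_peak_at_k_tau(self, gold_system):
        ph = make_phantom("blobs", (128, 128), 0.02, {"count": 6}, seed=3)
        tilt = Tilt.from_mrad(10.0, 60.0)
        psi = multislice_exit_wave(ph, tilt, gold_system)
        grid = FrequencyGrid((128, 128), 0.02)
        spec = np.abs(np.fft.fft2(psi))
        kt = snap_tilt_to_grid(tilt, grid, gold_system.wavelength_nm)
        iy = int(round(kt[1] * 128 * 0.02)) % 128
        ix = int(round(kt[0] * 128 * 0.02)) % 128
        assert np.unravel_index(spec.argmax(), spec.shape) == (iy, ix)

    def test_shifted_spectrum_oracle_identity(self, blob_series_small, gold_system):
        # forward image == |F^-1[O_hat(k - kt) w(k)]|^2 via an explicit roll
        phantom, series = blob_series_small
        grid = series.grid
        w = axial_wtf(grid, gold_system)
        o_hat = np.fft.fft2(phantom.transmission(0))
        for j, tilt in enumerate(series.tilts):
            kt = snap_tilt_to_grid(tilt, grid, gold_system.wavelength_nm)
            oy = int(round(kt[1] * grid.shape[0] * grid.pixel_size))
            ox = int(round(kt[0] * grid.shape[1] * grid.pixel_size))
            oracle = np.abs(np.fft.ifft2(np.roll(o_hat, (oy, ox), axis=(0, 1)) * w)) ** 2
            oracle /= oracle.mean()
            measured = series.images[j] / series.images[j].mean()
            rel_rms = np.sqrt(np.mean((measured - oracle) ** 2)) / np.sqrt(
                np.mean(oracle**2)
            )
            assert rel_rms < 1e-8


class TestDetector:
    def test_noiseless_mode_returns_scaled_expectation(self):
        img = np.full((64, 64), 1.0)
        img[10, 10] = 3.0
        out = apply_detector(img / img.mean(), 500.0, 0.1, DetectorModel(seed=0), noiseless=True)
        assert np.allclose(out, 500.0 * 0.01 * img / img.mean())

    def test_poisson_mean_and_variance(self):
        # constant image: ensemble mean ~ expected counts, variance ~ mean
        det = DetectorModel(mtf_sigma=None, seed=42)
        expected = 25.0  # fluence * px^2
        rng = np.random.default_rng(123)
        draws = np.stack(
            [
                apply_detector(np.ones((32, 32)), 2500.0, 0.1, det, rng=rng)
                for _ in range(100)
            ]
        )
        n = draws.size
        se_mean = np.sqrt(expected / n)
        assert abs(draws.mean() - expected) < 3 * se_mean
        assert abs(draws.var() - expected) < 3 * expected * np.sqrt(2.0 / n)

    def test_mtf_preserves_total_counts(self):
        det = DetectorModel(mtf_sigma=0.35, seed=1)
        rng = np.random.default_rng(5)
        img = rng.uniform(0.5, 1.5, (64, 64))
        img /= img.mean()
        out = apply_detector(img, 1000.0, 0.1, det, rng=np.random.default_rng(2))
        raw = apply_detector(
            img, 1000.0, 0.1, DetectorModel(mtf_sigma=None, seed=1),
            rng=np.random.default_rng(2),
        )
        assert out.sum() == pytest.approx(raw.sum(), rel=1e-10)

    def test_negative_input_rejected(self):
        with pytest.raises(ForwardError):
            apply_detector(np.full((8, 8), -1.0), 10.0, 0.1, DetectorModel())


class TestTiltSeriesSimulation:
    def test_robust_protocol_layout(self, gold_series):
        assert gold_series.n_images == 7
        mags = [t.magnitude_mrad for t in gold_series.tilts]
        assert mags[0] == 0.0
        assert np.allclose(mags[1:], 10.0)
        az = np.diff([t.azimuth_deg for t in gold_series.tilts[1:]])
        assert np.allclose(az, 60.0)

    def test_low_fluence_protocol_has_no_axial(self):
        ph = make_phantom("ice", (64, 64), 0.1, {}, seed=0)
        sys_ = OpticalSystem(voltage_kv=300)
        series = simulate_tilt_series(
            ph, TiltProtocol.low_fluence(5.0), sys_, DetectorModel(seed=0), 450.0
        )
        assert series.n_images == 4
        assert all(t.magnitude > 0 for t in series.tilts)

    def test_fluence_budget_conserved(self, gold_series):
        assert gold_series.fluence_per_image * gold_series.n_images == pytest.approx(
            4.6e5
        )

    def test_identical_seeds_bit_identical(self):
        ph = make_phantom("ice", (64, 64), 0.1, {}, seed=0)
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=-100.0)
        kw = dict(
            phantom=ph,
            protocol=TiltProtocol.low_fluence(5.0),
            system=sys_,
            detector=DetectorModel(seed=9),
            total_fluence=1e3,
        )
        a = simulate_tilt_series(**kw)
        b = simulate_tilt_series(**kw)
        assert np.array_equal(a.images, b.images)
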