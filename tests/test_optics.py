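import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efp import (
    FrequencyGrid,
    OpticalSystem,
    OpticsError,
    Tilt,
    aberration_phase,
    aberration_phase_gradient,
    axial_wtf,
    central_transfer_loss,
    effective_wtf,
    electron_wavelength,
    extended_resolution,
    optimal_tilt,
    tilt_defocus_offset,
    tilt_induced_shift,
)


class TestWavelength:
    @pytest.mark.parametrize(
        "kv,expected_nm",
        [(300.0, 1.9687e-3), (100.0, 3.7014e-3)],
    )
    def test_relativistic_values(self, kv, expected_nm):
        assert electron_wavelength(kv) == pytest.approx(expected_nm, rel=1e-4)

    @pytest.mark.parametrize("kv", [0.0, -5.0])
    def test_nonpositive_voltage_rejected(self, kv):
        with pytest.raises(OpticsError):
            electron_wavelength(kv)


class TestAberrationPhase:
    def test_zero_aberrations_give_zero_phase(self):
        sys_ = OpticalSystem(voltage_kv=300)
        k = np.linspace(0, 10, 50)
        assert np.allclose(aberration_phase(k, sys_), 0.0)

    def test_pure_defocus_value(self):
        # chi = pi lam C1 k^2 at C1 = 2.5 nm, |k| = 5 /nm, 300 kV
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=2.5)
        assert aberration_phase(5.0, sys_) == pytest.approx(0.3866, abs=2e-4)

    def test_overfocus_positive_phase(self):
        # overfocus-positive sign convention: C1 > 0 => chi > 0 at k > 0
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=100.0)
        assert aberration_phase(2.0, sys_) > 0

    def test_gradient_matches_numerical_derivative(self):
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=-2000.0, c3_mm=2.7)
        k = np.array([0.5, 2.0, 5.0])
        h = 1e-6
        num = (aberration_phase(k + h, sys_) - aberration_phase(k - h, sys_)) / (2 * h)
        assert np.allclose(aberration_phase_gradient(k, sys_), num, rtol=1e-6)


class TestEffectiveWTF:
    def test_zero_tilt_reduces_to_axial(self, cryo_system):
        grid = FrequencyGrid((64, 64), 0.2)
        w_eff = effective_wtf(grid, cryo_system, Tilt(0.0))
        assert np.allclose(w_eff, axial_wtf(grid, cryo_system))

    def test_temporal_envelope_peaks_on_achromatic_circle(self):
        # the defocus-spread damping vanishes where |q + kt| = |kt|
        sys_ = OpticalSystem(voltage_kv=300, focal_spread_nm=4.3)
        grid = FrequencyGrid((256, 256), 0.02)
        tilt = Tilt.from_mrad(15.0, 0.0)
        w = np.abs(effective_wtf(grid, sys_, tilt))
        kt = tilt.k_tau(sys_.wavelength_nm)
        ring = np.abs(np.hypot(grid.kx + kt[0], grid.ky + kt[1]) - np.hypot(*kt)) < min(
            grid.step
        )
        assert w[ring].min() > 0.995
        # while the passband centre q = -kt is measurably damped (~45%)
        centre = np.unravel_index(
            np.argmin(np.hypot(grid.kx + kt[0], grid.ky + kt[1])), grid.shape
        )
        assert w[centre] < 0.6

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        c1=st.floats(-2000, 2000),
        delta=st.floats(0, 10),
        tau_mrad=st.floats(0, 15),
        azimuth=st.floats(0, 2 * np.pi),
    )
    def test_magnitude_bounded_by_one(self, c1, delta, tau_mrad, azimuth):
        sys_ = OpticalSystem(
            voltage_kv=300,
            c1_nm=c1,
            c3_mm=2.7,
            focal_spread_nm=delta,
            illum_semiangle_mrad=0.02,
        )
        grid = FrequencyGrid((32, 32), 0.05)
        w = effective_wtf(grid, sys_, Tilt(tau_mrad * 1e-3, azimuth))
        assert np.abs(w).max() <= 1.0 + 1e-12


class TestCentralTransferLoss:
    @pytest.mark.parametrize(
        "tau_mrad,delta,expected",
        [(10.0, 4.3, 0.11), (15.0, 4.3, 0.45)],
    )
    def test_printed_loss_values(self, tau_mrad, delta, expected):
        sys_ = OpticalSystem(voltage_kv=300, focal_spread_nm=delta)
        assert central_transfer_loss(sys_, tau_mrad * 1e-3) == pytest.approx(
            expected, abs=0.02
        )

    def test_zero_for_zero_tilt_or_zero_spread(self):
        assert central_transfer_loss(
            OpticalSystem(voltage_kv=300, focal_spread_nm=4.3), 0.0
        ) == 0.0
        assert central_transfer_loss(
            OpticalSystem(voltage_kv=300, focal_spread_nm=0.0), 0.015
        ) == 0.0

    def test_strictly_increasing_in_tilt(self):
        sys_ = OpticalSystem(voltage_kv=300, focal_spread_nm=4.3)
        taus = np.linspace(1e-3, 20e-3, 30)
        losses = [central_transfer_loss(sys_, t) for t in taus]
        assert np.all(np.diff(losses) > 0)

    def test_matches_effective_wtf_at_passband_centre(self):
        # 1 - |w'| at the grid point nearest q = -kt, envelopes Et only
        sys_ = OpticalSystem(voltage_kv=300, focal_spread_nm=4.3)
        grid = FrequencyGrid((512, 512), 0.02)
        tilt = Tilt.from_mrad(10.0, np.deg2rad(30.0))
        w = np.abs(effective_wtf(grid, sys_, tilt, include_spatial=False))
        kt = tilt.k_tau(sys_.wavelength_nm)
        idx = np.unravel_index(
            np.argmin(np.hypot(grid.kx + kt[0], grid.ky + kt[1])), grid.shape
        )
        assert 1.0 - w[idx] == pytest.approx(
            central_transfer_loss(sys_, tilt.magnitude), abs=0.01
        )


class TestTiltRelations:
    def test_optimal_coupling_cryo_value(self):
        # sqrt(-C1/C3) for C1 = -2000 nm, C3 = 2.7 mm -> 27.2 mrad
        assert optimal_tilt(-2000.0, 2.7) * 1e3 == pytest.approx(27.2, abs=0.1)

    def test_optimal_tilt_edge_cases(self):
        assert optimal_tilt(0.0, 2.7) == 0.0
        with pytest.raises(OpticsError):
            optimal_tilt(2000.0, 2.7)
        with pytest.raises(OpticsError):
            optimal_tilt(-2000.0, 0.0)

    def test_defocus_offset_cryo_protocol(self):
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=-2000.0, c3_mm=2.7)
        dc1, rel = tilt_defocus_offset(sys_, 5e-3)
        assert dc1 == pytest.approx(135.0, rel=1e-6)
        assert rel == pytest.approx(0.068, abs=0.002)

    def test_defocus_offset_gold_experiment(self):
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=11.5, c3_mm=0.0015)
        dc1, _ = tilt_defocus_offset(sys_, 12.3e-3)
        assert dc1 == pytest.approx(0.454, abs=0.001)

    def test_defocus_offset_degenerate(self):
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=-2000.0, c3_mm=2.7)
        assert tilt_defocus_offset(sys_, 0.0) == (0.0, 0.0)
        with pytest.raises(OpticsError):
            tilt_defocus_offset(OpticalSystem(voltage_kv=300, c3_mm=2.7), 5e-3)

    @pytest.mark.parametrize(
        "c1,c3_mm,tau_mrad,expected_nm",
        [(-2000.0, 2.7, 1.9, 3.7815), (11.5, 0.0015, 12.3, 0.1443)],
    )
    def test_tilt_shift_magnitudes(self, c1, c3_mm, tau_mrad, expected_nm):
        sys_ = OpticalSystem(voltage_kv=300, c1_nm=c1, c3_mm=c3_mm)
        s = tilt_induced_shift(sys_, Tilt(tau_mrad * 1e-3, 0.7))
        assert np.hypot(*s) == pytest.approx(abs(expected_nm), abs=2e-3)

    def test_tilt_shift_zero_for_axial(self, cryo_system):
        assert np.allclose(tilt_induced_shift(cryo_system, Tilt(0.0)), 0.0)

    def test_tilt_shift_matches_phase_gradient(self, cryo_system):
        # |s| = |grad chi(kt)| / 2 pi by numerical differentiation
        tilt = Tilt.from_mrad(5.0, 123.0)
        kt_mag = tilt.magnitude / cryo_system.wavelength_nm
        h = 1e-6
        num = (
            aberration_phase(kt_mag + h, cryo_system)
            - aberration_phase(kt_mag - h, cryo_system)
        ) / (2 * h)
        s = tilt_induced_shift(cryo_system, tilt)
        assert np.hypot(*s) == pytest.approx(abs(num) / (2 * np.pi), rel=1e-6)

    def test_resolution_extension_at_5mrad(self):
        # 0.20 nm axial limit -> ~0.13 nm with a 5 mrad tilt at 300 kV
        assert extended_resolution(0.20, 5e-3, 300.0) == pytest.approx(0.133, abs=0.003)


class TestTiltType:
    def test_k_tau_magnitude_consistency(self):
        tilt = Tilt.from_mrad(12.3, 45.0)
        lam = electron_wavelength(300.0)
        assert np.hypot(*tilt.k_tau(lam)) == pytest.approx(
            tilt.magnitude / lam, rel=1e-12
        )

    def test_negative_magnitude_rejected(self):
        with pytest.raises(OpticsError):
            Tilt(-1e-3)


class TestFrequencyGrid:
    def test_nyquist_and_step(self):
        grid = FrequencyGrid((128, 64), 0.05)
        assert grid.nyquist == pytest.approx(10.0)
        d_ky, d_kx = grid.step
        assert d_ky == pytest.approx(1.0 / (128 * 0.05))
        assert d_kx == pytest.approx(1.0 / (64 * 0.05))
        assert grid.kx[0, 0] == 0.0 and grid.ky[0, 0] == 0.0
        assert grid.kx.max() == pytest.approx(grid.nyquist - d_kx)
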