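"""Spherical-resonator theory and the radial ringdown solver."""

import numpy as np
import pytest

import ionomark as im
from ionomark.analysis import resonance_amplitude, spectrum
from ionomark.materials import GOLD, WATER
from ionomark.proton_dose import marker_deposition_profile
from ionomark.wave_radial import radial_eigenmode


class TestResonanceFrequency:
    @pytest.mark.parametrize(
        "diameter_mm, n, expected_mhz",
        [(2.0, 1, 1.62), (2.0, 2, 3.24), (1.0, 1, 3.24)],
    )
    def test_eigenfrequencies(self, diameter_mm, n, expected_mhz):
        f = im.resonance_frequency(GOLD.v, diameter_mm * 1e-3, n)
        assert f == pytest.approx(expected_mhz * 1e6, rel=1e-6)

    def test_invalid_mode_index(self):
        with pytest.raises(ValueError):
            im.resonance_frequency(GOLD.v, 2e-3, 0)


class TestAmplitudeFactor:
    def test_zero_width_pulse(self):
        assert im.amplitude_factor(0.0, 1.62e6) == 1.0

    def test_200_over_100ns_ratio(self):
        ratio = im.amplitude_factor(200e-9, 1.62e6, reference_sigma=100e-9)
        assert ratio == pytest.approx(0.211, abs=0.002)

    def test_strictly_decreasing(self):
        s = np.linspace(0, 500e-9, 100)
        a = im.amplitude_factor(s, 1.62e6)
        assert np.all(np.diff(a) < 0)


class TestRadialEigenmode:
    def test_center_limit(self):
        assert radial_eigenmode(0.0) == 1.0

    def test_first_zero_at_pi(self):
        assert radial_eigenmode(np.pi) == pytest.approx(0.0, abs=1e-12)

    def test_satisfies_radial_helmholtz(self):
        # p'' + (2/r')p' + p = 0 for the zero-order spherical Bessel profile
        rp = np.linspace(0.05, 10.0, 2000)
        h = rp[1] - rp[0]
        p = radial_eigenmode(rp)
        d1 = np.gradient(p, h)
        d2 = np.gradient(d1, h)
        residual = d2[5:-5] + 2.0 / rp[5:-5] * d1[5:-5] + p[5:-5]
        assert np.max(np.abs(residual)) < 1e-4  # limited by FD differentiation


class TestRingdown:
    def test_spectral_peak_at_fundamental(self, ring_uniform):
        spec = spectrum(ring_uniform, t_start=12e-6)
        peak = resonance_amplitude(spec, 1.62e6)
        assert peak.detected
        assert peak.frequency == pytest.approx(1.62e6, rel=0.02)

    def test_linear_in_deposited_energy(self, marker22, ring_uniform):
        tr2 = im.ringdown(marker22, 2.0, 100e-9, r_detector_m=20.6e-3,
                          duration_s=30e-6, record_dt_s=5e-9)
        # atol floors out denormal leading-edge samples (~1e-309)
        np.testing.assert_allclose(
            tr2.pressure, 2.0 * ring_uniform.pressure, rtol=1e-9, atol=1e-30
        )

    def test_far_field_one_over_r_decay(self, marker22):
        tr = im.ringdown(marker22, 1.0, 100e-9,
                         r_detector_m=np.array([12e-3, 20e-3]),
                         duration_s=30e-6, record_dt_s=5e-9)
        ratio = np.abs(tr.pressure[0]).max() / np.abs(tr.pressure[1]).max()
        assert ratio == pytest.approx(20.0 / 12.0, rel=0.02)

    def test_impedance_mismatch_traps_the_wave(self, marker22):
        # broadband release recorded just inside and just outside the
        # interface: the internal peak stays at the initial pressure p0
        # while only ~T/2 of it appears in the water (the initial release
        # splits into two characteristics; the outward-travelling half,
        # amplitude p0/2, is transmitted with coefficient T ≈ 0.047)
        tr = im.ringdown(marker22, 1.0, 0.0,
                         r_detector_m=np.array([0.9e-3, 1.1e-3]),
                         duration_s=3e-6, record_dt_s=2e-9)
        from ionomark.source import MEV_TO_J
        p0 = GOLD.gamma * 1.0 * MEV_TO_J / (4 / 3 * np.pi * (1e-3) ** 3) * 1e3
        p_in = np.abs(tr.pressure[0]).max()
        p_out = np.abs(tr.pressure[1]).max()
        t_coef = im.pressure_transmission(GOLD.z_acoustic, WATER.z_acoustic)
        assert p_in / p0 == pytest.approx(1.0, abs=0.35)
        assert p_out / p_in == pytest.approx(t_coef / 2.0, rel=0.4)
        # the headline statement: only a few percent escapes
        assert p_out / p_in < 0.06

    def test_ringdown_quality_factor_finite(self, ring_uniform):
        # the resonance must decay (reflectance < 1): late-window energy
        # strictly below the early post-arrival window
        p = ring_uniform.pressure[0]
        t = ring_uniform.times
        early = np.sum(p[(t > 14e-6) & (t < 20e-6)] ** 2)
        late = np.sum(p[(t > 24e-6) & (t < 30e-6)] ** 2)
        assert 0.0 < late < early

    def test_onset_kinematics(self, ring_uniform, marker22):
        # arrival at (detector radius - marker radius)/v_water
        p = ring_uniform.pressure[0]
        i = np.nonzero(np.abs(p) >= 0.05 * np.abs(p).max())[0][0]
        expected = (20.6e-3 - 1e-3) / WATER.v
        assert ring_uniform.times[i] == pytest.approx(expected, abs=0.5e-6)

    def test_grid_refinement_converges(self, marker22):
        freqs = []
        for dr in (10e-6, 5e-6):
            tr = im.ringdown(marker22, 1.0, 100e-9, r_detector_m=15e-3,
                             duration_s=20e-6, dr_m=dr, record_dt_s=5e-9)
            peak = resonance_amplitude(spectrum(tr, t_start=10e-6), 1.62e6)
            freqs.append(peak.frequency)
        assert abs(freqs[1] - freqs[0]) / freqs[1] < 0.01

    def test_local_source_profile_accepted(self, beam60, marker22):
        prof = marker_deposition_profile(beam60, marker22, r_res_mm=5.0)
        tr = im.ringdown(marker22, prof[1].sum(), 100e-9, r_detector_m=15e-3,
                         duration_s=20e-6, record_dt_s=5e-9, source_profile=prof)
        peak = resonance_amplitude(spectrum(tr, t_start=9e-6), 1.62e6)
        assert peak.detected
        assert peak.frequency == pytest.approx(1.62e6, rel=0.02)

    def test_coarse_grid_rejected(self, marker22):
        with pytest.raises(ValueError, match="dr"):
            im.ringdown(marker22, 1.0, 100e-9, dr_m=50e-6, duration_s=5e-6)

    def test_detector_outside_domain_rejected(self, marker22):
        with pytest.raises(ValueError, match="detector"):
            im.ringdown(marker22, 1.0, 100e-9, r_detector_m=30e-3,
                        duration_s=5e-6)
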