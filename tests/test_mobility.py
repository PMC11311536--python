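import math

import numpy as np
import pytest

from driftchem import (
    DriftSpectrum,
    InstrumentConfig,
    ccs_from_drift,
    drift_from_ccs,
    pick_peaks,
    read_spectrum,
    write_spectrum,
)


def hand_mason_schamp_drift(ccs_A2, inst, ion_mass_u, z):
    """Independent hand calculation of the Mason–Schamp chain, written
    directly in SI from CODATA constants (no shared code with mobility)."""
    e = 1.602176634e-19
    kb = 1.380649e-23
    u = 1.66053906660e-27
    n0 = 2.686781e25
    mu = ion_mass_u * inst.gas_mass / (ion_mass_u + inst.gas_mass) * u
    omega = ccs_A2 * 1e-20
    k0 = (3 * z * e / (16 * n0)) * math.sqrt(
        2 * math.pi / (mu * kb * inst.temperature)
    ) / omega  # m²/(V s)
    k = k0 / ((inst.pressure / 760.0) * (273.15 / inst.temperature)) * 1e4
    t_s = inst.drift_length**2 / (inst.drift_voltage * k)
    return t_s * 1e3  # ms


class TestMasonSchamp:
    def test_round_trip_identity(self, instrument):
        for ccs in (120.0, 175.3, 310.0):
            td = drift_from_ccs(ccs, instrument, 320.18, 1)
            back = ccs_from_drift(td, instrument, 320.18, 1)
            assert abs(back - ccs) / ccs < 1e-10

    def test_doubling_charge_halves_drift_time(self, instrument):
        t1 = drift_from_ccs(175.3, instrument, 320.18, 1)
        t2 = drift_from_ccs(175.3, instrument, 320.18, 2)
        assert t1 / t2 == pytest.approx(2.0, rel=1e-12)

    def test_against_independent_hand_calculation(self):
        inst = InstrumentConfig(pressure=3.94, temperature=300.0)
        expected = hand_mason_schamp_drift(175.3, inst, 320.18, 1)
        got = drift_from_ccs(175.3, inst, 320.18, 1)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_ccs_linear_in_drift_time(self, instrument):
        td = np.linspace(5.0, 50.0, 10)
        ccs = np.array([ccs_from_drift(t, instrument, 250.0, 1) for t in td])
        slope = ccs / td
        assert np.allclose(slope, slope[0], rtol=1e-12)

    def test_invalid_inputs(self, instrument):
        with pytest.raises(ValueError):
            ccs_from_drift(-1.0, instrument, 250.0, 1)
        with pytest.raises(ValueError):
            ccs_from_drift(10.0, instrument, 250.0, 0)
        with pytest.raises(ValueError):
            InstrumentConfig(pressure=50.0)


def _gaussian_spectrum(centers, amps, fwhm, instrument, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(1.0, 60.0, 0.02)
    y = np.zeros_like(t)
    sigma = fwhm / 2.3548
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0, noise_sd, t.size), 0, None)
    return DriftSpectrum(times=t, intensities=y, mz=320.18, charge_state=1,
                         instrument=instrument)


class TestPeakPicking:
    def test_single_planted_gaussian_centroid(self, instrument):
        sp = _gaussian_spectrum([25.0], [1000.0], 0.6, instrument)
        peaks = pick_peaks(sp)
        assert len(peaks) == 1
        assert abs(peaks[0].drift_time - 25.0) / 25.0 < 0.005
        assert peaks[0].ccs_exp == pytest.approx(
            ccs_from_drift(25.0, instrument, 320.18, 1), rel=0.005
        )

    def test_two_peaks_resolved_then_merged(self, instrument):
        fwhm = 0.6
        sp = _gaussian_spectrum([25.0, 25.0 + 3 * fwhm], [1000.0, 800.0],
                                fwhm, instrument)
        assert len(pick_peaks(sp, min_separation=0.2)) == 2
        sp2 = _gaussian_spectrum([25.0, 25.0 + 0.3 * fwhm], [1000.0, 800.0],
                                 fwhm, instrument)
        assert len(pick_peaks(sp2, min_separation=2 * fwhm)) == 1

    def test_noise_below_threshold_gives_empty_list(self, instrument):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 60.0, 0.02)
        y = np.abs(rng.normal(0, 1.0, t.size))
        sp = DriftSpectrum(times=t, intensities=y, mz=320.18, charge_state=1,
                           instrument=instrument)
        # relative threshold of 1 means nothing but the single global max
        # qualifies, and isolated noise maxima carry no Gaussian shape
        peaks = pick_peaks(sp, min_rel_intensity=1.01)
        assert peaks == []

    def test_flat_spectrum_is_empty_not_error(self, instrument):
        t = np.arange(1.0, 10.0, 0.02)
        sp = DriftSpectrum(times=t, intensities=np.zeros_like(t), mz=100.0,
                           charge_state=1, instrument=instrument)
        assert pick_peaks(sp) == []

    def test_centroid_bias_small_at_high_snr(self, instrument):
        """Centroid bias < 0.2% of drift time across 100 random spectra
        with SNR >= 10."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            c = rng.uniform(10.0, 50.0)
            amp = 1000.0
            snr = rng.uniform(10.0, 100.0)
            sp = _gaussian_spectrum([c], [amp], 0.02 * c, instrument,
                                    noise_sd=amp / snr,
                                    seed=int(rng.integers(2**31)))
            peaks = pick_peaks(sp)
            assert peaks, f"no peak found at {c:.2f} ms"
            nearest = min(peaks, key=lambda p: abs(p.drift_time - c))
            worst = max(worst, abs(nearest.drift_time - c) / c)
        assert worst < 0.002


class TestSpectrumIO:
    def test_round_trip(self, tmp_path, instrument):
        sp = _gaussian_spectrum([20.0], [500.0], 0.5, instrument)
        path = tmp_path / "spec.txt"
        write_spectrum(sp, path)
        back = read_spectrum(path)
        assert back.mz == pytest.approx(sp.mz)
        assert back.charge_state == sp.charge_state
        assert back.instrument.pressure == pytest.approx(instrument.pressure)
        assert np.allclose(back.times, sp.times, atol=1e-6)
        assert np.allclose(back.intensities, sp.intensities, atol=1e-6)
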