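import numpy as np
import pytest

from conftest import sine_recording
from organoid_ephys.cfc import (BandPair, band_phase_amplitude, comodulogram,
                                mi_surrogate_null, modulation_index)
from organoid_ephys.pipeline import _lfp_spec_from_dict
from organoid_ephys.studies import _pac_spec
from organoid_ephys.synth import gen_lfp


def oracle_mi(phase, amp, n_bins=18):
    """Direct-binning oracle: explicit per-bin masks and loop."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for j in range(n_bins):
        mask = (phase >= edges[j]) & (phase < edges[j + 1])
        if j == n_bins - 1:
            mask |= phase == np.pi
        if mask.any():
            means.append(amp[mask].mean())
    means = np.array(means)
    p = means / means.sum()
    kl = sum(pj * np.log(pj * len(means)) for pj in p if pj > 0)
    return kl / np.log(n_bins)


def pac_recording(depth, seed):
    return gen_lfp(_lfp_spec_from_dict({**_pac_spec(depth), "seed": seed}))[0]


class TestBandPhaseAmplitude:
    def test_sine_envelope_is_flat_at_amplitude(self):
        rec = sine_recording(10, 1000.0, 30, amplitude=0.7)
        env = band_phase_amplitude(rec, (8, 12), "amplitude")
        interior = env[5000:-5000]
        assert np.allclose(interior, 0.7, rtol=0.02)
        assert np.all(env >= 0)

    def test_sine_phase_advances_at_carrier_frequency(self):
        fs, f = 1000.0, 10.0
        rec = sine_recording(f, fs, 30)
        ph = np.unwrap(band_phase_amplitude(rec, (8, 12), "phase"))
        interior = ph[5000:-5000]
        slope = np.polyfit(np.arange(interior.size) / fs, interior, 1)[0]
        assert np.isclose(slope, 2 * np.pi * f, rtol=0.005)

    def test_band_too_narrow_rejected(self):
        rec = sine_recording(10, 10000.0, 2)
        with pytest.raises(ValueError, match="minimum width"):
            band_phase_amplitude(rec, (10.0, 10.1), "phase")

    def test_bad_mode_rejected(self):
        rec = sine_recording(10, 1000.0, 2)
        with pytest.raises(ValueError, match="mode"):
            band_phase_amplitude(rec, (8, 12), "envelope")


class TestModulationIndex:
    def test_point_mass_reaches_one(self):
        n_bins = 18
        phase = np.linspace(-np.pi, np.pi, 18000, endpoint=False)
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        amp = np.where((phase >= edges[4]) & (phase < edges[5]), 2.5, 0.0)
        assert modulation_index(phase, amp, n_bins) == pytest.approx(1.0)

    def test_matches_direct_binning_oracle(self):
        rec = pac_recording(0.8, seed=11)
        ph = band_phase_amplitude(rec, (1, 4), "phase")[2000:-2000]
        am = band_phase_amplitude(rec, (150, 250), "amplitude")[2000:-2000]
        assert modulation_index(ph, am) == pytest.approx(oracle_mi(ph, am),
                                                         abs=1e-10)

    def test_shuffled_amplitude_below_surrogate_tail(self, rng):
        rec = pac_recording(0.8, seed=3)
        ph = band_phase_amplitude(rec, (1, 4), "phase")[2000:-2000]
        am = band_phase_amplitude(rec, (150, 250), "amplitude")[2000:-2000]
        am_shuffled = rng.permutation(am)
        null = mi_surrogate_null(ph, am_shuffled, rec.fs, n_surrogates=100, seed=0)
        assert null.mi_obs < np.quantile(null.null_values, 0.99)

    def test_invariances(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 20000)
        am = rng.gamma(2.0, 1.0, 20000)
        base = modulation_index(ph, am)
        assert modulation_index(ph, 7.3 * am) == pytest.approx(base, rel=1e-12)
        k = 4321
        rolled = modulation_index(np.roll(ph, k), np.roll(am, k))
        assert rolled == pytest.approx(base, rel=1e-12)

    def test_depth_increases_mi(self):
        mis = [np.mean([
            modulation_index(
                band_phase_amplitude(pac_recording(d, seed=50 + s), (1, 4),
                                     "phase")[2000:-2000],
                band_phase_amplitude(pac_recording(d, seed=50 + s), (150, 250),
                                     "amplitude")[2000:-2000])
            for s in range(3)])
            for d in (0.0, 0.5, 1.0)]
        assert mis[0] < mis[1] < mis[2]

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            modulation_index(np.linspace(-3, 3, 100), np.zeros(100))

    def test_empty_bin_warns_and_stays_bounded(self):
        phase = np.full(1000, 0.1)  # single occupied bin
        amp = np.abs(np.random.default_rng(0).standard_normal(1000))
        with pytest.warns(UserWarning, match="empty phase bins"):
            mi = modulation_index(phase, amp)
        assert mi == 0.0  # one occupied bin carries no coupling information


class TestSurrogates:
    def test_coupled_signal_strongly_significant(self):
        rec = pac_recording(1.0, seed=5)
        ph = band_phase_amplitude(rec, (1, 4), "phase")[2000:-2000]
        am = band_phase_amplitude(rec, (150, 250), "amplitude")[2000:-2000]
        null = mi_surrogate_null(ph, am, rec.fs, n_surrogates=100, seed=1)
        assert null.z > 5

    def test_deterministic_under_seed(self):
        rec = pac_recording(0.5, seed=6)
        ph = band_phase_amplitude(rec, (1, 4), "phase")[2000:-2000]
        am = band_phase_amplitude(rec, (150, 250), "amplitude")[2000:-2000]
        z1 = mi_surrogate_null(ph, am, rec.fs, n_surrogates=60, seed=9).z
        z2 = mi_surrogate_null(ph, am, rec.fs, n_surrogates=60, seed=9).z
        assert z1 == z2

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match="50"):
            mi_surrogate_null(np.zeros(5000), np.ones(5000), 1000.0,
                              n_surrogates=10)


class TestComodulogram:
    def test_localizes_injected_coupling(self):
        rec = pac_recording(0.8, seed=21)
        com = comodulogram(rec, n_surrogates=60, seed=0)
        i, j = np.unravel_index(np.argmax(com.z), com.z.shape)
        assert com.phase_bands[i][0] == "delta"
        assert com.amp_bands[j][0] == "HFO"
        assert com.mi.shape == (5, 3)
        assert np.all((com.mi >= 0) & (com.mi <= 1))

    def test_default_grid_includes_delta_and_hfo(self):
        rec = pac_recording(0.0, seed=2)
        com = comodulogram(rec, n_surrogates=0)
        assert "delta" in [b[0] for b in com.phase_bands]
        assert "HFO" in [b[0] for b in com.amp_bands]
        assert np.all(np.isnan(com.z))

    def test_invalid_pair_named_in_error(self):
        rec = sine_recording(5, 1000.0, 10)
        with pytest.raises(ValueError, match="below amplitude band"):
            comodulogram(rec, phase_bands=[("fast", 50.0, 90.0)],
                         amp_bands=[("slow", 20.0, 40.0)], n_surrogates=0)


class TestBandPair:
    def test_validation(self):
        BandPair((1, 4), (150, 250)).validate(1000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            BandPair((1, 4), (150, 600)).validate(1000.0)
        with pytest.raises(ValueError, match="below"):
            BandPair((10, 40), (30, 80)).validate(1000.0)
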