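import numpy as np
import pytest
from scipy import stats as sps

from organoid_ephys.synth import (BurstSpec, LfpSynthSpec, LineNoiseSpec,
                                  PacSpec, SpikeSynthSpec, derive_seed,
                                  gen_cell_attached, gen_group_dataset,
                                  gen_lfp, gen_spike_times, write_dataset)


class TestLfpGenerator:
    def test_deterministic_under_seed(self):
        spec = LfpSynthSpec(duration=10, fs=1000, noise_rms=0.05,
                            oscillations=((1, 4, 0.1),), seed=7)
        a, _ = gen_lfp(spec)
        b, _ = gen_lfp(spec)
        assert np.array_equal(a.samples, b.samples)

    def test_oscillation_variance_exact(self):
        spec = LfpSynthSpec(duration=120, fs=1000, noise_rms=0.0,
                            oscillations=((5, 15, 0.3),), seed=1)
        rec, truth = gen_lfp(spec)
        assert np.isclose(rec.samples.var(), 0.09, rtol=0.02)
        assert truth.band_variances["osc0:5-15Hz"] == pytest.approx(0.09)

    def test_one_over_f_slope(self):
        """Fitted log-log PSD slope over 1-100 Hz is -1 for alpha=1."""
        spec = LfpSynthSpec(duration=120, fs=1000, noise_exponent=1.0,
                            noise_rms=1.0, seed=3)
        rec, _ = gen_lfp(spec)
        f = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        p = np.abs(np.fft.rfft(rec.samples)) ** 2
        # bin the raw periodogram in log-spaced bands to stabilize the fit
        edges = np.logspace(0, 2, 25)
        centers, means = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (f >= lo) & (f < hi)
            if m.any():
                centers.append(np.sqrt(lo * hi))
                means.append(p[m].mean())
        slope = np.polyfit(np.log10(centers), np.log10(means), 1)[0]
        assert abs(slope - (-1.0)) <= 0.15

    def test_line_noise_peaks_only_at_harmonics(self):
        spec = LfpSynthSpec(duration=20, fs=1000, noise_rms=0.0,
                            line_noise=LineNoiseSpec(60, 5, 0.2), seed=2)
        rec, _ = gen_lfp(spec)
        f = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        p = np.abs(np.fft.rfft(rec.samples)) ** 2
        peak_freqs = f[p > 0.01 * p.max()]
        assert set(np.round(peak_freqs).astype(int)) <= {60, 120, 180, 240, 300}

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match=r"\(30, 600\)"):
            LfpSynthSpec(duration=1, fs=1000, oscillations=((30, 600, 0.1),))

    def test_pac_depth_recorded_and_modulation_present(self):
        spec = LfpSynthSpec(
            duration=30, fs=1000, noise_rms=0.0,
            pac=PacSpec((2, 3), (180, 220), depth=1.0, carrier_rms=0.1),
            seed=4)
        rec, truth = gen_lfp(spec)
        assert truth.pac_depth == 1.0
        # carrier rms is exact after modulation normalization
        assert np.isclose(rec.samples.std(), np.sqrt(0.1 ** 2 + 0.1 ** 2),
                          rtol=0.05)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            PacSpec((2, 3), (100, 200), depth=1.5, carrier_rms=0.1)


class TestSpikeGenerator:
    def test_poisson_count_in_expected_range(self):
        spec = SpikeSynthSpec(duration=240, fs=10000, rate=2.0, seed=9)
        times = gen_spike_times(spec)
        assert abs(times.size - 480) <= 4 * np.sqrt(480)

    def test_zero_rate_pure_noise(self):
        spec = SpikeSynthSpec(duration=5, fs=10000, rate=0.0, noise_sd=0.1,
                              seed=1)
        rec, truth = gen_cell_attached(spec)
        assert truth.spike_times.size == 0
        assert np.isclose(rec.samples.std(), 0.1, rtol=0.05)

    def test_refractory_respected(self):
        spec = SpikeSynthSpec(duration=60, fs=10000, rate=50.0,
                              refractory=0.005, seed=2)
        times = gen_spike_times(spec)
        assert np.all(np.diff(times) >= 0.005)

    def test_burst_isi_bimodal(self):
        """Burst trains reject a single-exponential ISI model (KS test)."""
        spec = SpikeSynthSpec(
            duration=600, fs=10000, burst=BurstSpec(0.2, 5, 0.02), seed=3)
        times = gen_spike_times(spec)
        isi = np.diff(times)
        ks = sps.kstest(isi, "expon", args=(0, isi.mean()))
        assert ks.pvalue < 1e-6
        # and a matched-rate Poisson train does not
        pois = gen_spike_times(SpikeSynthSpec(duration=600, fs=10000,
                                              rate=times.size / 600, seed=4))
        isi_p = np.diff(pois)
        assert sps.kstest(isi_p, "expon", args=(0, isi_p.mean())).pvalue > 1e-3

    def test_template_longer_than_trace_rejected(self):
        spec = SpikeSynthSpec(duration=0.001, fs=10000, rate=1.0)
        with pytest.raises(ValueError, match="template"):
            gen_cell_attached(spec)

    def test_deterministic_under_seed(self):
        spec = SpikeSynthSpec(duration=10, fs=10000, rate=3.0, seed=11)
        a, ta = gen_cell_attached(spec)
        b, tb = gen_cell_attached(spec)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(ta.spike_times, tb.spike_times)


class TestGroupDataset:
    def _specs(self):
        return {"WT": LfpSynthSpec(duration=2, fs=500, noise_rms=0.05),
                "KO": LfpSynthSpec(duration=2, fs=500, noise_rms=0.1)}

    def test_group_sizes_and_labels(self):
        records = gen_group_dataset(self._specs(), n_per_group=14,
                                    master_seed=1)
        assert len(records) == 28
        assert sum(r.group == "WT" for r in records) == 14
        assert records[0].recording.labels["genotype"] == "WT"

    def test_unequal_design(self):
        records = gen_group_dataset(self._specs(), {"WT": 3, "KO": 5},
                                    master_seed=1)
        assert sum(r.group == "WT" for r in records) == 3
        assert sum(r.group == "KO" for r in records) == 5

    def test_single_recording(self):
        records = gen_group_dataset(
            {"only": LfpSynthSpec(duration=1, fs=500)}, 1, 0)
        assert len(records) == 1 and records[0].rec_id == "only_000"

    def test_reproducible_and_independent(self):
        a = gen_group_dataset(self._specs(), 2, master_seed=5)
        b = gen_group_dataset(self._specs(), 2, master_seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.recording.samples, rb.recording.samples)
        # different recordings differ
        assert not np.array_equal(a[0].recording.samples,
                                  a[1].recording.samples)

    def test_seed_derivation_stable(self):
        assert derive_seed(1, "WT", 0) == derive_seed(1, "WT", 0)
        assert derive_seed(1, "WT", 0) != derive_seed(1, "WT", 1)
        assert derive_seed(1, "WT", 0) < 2 ** 31

    def test_empty_spec_map_rejected(self):
        with pytest.raises(ValueError, match="at least one group"):
            gen_group_dataset({}, 3, 0)

    def test_write_dataset_manifest(self, tmp_path):
        records = gen_group_dataset(self._specs(), 2, 0)
        manifest = write_dataset(records, tmp_path)
        import pandas as pd

        df = pd.read_csv(manifest)
        assert len(df) == 4
        assert set(df.columns) >= {"rec_id", "group", "file", "truth_file"}
        from organoid_ephys.io import read_recording

        back = read_recording(tmp_path / df["file"].iloc[0])
        assert np.array_equal(back.samples, records[0].recording.samples)
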