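"""Canonical synthetic study conditions and validation experiments.

This module freezes the synthetic designs used to validate the pipeline —
group sizes and effect structure mirror the slice/cell experiments the
analysis was built for (n = 14 slices per genotype for LFP band power with
a 3x slow-wave power elevation; 24/41/40 cells with one group's firing
rate 4x the others) — and provides functions that run each validation
end-to-end and return scalar metrics.

Traces for the Monte-Carlo experiments are synthesized at 1 kHz for
60-120 s: the band structure under study lives below 250 Hz, so a 1 kHz
grid keeps every analysis band and all five notch harmonics below Nyquist
while keeping hundreds of replicate pipeline runs cheap.  The filter
contract is checked at the full 25 kHz acquisition rate.

Every function takes a ``seed`` and derives all randomness from it.
"""

from __future__ import annotations

import numpy as np

from .cfc import band_phase_amplitude, mi_surrogate_null, modulation_index
from .io import Recording
from .pipeline import PipelineConfig, run_bandpower_pipeline, run_cfc_pipeline, run_spike_pipeline
from .preprocess import FilterSpec, apply_notch
from .spectral import SWO_BAND, band_auc, compute_psd, normalize_psd
from .spikes import detect_spikes, spike_bandpass
from .synth import LfpSynthSpec, SpikeSynthSpec, gen_cell_attached, gen_lfp, gen_spike_times

__all__ = [
    "lfp_control_spec",
    "lfp_hyperexcitable_spec",
    "notch_contract",
    "parseval_ratios",
    "swo_recovery_errors",
    "group_power_rate",
    "null_rejection_rate",
    "mi_point_mass",
    "mi_depth_curve",
    "uncoupled_z_fraction",
    "cfc_localization_rate",
    "spike_detection_metrics",
    "false_positive_zero_fraction",
    "firing_rate_bias",
    "rate_design_success",
    "determinism_check",
]


# ---------------------------------------------------------------------------
# canonical study conditions
# ---------------------------------------------------------------------------

#: Monte-Carlo synthesis rate (Hz); see module docstring.
MC_FS = 1000.0
#: Monte-Carlo LFP trace length (s).
MC_DURATION = 60.0


def lfp_control_spec() -> dict:
    """Control-like LFP recipe: 1/f background, modest slow-wave band,
    mains contamination and slow drift (both removed by preprocessing)."""
    return dict(
        duration=MC_DURATION, fs=MC_FS, noise_exponent=1.0, noise_rms=0.05,
        oscillations=[[SWO_BAND[0], SWO_BAND[1], 0.05]],
        line_noise=dict(base=60.0, n_harmonics=5, amplitude=0.02),
        drift_rms=0.05,
    )


def lfp_hyperexcitable_spec(power_fold: float = 3.0) -> dict:
    """Knockout-like recipe: slow-wave band variance multiplied by
    ``power_fold`` (amplitude by its square root)."""
    spec = lfp_control_spec()
    spec["oscillations"] = [[SWO_BAND[0], SWO_BAND[1],
                             float(0.05 * np.sqrt(power_fold))]]
    return spec


def _pac_spec(depth: float) -> dict:
    """PAC recipe with the injection confined to the delta:HFO grid cell."""
    return dict(
        duration=MC_DURATION, fs=MC_FS, noise_exponent=1.0, noise_rms=0.05,
        pac=dict(phase_band=[2.0, 3.0], amp_band=[180.0, 220.0],
                 depth=depth, carrier_rms=0.05, slow_rms=0.1),
    )


def _cell_spec(rate: float, duration: float = 240.0, snr: float = 8.0) -> dict:
    return dict(duration=duration, fs=10000.0, rate=rate,
                amplitude=0.1 * snr, noise_sd=0.1)


# ---------------------------------------------------------------------------
# filter / spectral contracts
# ---------------------------------------------------------------------------


def notch_contract(fs: float = 25000.0, duration: float = 10.0) -> dict:
    """Measure notch attenuation and passband deviation with a DFT probe.

    Feeds pure sinusoids through the notch cascade and measures the gain at
    the probe frequency by direct DFT projection on the interior of the
    trace (edges excluded).  Returns the minimum attenuation over the five
    harmonics (dB, positive) and the maximum passband deviation (dB) at
    probes >= 2 Hz away from every notch.
    """
    spec = FilterSpec()
    t = np.arange(int(duration * fs)) / fs
    n0 = int(2.0 * fs)

    def gain_db(f: float) -> float:
        x = np.sin(2 * np.pi * f * t)
        y = apply_notch(Recording(x, fs), spec).samples
        probe = np.exp(-2j * np.pi * f * np.arange(x.size - 2 * n0) / fs)
        num = abs(np.vdot(probe, y[n0:-n0]))
        den = abs(np.vdot(probe, x[n0:-n0]))
        return 20.0 * np.log10(num / den)

    stop = [-gain_db(f) for f in spec.notch_frequencies()]
    passband_probes = [10.0, 30.0, 58.0, 62.0, 79.9, 100.0, 118.0, 122.0,
                       178.0, 182.0, 238.0, 242.0, 298.0, 302.0]
    dev = [abs(gain_db(f)) for f in passband_probes]
    return {"min_stopband_db": float(min(stop)),
            "max_passband_dev_db": float(max(dev))}


def parseval_ratios(seed: int, duration: float = 240.0, fs: float = MC_FS) -> dict:
    """Integral of the PSD over the trace variance, for white and
    band-limited noise (1.0 means exact energy conservation)."""
    rng = np.random.default_rng(seed)
    white = Recording(rng.standard_normal(int(duration * fs)), fs)
    psd_w = compute_psd(white)
    band_spec = LfpSynthSpec(duration=duration, fs=fs, noise_rms=0.0,
                             oscillations=((5.0, 15.0, 1.0),), seed=seed + 1)
    band_rec, _ = gen_lfp(band_spec)
    psd_b = compute_psd(band_rec)
    return {
        "white": float(psd_w.power.sum() * psd_w.df / white.samples.var()),
        "band": float(psd_b.power.sum() * psd_b.df / band_rec.samples.var()),
    }


def swo_recovery_errors(seed: int, fracs=(0.1, 0.3, 0.6),
                        n_seeds: int = 20) -> dict:
    """Recover known SWO:total variance fractions from the normalized PSD.

    Signals hold exactly two band-limited components (0.25-1 Hz and
    2-80 Hz) with variance ratio frac : 1-frac; returns the mean absolute
    error of the estimated SWO AUC fraction per target fraction.
    """
    errors = {}
    for frac in fracs:
        ests = []
        for i in range(n_seeds):
            spec = LfpSynthSpec(
                duration=120.0, fs=MC_FS, noise_rms=0.0,
                oscillations=(
                    (SWO_BAND[0], SWO_BAND[1], float(np.sqrt(frac))),
                    (2.0, 80.0, float(np.sqrt(1.0 - frac))),
                ),
                seed=seed + 1000 * int(frac * 10) + i,
            )
            rec, _ = gen_lfp(spec)
            psd = normalize_psd(compute_psd(rec))
            ests.append(band_auc(psd, *SWO_BAND).auc)
        errors[frac] = float(np.mean(np.abs(np.array(ests) - frac)))
    return errors


# ---------------------------------------------------------------------------
# group band-power experiments
# ---------------------------------------------------------------------------


def _bandpower_p(config: PipelineConfig) -> tuple[str, float]:
    report = run_bandpower_pipeline(config).reports["SWO"]
    return report.test_name, float(report.comparisons["p_adj"].iloc[0])


def group_power_rate(seed: int, n_reps: int = 100, power_fold: float = 3.0,
                     n_per_group: int = 14, p_cut: float = 0.01) -> float:
    """Fraction of replicate pipeline runs detecting the slow-wave power
    elevation at p < ``p_cut`` (control vs ``power_fold`` x SWO, n=14/group)."""
    hits = 0
    for rep in range(n_reps):
        config = PipelineConfig(
            synth_groups={"control": lfp_control_spec(),
                          "hyper": lfp_hyperexcitable_spec(power_fold)},
            n_per_group=n_per_group, seed=seed + rep,
        )
        _, p = _bandpower_p(config)
        hits += p < p_cut
    return hits / n_reps


def null_rejection_rate(seed: int, n_reps: int = 500,
                        n_per_group: int = 14, alpha: float = 0.05) -> float:
    """Type-I error of the band-power pipeline: identical specs in both
    groups, fraction of runs with p <= alpha."""
    hits = 0
    for rep in range(n_reps):
        config = PipelineConfig(
            synth_groups={"a": lfp_control_spec(), "b": lfp_control_spec()},
            n_per_group=n_per_group, seed=seed + rep,
        )
        _, p = _bandpower_p(config)
        hits += p <= alpha
    return hits / n_reps


# ---------------------------------------------------------------------------
# coupling experiments
# ---------------------------------------------------------------------------


def mi_point_mass(n_bins: int = 18, n: int = 18000) -> float:
    """MI of an envelope concentrated in a single phase bin (analytic: 1)."""
    phase = np.linspace(-np.pi, np.pi, n, endpoint=False)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    amp = np.where((phase >= edges[9]) & (phase < edges[10]), 1.0, 0.0)
    return modulation_index(phase, amp, n_bins)


def _pac_phase_amp(depth: float, seed: int) -> tuple[np.ndarray, np.ndarray, float]:
    from .pipeline import _lfp_spec_from_dict

    spec = _lfp_spec_from_dict({**_pac_spec(depth), "seed": seed})
    rec, _ = gen_lfp(spec)
    ph = band_phase_amplitude(rec, (1.0, 4.0), "phase")
    am = band_phase_amplitude(rec, (150.0, 250.0), "amplitude")
    k = int(2.0 / 1.0 * rec.fs)
    return ph[k:-k], am[k:-k], rec.fs


def mi_depth_curve(seed: int, depths=(0.0, 0.25, 0.5, 0.75, 1.0),
                   n_seeds: int = 20) -> dict:
    """Mean MI at the delta:HFO pair per generator coupling depth."""
    curve = {}
    for d in depths:
        vals = [modulation_index(*_pac_phase_amp(d, seed + 100 * i + int(d * 4))[:2])
                for i in range(n_seeds)]
        curve[d] = float(np.mean(vals))
    return curve


def uncoupled_z_fraction(seed: int, n_seeds: int = 20,
                         n_surrogates: int = 100) -> float:
    """Fraction of depth-0 recordings whose surrogate |z| < 3."""
    ok = 0
    for i in range(n_seeds):
        ph, am, fs = _pac_phase_amp(0.0, seed + i)
        null = mi_surrogate_null(ph, am, fs, n_surrogates=n_surrogates,
                                 seed=seed + i)
        ok += abs(null.z) < 3.0
    return ok / n_seeds


def cfc_localization_rate(seed: int, n_runs: int = 50, depth: float = 0.8,
                          n_per_group: int = 8) -> float:
    """Fraction of replicate CFC pipelines where the delta:HFO pair is both
    the largest group contrast and the only Holm-Sidak-significant pair."""
    ok = 0
    for rep in range(n_runs):
        config = PipelineConfig(
            synth_groups={"control": _pac_spec(0.0), "coupled": _pac_spec(depth)},
            n_per_group=n_per_group, seed=seed + rep, n_surrogates=60,
        )
        res = run_cfc_pipeline(config)
        sig = res.contrast[res.contrast["p_adj"] <= 0.05]
        best = res.contrast.loc[res.contrast["statistic"].abs().idxmax()]
        ok += (
            len(sig) == 1
            and sig.iloc[0]["phase_band"] == "delta"
            and sig.iloc[0]["amp_band"] == "HFO"
            and best["phase_band"] == "delta"
            and best["amp_band"] == "HFO"
        )
    return ok / n_runs


# ---------------------------------------------------------------------------
# spike experiments
# ---------------------------------------------------------------------------


def _match_spikes(detected: np.ndarray, truth: np.ndarray,
                  tol: float = 0.0015) -> int:
    """Count one-to-one matches between detected and true times within tol."""
    matched = 0
    used = np.zeros(detected.size, bool)
    for t in truth:
        j = np.searchsorted(detected, t)
        best = -1
        best_dt = tol
        for k in (j - 1, j, j + 1):
            if 0 <= k < detected.size and not used[k]:
                dt = abs(detected[k] - t)
                if dt <= best_dt:
                    best, best_dt = k, dt
        if best >= 0:
            used[best] = True
            matched += 1
    return matched


def spike_detection_metrics(seed: int, rate: float = 2.0, snr: float = 8.0,
                            n_seeds: int = 5) -> dict:
    """Recall and precision of the detection chain on 240 s, 10 kHz traces."""
    recalls, precisions = [], []
    for i in range(n_seeds):
        spec = SpikeSynthSpec(**{**_cell_spec(rate, snr=snr), "seed": seed + i})
        rec, truth = gen_cell_attached(spec)
        train = detect_spikes(spike_bandpass(rec))
        matched = _match_spikes(train.spike_times, truth.spike_times)
        recalls.append(matched / truth.spike_times.size)
        precisions.append(matched / train.n_spikes if train.n_spikes else 1.0)
    return {"recall": float(np.mean(recalls)),
            "precision": float(np.mean(precisions))}


def false_positive_zero_fraction(seed: int, n_seeds: int = 100) -> float:
    """Fraction of pure-noise traces (240 s, 10 kHz) with zero detections."""
    zero = 0
    for i in range(n_seeds):
        spec = SpikeSynthSpec(**{**_cell_spec(0.0), "seed": seed + i})
        rec, _ = gen_cell_attached(spec)
        train = detect_spikes(spike_bandpass(rec))
        zero += train.n_spikes == 0
    return zero / n_seeds


def firing_rate_bias(seed: int, rates=(0.5, 2.0, 10.0),
                     n_seeds: int = 200) -> dict:
    """Relative bias of the 4-min firing-rate estimator vs nominal rate."""
    bias = {}
    for lam in rates:
        ests = []
        for i in range(n_seeds):
            spec = SpikeSynthSpec(**{**_cell_spec(lam), "seed": seed + i})
            times = gen_spike_times(spec)
            ests.append(times.size / spec.duration)
        bias[lam] = float(abs(np.mean(ests) - lam) / lam)
    return bias


def rate_design_success(seed: int, n_reps: int = 100,
                        rates=(0.5, 2.0, 0.5),
                        ns=(24, 41, 40)) -> float:
    """Three-group firing-rate design (one group 4x elevated, unequal n).

    Success means Tukey flags the elevated group against both others at
    p_adj <= 0.05 and does *not* flag the two equal groups.
    """
    groups = ["parental", "patient", "rescue"]
    specs = {g: _cell_spec(r) for g, r in zip(groups, rates)}
    n_map = dict(zip(groups, ns))
    ok = 0
    for rep in range(n_reps):
        config = PipelineConfig(
            synth_groups=specs, synth_kind="spikes", n_per_group=n_map,
            seed=seed + rep, detect=False,
        )
        comp = run_spike_pipeline(config).report.comparisons
        def p_of(a, b):
            row = comp[((comp.group_a == a) & (comp.group_b == b)) |
                       ((comp.group_a == b) & (comp.group_b == a))]
            return float(row["p_adj"].iloc[0])
        ok += (p_of("patient", "parental") <= 0.05
               and p_of("patient", "rescue") <= 0.05
               and p_of("parental", "rescue") > 0.05)
    return ok / n_reps


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def determinism_check(seed: int, tmpdir) -> bool:
    """Identical config+seed must reproduce byte-identical output tables."""
    from pathlib import Path

    tmpdir = Path(tmpdir)
    outputs = []
    for run in ("run1", "run2"):
        out = tmpdir / run
        config = PipelineConfig(
            synth_groups={"control": lfp_control_spec(),
                          "hyper": lfp_hyperexcitable_spec()},
            n_per_group=4, seed=seed, out_dir=str(out),
        )
        run_bandpower_pipeline(config)
        cfc_cfg = PipelineConfig(
            synth_groups={"control": _pac_spec(0.0), "coupled": _pac_spec(0.8)},
            n_per_group=3, seed=seed, n_surrogates=60, out_dir=str(out),
        )
        run_cfc_pipeline(cfc_cfg)
        spike_cfg = PipelineConfig(
            synth_groups={"a": _cell_spec(1.0, duration=30.0),
                          "b": _cell_spec(2.0, duration=30.0)},
            synth_kind="spikes", n_per_group=3, seed=seed, detect=False,
            rate_window_s=30.0, out_dir=str(out),
        )
        run_spike_pipeline(spike_cfg)
        outputs.append({p.name: p.read_bytes()
                        for p in sorted(out.glob("*.csv"))})
    return outputs[0] == outputs[1]
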