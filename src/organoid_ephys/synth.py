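"""Synthetic LFP and cell-attached recordings with known ground truth.

Every downstream stage (filtering, band power, coupling, spike detection,
group statistics) is validated against recordings whose spectral content,
coupling depth and spike times are known by construction:

* 1/f^alpha background: white Gaussian noise spectrally shaped by
  f^(-alpha/2) with the DC bin zeroed, rescaled to an exact RMS.
* Band-limited oscillations: white noise band-limited in the Fourier
  domain (brick-wall), rescaled to an exact RMS.  Brick-wall confinement
  keeps the injected band variance exact and is numerically robust at
  sub-Hz bands where an IIR band-pass at 25 kHz has normalized corners
  near 1e-5.
* Phase-amplitude coupling: a slow band-limited component provides the
  phase; a fast band-limited carrier is amplitude-modulated by
  (1 + depth*cos(phase))/norm, with the product rescaled so the fast
  component's RMS is exactly ``carrier_rms``.
* Line noise: equal-amplitude sinusoids at the mains base and harmonics.
* Drift: Fourier-domain noise below 0.05 Hz.
* Spikes: biphasic ~1.5 ms templates at Poisson (refractory-thinned) or
  burst times, plus white noise.

All generators are pure functions of their spec (seed included): the same
spec yields bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Recording, write_recording

__all__ = [
    "PacSpec",
    "LineNoiseSpec",
    "LfpSynthSpec",
    "BurstSpec",
    "SpikeSynthSpec",
    "GroundTruth",
    "gen_lfp",
    "gen_spike_times",
    "gen_cell_attached",
    "gen_group_dataset",
    "spike_template",
    "write_dataset",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PacSpec:
    """Phase-amplitude-coupled component.

    ``slow_rms`` sets the amplitude of the slow, phase-providing component
    that is added to the signal (without it the phase band would be empty
    downstream); it defaults to ``carrier_rms``.
    """

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    depth: float
    carrier_rms: float
    slow_rms: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.depth <= 1:
            raise ValueError(f"PAC depth must be in [0, 1], got {self.depth}")
        if self.carrier_rms < 0:
            raise ValueError("carrier_rms must be >= 0")


@dataclass(frozen=True)
class LineNoiseSpec:
    base: float = 60.0
    n_harmonics: int = 1
    amplitude: float = 0.1   # mV, per harmonic (sinusoid amplitude)

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class LfpSynthSpec:
    """Recipe for a synthetic LFP trace (amplitudes in mV, bands in Hz)."""

    duration: float
    fs: float
    noise_exponent: float = 1.0
    noise_rms: float = 0.05
    oscillations: tuple[tuple[float, float, float], ...] = ()
    pac: PacSpec | None = None
    line_noise: LineNoiseSpec | None = None
    drift_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be > 0")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        for rms in (self.noise_rms, self.drift_rms):
            if rms < 0:
                raise ValueError("rms values must be >= 0")
        nyq = self.fs / 2
        for f_lo, f_hi, rms in self.oscillations:
            if not 0 < f_lo < f_hi < nyq:
                raise ValueError(
                    f"oscillation band ({f_lo}, {f_hi}) Hz must satisfy "
                    f"0 < f_lo < f_hi < Nyquist ({nyq:g} Hz)"
                )
            if rms < 0:
                raise ValueError("oscillation rms must be >= 0")
        if self.pac is not None:
            for name, (f_lo, f_hi) in (("phase", self.pac.phase_band),
                                       ("amp", self.pac.amp_band)):
                if not 0 < f_lo < f_hi < nyq:
                    raise ValueError(
                        f"PAC {name} band ({f_lo}, {f_hi}) Hz must satisfy "
                        f"0 < f_lo < f_hi < Nyquist ({nyq:g} Hz)"
                    )
        if self.line_noise is not None:
            top = self.line_noise.base * self.line_noise.n_harmonics
            if top >= nyq:
                raise ValueError(
                    f"line-noise harmonic {top:g} Hz reaches Nyquist ({nyq:g} Hz)"
                )


@dataclass(frozen=True)
class BurstSpec:
    burst_rate: float        # bursts / second (Poisson onsets)
    spikes_per_burst: int
    intra_isi: float         # seconds between spikes within a burst

    def __post_init__(self) -> None:
        if self.burst_rate < 0 or self.spikes_per_burst < 1 or self.intra_isi <= 0:
            raise ValueError("invalid burst specification")


@dataclass(frozen=True)
class SpikeSynthSpec:
    """Recipe for a synthetic cell-attached trace.

    ``rate`` drives a Poisson process (refractory-thinned); ``burst`` takes
    precedence when given.  ``amplitude`` is the spike peak in mV (negative
    deflection by default, matching capacitive cell-attached spikes) and
    ``noise_sd`` the background noise, so SNR = amplitude / noise_sd.
    """

    duration: float
    fs: float
    rate: float = 1.0
    burst: BurstSpec | None = None
    amplitude: float = 0.8
    noise_sd: float = 0.1
    refractory: float = 0.001
    template_ms: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was actually injected into a synthetic recording."""

    band_variances: dict[str, float] = field(default_factory=dict)  # mV^2
    pac_depth: float | None = None
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("ground-truth spike times must be strictly increasing")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via Fourier-amplitude shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-variance noise confined to [f_lo, f_hi] (Fourier brick-wall)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz holds no Fourier bins for this trace"
        )
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def spike_template(fs: float, total_ms: float = 1.5) -> np.ndarray:
    """Biphasic cell-attached-like spike template, peak magnitude 1.

    Built as the discrete derivative of a difference-of-exponentials bump,
    giving a fast negative lobe followed by a slower positive rebound.
    """
    n = max(int(round(total_ms * 1e-3 * fs)), 3)
    t = np.arange(n + 1) / fs
    tau_r, tau_d = 0.10e-3, 0.45e-3
    bump = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    w = np.diff(bump)
    w = w / np.max(np.abs(w))
    # orient the dominant lobe negative (downward capacitive spike)
    if abs(w.min()) < abs(w.max()):
        w = -w
    return w


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_lfp(spec: LfpSynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate a synthetic LFP recording and its ground truth."""
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(spec.seed)
    x = np.zeros(n)
    truth = GroundTruth()

    if spec.noise_rms > 0:
        x += spec.noise_rms * _shaped_noise(rng, n, spec.fs, spec.noise_exponent)
        truth.band_variances["background"] = spec.noise_rms ** 2

    for k, (f_lo, f_hi, rms) in enumerate(spec.oscillations):
        if rms == 0:
            continue
        x += rms * _bandlimited_noise(rng, n, spec.fs, f_lo, f_hi)
        truth.band_variances[f"osc{k}:{f_lo:g}-{f_hi:g}Hz"] = rms ** 2

    if spec.pac is not None and spec.pac.carrier_rms > 0:
        from scipy.signal import hilbert

        pac = spec.pac
        slow = _bandlimited_noise(rng, n, spec.fs, *pac.phase_band)
        phase = np.angle(hilbert(slow))
        carrier = _bandlimited_noise(rng, n, spec.fs, *pac.amp_band)
        modulated = carrier * (1.0 + pac.depth * np.cos(phase))
        sd = modulated.std()
        if sd > 0:
            modulated *= pac.carrier_rms / sd
        slow_rms = pac.slow_rms if pac.slow_rms is not None else pac.carrier_rms
        x += slow_rms * slow + modulated
        truth.pac_depth = pac.depth
        truth.band_variances[
            f"pac_slow:{pac.phase_band[0]:g}-{pac.phase_band[1]:g}Hz"
        ] = slow_rms ** 2
        truth.band_variances[
            f"pac_carrier:{pac.amp_band[0]:g}-{pac.amp_band[1]:g}Hz"
        ] = pac.carrier_rms ** 2

    if spec.line_noise is not None and spec.line_noise.amplitude > 0:
        t = np.arange(n) / spec.fs
        ph = rng.uniform(0, 2 * np.pi, size=spec.line_noise.n_harmonics)
        for k in range(1, spec.line_noise.n_harmonics + 1):
            x += spec.line_noise.amplitude * np.sin(
                2 * np.pi * spec.line_noise.base * k * t + ph[k - 1]
            )

    if spec.drift_rms > 0:
        f_hi_drift = min(0.05, spec.fs / 4)
        drift = _bandlimited_noise(rng, n, spec.fs, 1.0 / spec.duration, f_hi_drift)
        x += spec.drift_rms * drift
        truth.band_variances["drift"] = spec.drift_rms ** 2

    rec = Recording(
        samples=x,
        fs=spec.fs,
        modality="lfp",
        source=f"synthetic:lfp:seed={spec.seed}",
    )
    return rec, truth


def gen_spike_times(spec: SpikeSynthSpec) -> np.ndarray:
    """Ground-truth spike times (s) for a spike spec, without a waveform trace."""
    rng = np.random.default_rng(spec.seed)
    if spec.burst is not None:
        b = spec.burst
        n_exp = max(int(b.burst_rate * spec.duration * 3) + 10, 10)
        onsets = np.cumsum(rng.exponential(1.0 / b.burst_rate, size=n_exp)) \
            if b.burst_rate > 0 else np.array([])
        onsets = onsets[onsets < spec.duration]
        times = (onsets[:, None] + np.arange(b.spikes_per_burst) * b.intra_isi).ravel()
        times = np.sort(times[times < spec.duration])
    elif spec.rate > 0:
        n_exp = max(int(spec.rate * spec.duration * 3) + 10, 10)
        times = np.cumsum(rng.exponential(1.0 / spec.rate, size=n_exp))
        times = times[times < spec.duration]
    else:
        times = np.array([])
    # nonparalyzable refractory thinning
    if spec.refractory > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= spec.refractory:
                kept.append(t)
        times = np.asarray(kept)
    return times


def gen_cell_attached(spec: SpikeSynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate a synthetic cell-attached trace: noise + spike templates."""
    n = int(round(spec.duration * spec.fs))
    template = spike_template(spec.fs, spec.template_ms)
    if template.size > n:
        raise ValueError(
            f"spike template ({template.size} samples) longer than trace ({n})"
        )
    times = gen_spike_times(spec)
    rng = np.random.default_rng(spec.seed + 1)  # noise stream separate from times
    x = rng.standard_normal(n) * spec.noise_sd
    for t in times:
        i = int(round(t * spec.fs))
        j = min(i + template.size, n)
        x[i:j] += spec.amplitude * template[: j - i]
    rec = Recording(
        samples=x,
        fs=spec.fs,
        modality="cell_attached",
        source=f"synthetic:cell_attached:seed={spec.seed}",
    )
    return rec, GroundTruth(spike_times=times)


# ---------------------------------------------------------------------------
# group datasets
# ---------------------------------------------------------------------------


def derive_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic, well-mixed per-recording seed (< 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{group}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class SynthRecord:
    recording: Recording
    truth: GroundTruth
    group: str
    index: int

    @property
    def rec_id(self) -> str:
        return f"{self.group}_{self.index:03d}"


def gen_group_dataset(
    specs_by_group: dict[str, LfpSynthSpec | SpikeSynthSpec],
    n_per_group: int | dict[str, int],
    master_seed: int = 0,
) -> list[SynthRecord]:
    """Generate ``n_per_group`` recordings per group with derived seeds.

    ``n_per_group`` may be a single integer or a dict group -> n (unequal
    designs such as 24/41/40 cells).  Per-recording seeds are hashes of
    (master_seed, group, index), so the dataset is reproducible as a whole
    while recordings stay independent.  Labels carry the group (as
    genotype), replicate index, and seed.
    """
    if not specs_by_group:
        raise ValueError("specs_by_group must contain at least one group")
    if isinstance(n_per_group, dict):
        n_by_group = {g: int(n_per_group[g]) for g in specs_by_group}
    else:
        n_by_group = {g: int(n_per_group) for g in specs_by_group}
    if any(n < 1 for n in n_by_group.values()):
        raise ValueError("n_per_group must be >= 1")
    records: list[SynthRecord] = []
    for group, spec in specs_by_group.items():
        for i in range(n_by_group[group]):
            seed = derive_seed(master_seed, group, i)
            child = replace(spec, seed=seed)
            if isinstance(child, LfpSynthSpec):
                rec, truth = gen_lfp(child)
            elif isinstance(child, SpikeSynthSpec):
                rec, truth = gen_cell_attached(child)
            else:
                raise TypeError(f"unsupported spec type {type(child).__name__}")
            rec.labels.update({"genotype": group, "slice_id": i, "seed": seed})
            records.append(SynthRecord(rec, truth, group, i))
    return records


def write_dataset(records: Sequence[SynthRecord], outdir: str | Path) -> Path:
    """Write recordings, ground truths and a manifest CSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rec_path = outdir / f"{r.rec_id}.raw"
        truth_path = outdir / f"{r.rec_id}.truth.json"
        write_recording(r.recording, rec_path, format="raw")
        truth_path.write_text(json.dumps({
            "band_variances": r.truth.band_variances,
            "pac_depth": r.truth.pac_depth,
            "spike_times": r.truth.spike_times.tolist(),
        }, indent=1))
        rows.append({
            "rec_id": r.rec_id,
            "group": r.group,
            "index": r.index,
            "file": rec_path.name,
            "truth_file": truth_path.name,
            "modality": r.recording.modality,
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
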