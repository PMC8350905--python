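"""Spectral power, band AUC and spectrograms for LFP recordings.

The power spectral density is a Welch-style average of linearly detrended,
Hamming-windowed, 50%-overlapping segment periodograms (one-sided density,
mV^2/Hz).  Band "AUC" is the summed binned power over a frequency range,
the hyperexcitability readout used for the 0.25-1 Hz slow-wave band and the
30-79.9 Hz low-gamma band.

"Normalized" spectral power here means the PSD is scaled to unit integral
over a fixed analysis range (default 0.25-100 Hz), making band AUC a
dimensionless band fraction comparable across slices with different
absolute amplitudes.  Group-level "fold" values additionally divide each
recording's AUC by the control-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Recording
from .preprocess import Blocks, detrend_windowed

__all__ = [
    "SpectralDensity",
    "BandPower",
    "Spectrogram",
    "ANALYSIS_RANGE",
    "SWO_BAND",
    "LOW_GAMMA_BAND",
    "compute_psd",
    "normalize_psd",
    "band_auc",
    "group_auc_fold",
    "compute_spectrogram",
]

#: default normalization range for "normalized spectral power", Hz
ANALYSIS_RANGE = (0.25, 100.0)
#: slow-wave oscillation band, Hz
SWO_BAND = (0.25, 1.0)
#: low gamma band, Hz
LOW_GAMMA_BAND = (30.0, 79.9)


@dataclass
class SpectralDensity:
    freqs: np.ndarray          # Hz, ascending uniform grid
    power: np.ndarray          # mV^2/Hz raw; unitless/Hz when normalized
    df: float                  # bin width, Hz
    normalized: bool = False
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same length")
        if np.any(self.power < -1e-30):
            raise ValueError("power must be nonnegative")


@dataclass
class BandPower:
    label: str
    f_lo: float
    f_hi: float
    auc: float
    auc_fold: float | None = None


@dataclass
class Spectrogram:
    times: np.ndarray          # s, block centers
    freqs: np.ndarray          # Hz
    power: np.ndarray          # (time, frequency), one-sided density

    def __post_init__(self) -> None:
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError("power matrix dims must match time/frequency axes")


def _blocks_psd(blocks: Blocks) -> SpectralDensity:
    """One-sided averaged periodogram of windowed blocks (density scaling)."""
    L = blocks.block_len
    win_power = float(np.sum(blocks.window ** 2))
    spec = np.fft.rfft(blocks.data, axis=1)
    p = (np.abs(spec) ** 2) / (blocks.fs * win_power)
    # one-sided: double everything except DC (and Nyquist when L is even)
    if L % 2 == 0:
        p[:, 1:-1] *= 2.0
    else:
        p[:, 1:] *= 2.0
    power = p.mean(axis=0)
    freqs = np.fft.rfftfreq(L, d=1.0 / blocks.fs)
    return SpectralDensity(
        freqs=freqs,
        power=power,
        df=blocks.fs / L,
        normalized=False,
        n_segments=blocks.n_blocks,
    )


def compute_psd(
    rec: Recording,
    segment_len: float = 4.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> SpectralDensity:
    """Welch-averaged PSD of a (preprocessed) recording.

    Satisfies Parseval for stationary inputs: integral of the PSD over
    frequency equals the trace variance to within a few percent.
    """
    if segment_len > rec.duration:
        raise ValueError(
            f"segment_len {segment_len:g} s exceeds the {rec.duration:g} s trace; "
            "use a shorter segment_len"
        )
    blocks = detrend_windowed(rec, segment_len=segment_len, overlap=overlap,
                              window=window)
    return _blocks_psd(blocks)


def normalize_psd(
    psd: SpectralDensity, range: tuple[float, float] = ANALYSIS_RANGE
) -> SpectralDensity:
    """Scale the PSD so its integral over ``range`` is 1."""
    f_lo, f_hi = range
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"normalization range {range} contains no frequency bins")
    total = float(psd.power[mask].sum() * psd.df)
    if total <= 0:
        raise ValueError("total power over the normalization range is zero")
    return replace(psd, power=psd.power / total, normalized=True)


def band_auc(
    psd: SpectralDensity, f_lo: float, f_hi: float, label: str = ""
) -> BandPower:
    """Summed binned power over [f_lo, f_hi] (bin centers, closed interval)."""
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"invalid band ({f_lo}, {f_hi})")
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    if not mask.any():
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz contains no bins at df={psd.df:g} Hz"
        )
    auc = float(psd.power[mask].sum() * psd.df)
    return BandPower(label=label or f"{f_lo:g}-{f_hi:g} Hz", f_lo=f_lo,
                     f_hi=f_hi, auc=auc)


def group_auc_fold(
    values_by_group: dict[str, np.ndarray], reference_group: str
) -> dict[str, np.ndarray]:
    """Divide every AUC by the reference (control) group's mean.

    The reference group's fold values then average to 1, matching bar plots
    where the control hovers at unity.
    """
    if reference_group not in values_by_group:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref = np.asarray(values_by_group[reference_group], float)
    if ref.size == 0:
        raise ValueError("reference group is empty")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError(f"reference-group mean must be > 0, got {ref_mean:g}")
    return {g: np.asarray(v, float) / ref_mean for g, v in values_by_group.items()}


def compute_spectrogram(
    rec: Recording,
    window_len: float = 4.0,
    step: float = 1.0,
    window: str = "hamming",
) -> Spectrogram:
    """Short-time power spectrogram (time x frequency, density scaling)."""
    if window_len > rec.duration:
        raise ValueError("window_len exceeds trace duration")
    L = int(round(window_len * rec.fs))
    step_samples = int(round(step * rec.fs))
    if step_samples < 1:
        raise ValueError("step too small for the sampling rate")
    if step_samples > L:
        raise ValueError("step larger than window_len is not supported")
    overlap = 1.0 - step_samples / L
    blocks = detrend_windowed(rec, segment_len=window_len, overlap=overlap,
                              window=window)
    win_power = float(np.sum(blocks.window ** 2))
    spec = np.fft.rfft(blocks.data, axis=1)
    p = (np.abs(spec) ** 2) / (rec.fs * win_power)
    if L % 2 == 0:
        p[:, 1:-1] *= 2.0
    else:
        p[:, 1:] *= 2.0
    times = blocks.t_starts + window_len / 2.0
    freqs = np.fft.rfftfreq(L, d=1.0 / rec.fs)
    return Spectrogram(times=times, freqs=freqs, power=p)


def psd_to_frame(psd: SpectralDensity) -> pd.DataFrame:
    """PSD as a two-column table (freq_hz, power) for CSV export."""
    return pd.DataFrame({"freq_hz": psd.freqs, "power": psd.power})
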