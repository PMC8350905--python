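"""Phase-amplitude cross-frequency coupling (PAC) via the modulation index.

A slow band's instantaneous phase and a fast band's amplitude envelope are
extracted from the analytic signal of band-passed data.  Coupling is scored
with the Kullback-Leibler modulation index: the fast envelope is averaged
in phase bins, normalized to a distribution P, and

    MI = KL(P || uniform) / log(n_bins)      in [0, 1],

so 0 means the envelope is phase-independent and 1 means all envelope mass
sits in a single phase bin.  Significance comes from a surrogate null built
by circularly time-shifting the envelope relative to the phase, which
preserves both marginals while destroying their alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "BandPair",
    "Comodulogram",
    "SurrogateNull",
    "DEFAULT_PHASE_BANDS",
    "DEFAULT_AMP_BANDS",
    "band_phase_amplitude",
    "modulation_index",
    "mi_surrogate_null",
    "comodulogram",
]

#: default slow (phase-providing) bands, Hz
DEFAULT_PHASE_BANDS: list[tuple[str, float, float]] = [
    ("SWO", 0.25, 1.0),
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
]
#: default fast (amplitude-providing) bands, Hz
DEFAULT_AMP_BANDS: list[tuple[str, float, float]] = [
    ("low_gamma", 30.0, 80.0),
    ("high_gamma", 80.0, 150.0),
    ("HFO", 150.0, 250.0),
]

_MIN_REL_WIDTH = 1e-4  # minimum band width as a fraction of Nyquist


@dataclass(frozen=True)
class BandPair:
    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    phase_label: str = ""
    amp_label: str = ""

    def validate(self, fs: float) -> None:
        p_lo, p_hi = self.phase_band
        a_lo, a_hi = self.amp_band
        if not 0 < p_lo < p_hi:
            raise ValueError(f"invalid phase band {self.phase_band}")
        if not 0 < a_lo < a_hi:
            raise ValueError(f"invalid amplitude band {self.amp_band}")
        if p_hi > a_lo:
            raise ValueError(
                f"phase band {self.phase_band} must lie below amplitude band "
                f"{self.amp_band} ({self.phase_label or 'phase'}:"
                f"{self.amp_label or 'amp'})"
            )
        if a_hi >= fs / 2:
            raise ValueError(
                f"amplitude band {self.amp_band} reaches Nyquist ({fs / 2:g} Hz)"
            )


@dataclass
class Comodulogram:
    phase_bands: list[tuple[str, float, float]]
    amp_bands: list[tuple[str, float, float]]
    mi: np.ndarray                 # (n_phase, n_amp), in [0, 1]
    z: np.ndarray                  # surrogate z-scores (NaN if no surrogates)
    n_bins: int
    n_surrogates: int
    seed: int


@dataclass
class SurrogateNull:
    mi_obs: float
    null_mean: float
    null_sd: float
    z: float
    null_values: np.ndarray


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 3) -> np.ndarray:
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < f_lo < f_hi < fs/2 ({fs / 2:g})")
    min_width = _MIN_REL_WIDTH * fs / 2
    if f_hi - f_lo < min_width:
        raise ValueError(
            f"band {band} is too narrow for an order-{order} filter at "
            f"fs={fs:g} Hz; minimum width {min_width:g} Hz"
        )
    return signal.butter(order, (f_lo, f_hi), btype="bandpass", fs=fs, output="sos")


def band_phase_amplitude(
    rec: Recording, band: tuple[float, float], mode: str
) -> np.ndarray:
    """Analytic-signal phase (radians) or envelope (mV) of a band-passed trace.

    ``mode`` is ``"phase"`` or ``"amplitude"``.  The first/last 2/f_lo
    seconds carry filter and Hilbert edge transients; trim them before
    statistics (``comodulogram`` does this internally).
    """
    if mode not in ("phase", "amplitude"):
        raise ValueError(f"mode must be 'phase' or 'amplitude', got {mode!r}")
    sos = _bandpass_sos(band, rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.samples)
    analytic = signal.hilbert(filtered)
    if mode == "phase":
        return np.angle(analytic)
    return np.abs(analytic)


def _phase_bin_index(phase: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)


def _mi_binned(idx: np.ndarray, counts: np.ndarray, amp: np.ndarray,
               n_bins: int, warn_empty: bool = True) -> float:
    """MI from precomputed phase-bin indices and bin counts."""
    if not np.any(amp > 0):
        raise ValueError("amplitude sequence is identically zero")
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    occupied = counts > 0
    n_occ = int(occupied.sum())
    if n_occ < n_bins and warn_empty:
        warnings.warn(
            f"{n_bins - n_occ} empty phase bins; MI computed over {n_occ} "
            "occupied bins (conservative)",
            stacklevel=3,
        )
    if n_occ < 2:
        return 0.0
    mean_amp = sums[occupied] / counts[occupied]
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("mean amplitude is zero in every occupied phase bin")
    p = mean_amp / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_occ)))
    return min(kl / np.log(n_bins), 1.0)


def modulation_index(
    phase: np.ndarray, amp: np.ndarray, n_bins: int = 18
) -> float:
    """KL-based modulation index of a phase/envelope pair.

    Empty phase bins are excluded and the distribution renormalized over the
    occupied bins (the uniform reference shrinks with them), which biases MI
    toward zero on very short traces; a warning is emitted when it happens.
    """
    phase = np.asarray(phase, float)
    amp = np.asarray(amp, float)
    if phase.shape != amp.shape or phase.ndim != 1:
        raise ValueError("phase and amp must be 1-D sequences of equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    idx = _phase_bin_index(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return _mi_binned(idx, counts, amp, n_bins)


def mi_surrogate_null(
    phase: np.ndarray,
    amp: np.ndarray,
    fs: float,
    n_surrogates: int = 200,
    seed: int = 0,
    n_bins: int = 18,
    min_shift_s: float = 1.0,
) -> SurrogateNull:
    """Surrogate null for MI built from circular shifts of the envelope.

    Shifts are uniform over [min_shift_s, T - min_shift_s] so the surrogate
    envelope is never nearly aligned with the observed one.
    """
    if n_surrogates < 50:
        raise ValueError("n_surrogates must be >= 50 for a usable null")
    phase = np.asarray(phase, float)
    amp = np.asarray(amp, float)
    n = phase.size
    min_shift = int(round(min_shift_s * fs))
    if n <= 2 * min_shift:
        raise ValueError(
            f"trace too short for surrogate shifts >= {min_shift_s:g} s"
        )
    idx = _phase_bin_index(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mi_obs = _mi_binned(idx, counts, amp, n_bins)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    null = np.array([
        _mi_binned(idx, counts, np.roll(amp, int(s)), n_bins, warn_empty=False)
        for s in shifts
    ])
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate surrogate null (zero variance)")
    mean = float(null.mean())
    return SurrogateNull(
        mi_obs=mi_obs,
        null_mean=mean,
        null_sd=sd,
        z=(mi_obs - mean) / sd,
        null_values=null,
    )


def comodulogram(
    rec: Recording,
    phase_bands: list[tuple[str, float, float]] | None = None,
    amp_bands: list[tuple[str, float, float]] | None = None,
    n_bins: int = 18,
    n_surrogates: int = 200,
    seed: int = 0,
) -> Comodulogram:
    """MI (and surrogate z) over a grid of phase x amplitude band pairs.

    Pass ``n_surrogates=0`` to skip the surrogate layer (z filled with NaN),
    e.g. when significance is assessed across recordings instead.
    """
    phase_bands = phase_bands if phase_bands is not None else list(DEFAULT_PHASE_BANDS)
    amp_bands = amp_bands if amp_bands is not None else list(DEFAULT_AMP_BANDS)
    if not phase_bands or not amp_bands:
        raise ValueError("phase_bands and amp_bands must be non-empty")
    for pl, p_lo, p_hi in phase_bands:
        for al, a_lo, a_hi in amp_bands:
            BandPair((p_lo, p_hi), (a_lo, a_hi), pl, al).validate(rec.fs)

    phases = {}
    trims = {}
    for pl, p_lo, p_hi in phase_bands:
        phases[pl] = band_phase_amplitude(rec, (p_lo, p_hi), "phase")
        trims[pl] = int(round(2.0 / p_lo * rec.fs))
    envs = {al: band_phase_amplitude(rec, (a_lo, a_hi), "amplitude")
            for al, a_lo, a_hi in amp_bands}

    mi = np.zeros((len(phase_bands), len(amp_bands)))
    zmat = np.full_like(mi, np.nan)
    for i, (pl, p_lo, p_hi) in enumerate(phase_bands):
        k = min(trims[pl], (phases[pl].size - 2) // 2)
        sl = slice(k, -k) if k > 0 else slice(None)
        ph = phases[pl][sl]
        idx = _phase_bin_index(ph, n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        for j, (al, _, _) in enumerate(amp_bands):
            am = envs[al][sl]
            mi[i, j] = _mi_binned(idx, counts, am, n_bins)
            if n_surrogates > 0:
                n = ph.size
                min_shift = min(int(round(rec.fs)), (n - 2) // 2)
                rng = np.random.default_rng(seed + 1000 * i + j)
                shifts = rng.integers(min_shift, n - min_shift,
                                      size=n_surrogates)
                null = np.array([
                    _mi_binned(idx, counts, np.roll(am, int(s)), n_bins,
                               warn_empty=False)
                    for s in shifts
                ])
                sd = float(null.std(ddof=1))
                zmat[i, j] = (mi[i, j] - null.mean()) / sd if sd > 0 else np.nan
    return Comodulogram(
        phase_bands=list(phase_bands),
        amp_bands=list(amp_bands),
        mi=mi,
        z=zmat,
        n_bins=n_bins,
        n_surrogates=n_surrogates,
        seed=seed,
    )
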