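# Methods

This note documents the models, conventions and numerical choices behind
`organoid-ephys`, and what the synthetic validation does and does not
establish about real recordings.

## Signal model and units

All voltages are millivolts, times seconds, frequencies hertz. A
`Recording` is a uniformly sampled single-channel trace with acquisition
metadata (modality, genotype/treatment/slice labels, provenance). Typical
acquisition rates are 25 kHz for slice LFPs and 10 kHz for cell-attached
recordings; nothing in the code assumes these values.

## Preprocessing

The LFP conditioning chain is notch-then-high-pass, both zero-phase
(forward–backward) so that waveform timing is preserved for the
phase-sensitive coupling analysis.

* **Notch.** Cascaded second-order IIR notches at 60 Hz and its
  harmonics (5 by default). The −3 dB width is constant at 1 Hz per
  notch (i.e. Q grows with the harmonic) rather than constant-Q: a
  constant Q of ~30 would widen the stopband to 10 Hz at the 300 Hz
  harmonic and bite into the gamma analysis bands, whereas the 1 Hz
  width keeps the passband within ±1 dB everywhere outside ±2 Hz of each
  notch even after two-pass filtering, while attenuation at the notch
  centers exceeds 100 dB. Narrow notches ring for seconds, so the
  forward–backward pass uses padding of several time constants (4/width).
* **High-pass.** Butterworth, order 4, cutoff 0.1 Hz for the analysis
  path (0.5 Hz is the spectrogram display convention). A 0.1 Hz filter
  rings for tens of seconds: `edge_exclusion_s` flags 3/cutoff seconds
  per side (capped at 10% of the trace so short recordings keep data),
  and the pipelines trim that margin before spectral statistics.
* **Detrending/segmentation.** Spectral estimation operates on
  overlapping segments (4 s, 50% overlap by default), each linearly
  detrended and Hamming-windowed.

## Spectral estimation and band AUC

The PSD is the mean of one-sided segment periodograms with density
scaling (Parseval holds to within a few percent for stationary inputs;
the implementation is cross-checked against an independent Welch
estimator in the tests). With 4 s segments the grid step is 0.25 Hz, so
the 0.25–1 Hz slow-wave band spans exactly four bins.

Two normalizations appear in figures of this kind, and the paper trail
for either is usually thin, so both are explicit here:

* **"Normalized spectral power"** scales the PSD to unit integral over a
  fixed analysis range, 0.25–100 Hz by default. Band AUC then becomes a
  dimensionless band *fraction*, comparable across slices with different
  absolute amplitudes. Raw (mV²) AUC is also available.
* **Fold normalization** divides each recording's AUC by the
  control-group mean, so control bars hover at 1. Fold values leave
  two-group test statistics unchanged (both groups are divided by the
  same constant); this is verified as a test invariant.

Band edges use a closed bin-center convention: a bin contributes iff its
center frequency lies in [f₁, f₂]. Sums over a partition of the analysis
range reproduce the total AUC exactly.

## Cross-frequency coupling

Phase and envelope come from the analytic signal (Hilbert transform) of
zero-phase Butterworth order-3 band-passed data; the first and last
2/f_lo seconds of the slow band are trimmed before binning to discard
filter and Hilbert edge transients.

The modulation index is the KL-divergence form: mean envelope per phase
bin (18 bins), normalized to a distribution, divergence from uniform
divided by log 18, so MI ∈ [0, 1] with 1 attained by a point-mass
distribution. Empty phase bins (possible on very short traces) are
excluded with renormalization over the occupied bins, which biases MI
toward zero — a conservative failure mode — and emits a warning.

Significance uses circular-shift surrogates: the envelope is rotated by
uniform random offsets of at least 1 s, MI recomputed per surrogate, and
the observed MI expressed as a z-score. The shift preserves both
marginals and the envelope autocorrelation while destroying phase
alignment. This matters beyond per-recording significance: amplitude
modulation makes the envelope marginal peakier, which *raises the MI
estimation floor of every phase band paired with that envelope*. A group
contrast on raw MI therefore flags spurious pairs; the pipeline contrast
runs on surrogate z-scores whenever surrogates are enabled, which removes
exactly that bias and localizes the contrast to the genuinely coupled
pair. The per-pair group contrast is a Welch t-test with step-down
Holm–Šídák correction across the band grid.

Default grid: phase SWO 0.25–1, δ 1–4, θ 4–8, α 8–12, β 12–30 Hz;
amplitude low γ 30–80, high γ 80–150, HFO 150–250 Hz; all configurable.
The MI algorithm itself (KL form, 18 bins) is a field-standard choice
rather than something the source experiments pin down.

## Spike detection and firing rate

Cell-attached traces are high-passed at 300 Hz (order 4, zero-phase) to
remove field potentials; a ~1.5 ms biphasic template at 10 kHz passes
with its peak preserved within 20%.

The threshold is median ± k·1.4826·MAD. The multiplier's design target
is "above the background-noise peaks": for a 4-minute 10 kHz trace the
expected extreme of ~2.4 million Gaussian samples is ≈5σ, so k = 5 sits
*at* the noise-peak level and admits roughly one noise event per
every-other recording, while the default k = 5.5 keeps the probability of
any noise crossing near 4% per 4-minute trace. Raising k further (≥ 6)
begins to miss genuine spikes at signal-to-noise 8, so 5.5 is the
operating point between the two failure modes; k is configurable and
should be re-examined for very long recordings or other noise levels.
Detection takes local extrema beyond threshold (negative polarity by
default — cell-attached capacitive spikes point down), keeping the larger
event within any 2 ms refractory window.

Firing rate is spike count over a 240 s window (placed at the start of
the recording) divided by the window length; shorter recordings fall
back to the available span with a warning.

## Group statistics

The decision tree follows the conventions of organoid/slice studies:
Shapiro–Wilk per group at α = 0.05 (a group with zero variance is routed
to the nonparametric branch), then Welch t / Mann–Whitney for two groups
and ANOVA + Tukey HSD / Kruskal–Wallis + Dunn beyond. Choices worth
noting:

* The normality gate is per group ("any group fails → nonparametric");
  aggregate wordings of this rule are ambiguous, and the per-group
  reading is the testable one.
* Mann–Whitney uses the asymptotic tie-corrected p with continuity
  correction, so p-values are well-defined under ties and match a
  closed-form oracle to 1e−8.
* Tukey rows report the studentized-range statistic q; `p_adj` is the
  k-group Tukey p (scipy, verified against statsmodels) and `p_raw` the
  same q referred to a 2-group range distribution, which the adjusted p
  can only exceed — keeping the report invariant `p_adj ≥ p_raw` exact.
* Dunn's z uses pooled rank sums with tie correction;
  multiplicity-adjusted p is Bonferroni-style (×m, clamped at 1),
  matching the common "Dunn's multiple comparisons" convention.
* Holm–Šídák is the step-down form: with p sorted ascending,
  p_adj(i) = max_{j≤i} [1 − (1 − p_(j))^(m−j+1)].
* ROUT-style outlier screening for univariate samples collapses the
  robust-regression-plus-FDR procedure to: biweight location, MAD scale,
  t-referred residuals (df = n − 2), Benjamini–Hochberg at Q (1% by
  default). This is an approximation to the proprietary original;
  removed points are always reported, never silently dropped.

## Synthetic recordings

The generator is first-class, tested code: every downstream stage is
validated against its ground truth.

* **Background**: white Gaussian noise shaped to 1/f^α in the Fourier
  domain (DC zeroed), rescaled to exact RMS.
* **Oscillations**: white noise brick-wall band-limited in the Fourier
  domain, rescaled to exact RMS. Frequency-domain band-limiting keeps the
  injected band variance exact and is numerically robust for sub-Hz bands
  at 25 kHz, where IIR band-passes with normalized corners near 1e−5 are
  unusable.
* **Coupling**: a band-limited slow component supplies the phase; an
  independent band-limited carrier is modulated by (1 + depth·cos φ) and
  rescaled so the fast component's RMS is exact. The slow component is
  injected too (amplitude `slow_rms`), since a recoverable phase band
  must exist in the trace.
* **Line noise and drift**: equal-amplitude harmonics of the mains
  frequency; sub-0.05 Hz Fourier-domain noise.
* **Spikes**: biphasic difference-of-exponentials templates (~1.5 ms,
  derivative of a double-exponential bump, dominant lobe negative) at
  Poisson times thinned by a 1 ms dead time (a 2 ms dead time would
  already bias a 10 Hz train's realized rate by 2%), or at burst times
  (Poisson burst onsets, fixed intra-burst ISI). SNR = template peak /
  noise SD.
* **Datasets**: per-recording seeds are SHA-256 hashes of
  (master seed, group, index), so whole datasets are reproducible while
  recordings stay independent; group sizes may be unequal.

What the generator does *not* emulate: nonstationarity (seizure-like
state transitions, 4-AP wash-in dynamics), electrode drift and artifacts,
spike-waveform variability and overlapping units, correlated
network firing, or any biophysics of the tissue. Passing the validation
suite therefore establishes the *correctness of the measurement chain* on
signals with known structure — not that the readouts are optimal or
artifact-proof on real recordings.

## Validation study conditions

The Monte-Carlo studies in `organoid_ephys.studies` fix the group sizes
and effect structure of the experimental designs this analysis serves:
n = 14 slices per genotype for LFP band power with a 3× slow-wave power
elevation; two groups of 8 recordings for coupling localization (depth
0.8 vs 0, injection confined to 2–3 Hz phase and 180–220 Hz carrier so
it lands inside a single δ:HFO grid cell); and 24/41/40 cells with one
group's firing rate 4× the others for the rate design. Traces for these
studies are synthesized at 1 kHz for 60–120 s — the analyzed band
structure lives below 250 Hz, so this grid keeps every band and all five
notch harmonics below Nyquist while making hundreds of replicate pipeline
runs cheap; the filter contract itself is verified at the full 25 kHz.
Spike-detection fidelity uses the full 240 s × 10 kHz condition; the
100-replicate rate-design study runs on synthesized spike *trains*
(detection validated separately) because 105 cells × 240 s × 10 kHz per
replicate would add nothing but waveform synthesis cost.

Determinism is a contract: generators are pure functions of their spec
(seed included), every pipeline output is reproducible byte-for-byte
from config + seed, and each output table is traceable to a config hash
recorded in the run manifest.

## Known limitations

* On-disk formats are CSV and float64-raw + JSON sidecar; vendor
  acquisition formats (pCLAMP, CED) and NWB are out of scope — convert
  first.
* The pure-noise false-positive guarantee of the spike detector is
  probabilistic, not absolute: at k = 5.5 about one 4-minute trace in
  twenty-five still contains a single suprathreshold noise extremum.
* Single channel only; no spike sorting; no time-resolved coupling; no
  mixed-effects modeling of organoid/batch nesting (labels are carried
  so such models can be fitted elsewhere).
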