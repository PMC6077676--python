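# Methods

`pcgkit` implements an end-to-end pipeline for classifying single-channel
heart-sound (phonocardiogram, PCG) recordings as normal or abnormal:
preprocessing, four-state segmentation, extraction of 515 features from nine
signal domains, two RBF-kernel support-vector machines (signal quality and
diagnosis), and the weighted three-way scoring function used by the public
heart-sound classification challenge. This note records the model choices,
the defaults that matter, and what the synthetic test bed does and does not
demonstrate.

## Signal model and preprocessing

A recording `x(n)` is a quasi-periodic train of cardiac cycles, each the
concatenation of four states: the first heart sound (S1), the systolic
interval, the second heart sound (S2), and the diastolic interval. Normal
heart sounds concentrate below ~200 Hz; murmurs extend the spectrum up to
roughly 800 Hz, which is why the feature bands stop at 820 Hz and the working
sampling rate is 2000 Hz (Nyquist above the highest analysis band).

Preprocessing is a fixed chain:

1. **High-pass at 10 Hz** — order-2 Butterworth applied forward–backward.
   Zero-phase filtering is a deliberate choice: a causal filter would delay
   the envelope and shift every state boundary.
2. **Spike removal** — the signal is cut into 500 ms windows; a window whose
   maximum absolute amplitude exceeds 3× the median of the window maxima is
   deemed to contain a spike, and the samples between the surrounding
   zero-crossings are zeroed. The procedure iterates because removing the
   dominant spike can expose the next one. Window length and threshold
   factor are configurable; the defaults are conventional values for
   stethoscope artifacts.
3. **Normalization** to zero mean, unit standard deviation. Normalization
   happens once, before segmentation; every feature is computed on the
   normalized signal. All amplitude- and energy-domain features are ratios
   and therefore invariant to this (and any) global rescaling.

## Segmentation

All 515 features depend only on the state decomposition, so the segmenter is
pluggable: external annotations (CSV of `state,start_sample,end_sample`,
0-based, half-open) are accepted verbatim, or a built-in segmenter runs.

The built-in segmenter is a deterministic duration-constrained Viterbi
decoder, deliberately simpler than a trained hidden semi-Markov model:

* **Envelope**: homomorphic envelope (low-pass at 8 Hz of the log magnitude
  of the analytic signal), decimated to 50 Hz frames.
* **Rhythm estimates**: the cycle period is the strongest envelope
  autocorrelation peak in the 30–200 bpm band (no peak → error). The
  S1-to-S2 spacing is the strongest autocorrelation peak strictly below half
  a cycle — systole is the shorter half of the cycle in this rhythm model,
  so searching below period/2 excludes the phase-swapped (S1↔S2) solution.
* **Decoding**: four states in hard-wired cyclic order, Gaussian emissions
  on the envelope (high mean for S1/S2, low for systole/diastole, means
  estimated from envelope quantiles), and Gaussian duration priors:
  S1 122±49 ms, S2 92±35 ms, systole and diastole means derived from the
  rhythm estimates. The duration prior is a soft (untruncated) Gaussian so
  that an atypical run — e.g. a terminal diastole covering a tail that
  contains no further beat — pays a quadratic penalty rather than forcing a
  spurious extra cycle. Boundary-truncated first/last runs are scored with
  the duration survival function. Ties break toward the earliest boundary
  (first-maximum argmax), making the decoder fully deterministic.
* **Boundary refinement**: the 20 ms frame grid clips the quiet onset and
  offset of each transient, so each decoded S1/S2 interval is grown outward
  at sample resolution while the envelope exceeds a stop threshold — the
  larger of 5 % of the state's median peak and 4× the median silence-state
  envelope (the ambient floor). The midpoint of the adjacent silence
  interval caps the growth so the partition survives.

On clean synthetic recordings this recovers ≈98 % sample-wise state accuracy
at 60–75 bpm. Known limitations: at ≥90 bpm with a long systolic fraction
the S1–S2 spacing approaches the half-cycle ambiguity limit and individual
recordings can mis-lock; loud murmurs raise the silence-state envelope and
pull accuracy down to roughly two-thirds. Both are accepted: noise-robust
segmentation is out of scope, and reference annotations can always be
injected (the synthetic generator provides ground truth; the evaluation
pipeline uses it).

## The 515 features

Canonical order and counts: time intervals (20), per-state spectra (308),
amplitude ratios (12), energy (47), record spectrum (27), cepstrum (65),
cyclostationarity (4), higher-order statistics (16), entropy (16). Features
that cannot be computed (too few cycles, empty state, zero-energy
denominator) are NaN, never silently zero; imputation is a model-time
concern.

Choices the headline definitions leave open, resolved here:

* **Per-state spectra** (30–790 Hz grid, 10 Hz steps, 77 × 4 states): each
  cycle's state slice is windowed with a Gaussian of SD = length/6 (a
  conventional width giving ≈3σ support), zero-padded to a per-state common
  FFT length with ≤10 Hz bin spacing, amplitude-normalized by the window
  sum, averaged over cycles, and read at each grid frequency's nearest bin.
* **Band energies** (27 bands, [10,40]…[790,820] Hz): fifth-order
  Butterworth band-passes applied in one direction (matching the plain
  `filter(b, a, x)` form of the definition), energy ratio against the raw
  signal. The four state-to-cycle energy ratios sum to exactly 1 per cycle
  because the cycle is the concatenation of its states.
* **Record spectrum ratios**: "whole band" means 10–820 Hz (the union of
  the 27 bands); a DFT bin belongs to the half-open band [lo, hi), so the
  27 ratios partition the mass and sum to 1.
* **Cepstrum**: real cepstrum (inverse DFT of the natural-log magnitude
  spectrum), first 13 coefficients; magnitudes floored at 1e-12× the peak
  before the log. Computed for the whole record and for each state's
  intervals concatenated in temporal order.
* **Cyclostationarity**: the cycle-frequency spectral density γ(α) is
  estimated as the magnitude spectrum of the mean-removed squared Hilbert
  envelope, per non-overlapping 3 s subsequence, on cycle frequencies
  (0, 10] Hz. The basic cycle frequency η is the largest peak in the
  physiological 0.5–2.5 Hz band; the degree of cyclostationarity is
  γ(η) / ∫γ (rectangle rule on the α grid) and peak sharpness is
  max γ / median γ. Means and SDs over subsequences; with a single
  subsequence the SDs are NaN.
* **Higher-order statistics**: skewness is Fisher's g1; kurtosis is the
  non-excess convention (Gaussian → 3).
* **Entropy**: sample entropy with m = 2, tolerance r = 0.2× the slice SD,
  counting template pairs over a common index range for lengths m and m+1;
  zero matches yield NaN rather than ±∞. Fuzzy measure entropy follows the
  local-plus-global formulation: fuzzy membership exp(−(d/r)^2) of the
  Chebyshev distance, local similarity on segments with their own means
  removed, global similarity on segments with the whole-slice mean removed.
  Slices are downsampled to 1000 Hz first, bounding the quadratic cost;
  both estimators are exact (verified against exhaustive pairwise oracles).

## Classification model

Two soft-margin SVMs share one implementation (`PcgSvm` → `fit()` →
`PcgSvmResults`): quality (1 clean / 0 noisy) and diagnosis (+1 abnormal /
−1 normal). The kernel is the Gaussian RBF
`exp(−‖xi−xj‖² / (2σ²))` with σ = 14 and C = 1 by default; a non-squared
exponential variant and a linear kernel exist for comparison runs. The
515 features mix units (seconds, ratios, log-magnitudes), so columns are
z-scored with training-split statistics before the kernel; missing values
are imputed with training-split medians; all-missing columns are dropped
with a warning. Class-weighted penalties are available but off by default.
The dual solution is exposed (support vectors, coefficients αi ∈ [0, C]
with Σαiyi = 0, bias) and checked in tests.

**Three-way decision rule.** Quality is predicted first; a record is
labeled 0 (uncertain) iff predicted noisy AND the absolute diagnosis margin
is below τ (default 0.3). τ = 0 disables the uncertain output; τ = ∞ sends
every noisy record to uncertain. The rule is a documented design choice —
the scoring function defines how "uncertain" is rewarded but not how it is
produced.

## Scoring and evaluation

Reference categories are diagnosis × quality; decisions are
normal/uncertain/abnormal. With weights wa1/wa2 (clean/noisy shares of the
abnormal cohort) and wn1/wn2 (same for normal):

    Se = wa1·Aa1/(Aa1+Aq1+An1) + wa2·(Aa2+Aq2)/(Aa2+Aq2+An2)
    Sp = wn1·Nn1/(Na1+Nq1+Nn1) + wn2·(Nn2+Nq2)/(Na2+Nq2+Nn2)
    Overall = (Se + Sp)/2

Uncertain counts as correct for noisy records only. A zero-denominator term
contributes 0 with a logged warning. By default each evaluated split is
scored with weights computed from that split's own references; full-cohort
weights are available as an option.

Feature ranking uses Pearson correlation with the ±1 label (Spearman
optional), missing values pairwise-excluded, constant features ranked last,
ties broken by canonical order. Domain contributions are reported as
membership counts in the top 10/100/200/300.

Experiment drivers: repeated stratified random splits (sampling each
diagnosis class separately; train_fraction = 1 is the memorization
protocol), and stratified k-fold cross-validation restricted to one feature
domain. Every repeat derives its seed from the master seed via a
splitmix-style ladder (`SeedSequence([master, index])`), so any single
repeat is reproducible in isolation.

## Synthetic test bed

The generator emulates exactly the signal properties the features exploit:

* S1/S2 as Hanning-windowed two-tone bursts (70+110 Hz and 90+140 Hz,
  S2 at 0.8× amplitude), durations 120/90 ms;
* cycle timing: 75 bpm by default with 3 % multiplicative Gaussian jitter,
  truncated so the transients always fit; the final cycle is truncated at
  the signal end, as in real recordings that stop mid-cycle;
* murmurs: Butterworth band-limited Gaussian noise (150–600 Hz) confined to
  systole and/or diastole at 0 dB relative to S1 RMS, with only a brief
  edge taper — heavy amplitude modulation would suppress the murmur's
  sample entropy, one of the discriminative directions the features rely on;
* a faint low-frequency ambient floor (low-passed noise at 80 Hz, 30 dB
  below signal RMS) under every recording, so no state is exactly silent
  and quiet states carry a smooth, low-entropy baseline;
* the noisy quality class receives broadband white noise (6 dB SNR) and
  Poisson spikes at 0.5 events/s; the quality label is 0 iff broadband SNR
  < 15 dB or spikes are present.

Dataset defaults for the end-to-end evaluation: 200 recordings (100 normal,
100 abnormal), 20 % noisy, 10 s each — large enough for stable 10-fold
scores, small enough that the full pipeline (including feature extraction)
runs in minutes on one CPU.

By construction, murmur recordings have larger high-band energy ratios,
larger high-frequency state-spectrum values, and larger systolic sample
entropy than normal ones; tests assert these one-sided directions over
seeds. What passing does **not** show: the generator has stationary murmur
morphology, no respiratory or hemodynamic variability, no pathology-specific
time-frequency signatures, and its class separation is far cleaner than the
real challenge data — synthetic cross-validated scores near 1.0 say the
pipeline is wired correctly, not that real-data scores will match. Running
on the real database is a manual, optional step
(`scripts/reproduce_challenge.py`).

## Numerical notes

* Sample SDs use ddof = 1; a single observation yields NaN, not 0.
* The resampler is polyphase (`resample_poly`), preserving tone frequency
  and duration to within one sample.
* Entropy distance matrices are built from one pairwise difference matrix
  with shifted running maxima (no (n, n, m) intermediates); this is an
  exact rewrite of the definitions, verified against brute force at 1e-9.
* WAV I/O: PCM16 (peak-scaled) or float32; integer samples are scaled to
  [−1, 1] on read. Multi-channel or empty files are rejected by name.
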