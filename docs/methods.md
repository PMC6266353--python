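# Methods

## Pseudo-real session model

A session is the sum of three fully-controlled parts.

**Stimulus schedule.**  Trials spell one letter each from a 6×6 matrix
(A–Z, 0–9 row-major; the layout is a package convention, exposed as
`SpellerMatrix`).  A trial holds `n_sequences` sequences; each sequence
is an independent random permutation of the 12 stimulus ids (1–6 rows,
7–12 columns) with onsets spaced by the stimulus-onset asynchrony
(0.125 s flash + 0.125 s ISI → 4 Hz).  Defaults: 35 trials × 10
sequences, 20 s initial and inter-trial pauses.  Counting identities
follow directly: 120 intensifications per trial, 4200 per session, of
which 2 per sequence (700 per session) are targets.  Note that with 2
targets among 12 flashes the session contains 700 *target* and 3500
*non-target* marked sections — the oddball ratio, not its inverse.

**Background EEG.**  A 1/f-amplitude-shaped Gaussian process (pink
noise, default 8 µV RMS per channel) plus a 10 Hz alpha sinusoid with an
independent uniform random phase per channel (default 10 µV amplitude),
giving excursions of roughly ±30 µV.  This reproduces the gross EEG
amplitude spectrum and the dominant posterior rhythm but none of the
stimulus-locked structure, artifacts, non-stationarity or inter-channel
correlation of recorded EEG; it stands in for sessions recorded from
viewers who attend no letter.  Passing tests therefore demonstrate
correct recovery under a stationary, Gaussian, ERP-free background — not
robustness to real artifacts or null-signals.

**ERP templates.**  A pool (default 70: two per trial of a 35-trial
session) of 1-s multichannel waveforms: a positive P3b bump (Gaussian,
peak 0.35 s, σ ≈ 0.09 s, 9 µV at the strongest site) preceded by a small
N2 negativity (0.20 s, −28 % of the peak), scaled by a parieto-central
topography (Pz = 1.0, Cz = 0.9, Fz = 0.55, …).  Per-template jitter of
peak latency (±15 ms SD), width (±10 %) and amplitude (±15 %) emulates
the variability of templates extracted from real averages.  At every
target event one pool member is drawn uniformly and added point-to-point
to the 1-s window at the stimulus onset; superposition is exactly
additive.

**Noise regimes.**  Experiment 2 lags each *injection* (never the
marker) by an independent draw from U(latency_low, latency_high),
default U(0, 0.4) s — degrading exactly the time-locking that ensemble
averaging exploits.  Experiment 3 subtracts `gain × gaussian_window ×`
the template restricted to the P3b window (148–996 ms after onset), with
`gain ~ U(0, 1)`.  The taper spans the window support with standard
deviation `support/6` (configurable via `gauss_window_shape`), so it is
≈0 at the edges and introduces no discontinuity; the source protocol
specifies the window's support but not its width, and `support/6` is the
conventional choice that confines the taper to its support.

**Randomness.**  One session-level seed; every sub-process (schedule,
background, pool, target letters, superposition) draws from an
independent spawned substream, so sessions are bit-reproducible and
changing one stage's consumption never perturbs another.

The *passive*/*active* modality distinction of the original protocol
(foreign vs own-subject templates) collapses under a synthetic pool; the
flag is retained as provenance metadata only.

## Preprocessing

4th-order Butterworth band-pass 0.1–10 Hz plus a 50 Hz notch (Q = 30),
both applied forward–backward so waveform latencies are not shifted —
every downstream feature is latency-sensitive.  The filter padding is
even-symmetric and spans three high-pass time constants; with the very
low 0.1 Hz corner the default short padding lets edge transients ring
across tens of seconds.  Downsampling 250 → 16 Hz uses polyphase
rational resampling (up 8 / down 125), which is alias-free and
bit-reproducible; stimulus onsets live in seconds and are snapped to the
nearest sample at segmentation time, never interpolated.  Segments are
`[onset, onset + 1 s)`; a segment is rejected when any channel's
peak-to-peak range exceeds 70 µV (interpreted as the per-channel range
within the window; configurable).  Ensemble averaging takes the
arithmetic mean of the first `n` same-stimulus segments of a trial.

## Feature extractors

Defaults chosen for 16-sample segments (1 s at 16 Hz); all extractors
are deterministic.

* **Matching pursuit** — stopping rule: 5 atoms (configurable; a
  residual threshold is also supported).  Weights use the plain inner
  product, valid because every dictionary is unit-normalized on
  construction.  Each residual is orthogonal to its selected atom, so
  `‖x‖² = Σw² + ε²` holds to numerical precision and the residual norm
  is non-increasing.  The MP2 dictionary holds symlet-2 detail atoms of
  every level whose support fits the segment, translated on the dyadic
  grid (step `2^level`) strictly inside the segment, plus the coarsest
  scaling atom; for N = 16 this gives 11 atoms.
* **Permutation entropy** — order m = 3, lag τ = 1, window W = 8 (half
  the segment); natural log; ties ranked earlier-index-first (standard
  Bandt–Pompe practice).  The sliding feature has length
  `N − (W + τ(m−1))`, the source formula kept verbatim even though it is
  one window short of the usual count.
* **SHCC** — G = 32 grid points by default; since G must be below the
  segment length, the pipeline clamps G to N − 1 for 16-sample segments
  (giving 14 slopes).  The printed resampling index arithmetic of the
  original description is self-referential; uniform linear-interpolation
  resampling onto G grid points (endpoints included) implements its
  evident intent.  Constant segments are rejected by the operator —
  min–max normalization is undefined — and excluded from classification
  candidacy (a flat trace carries no waveform).
* **Plot + SIFT** — magnification δ = 4 (image 64 px wide for 16-sample
  segments; δ is not specified by the source and 4 gives Bresenham lines
  room to express slope).  Image height is the ceiling of the normalized
  peak-to-peak amplitude; the zero line sits mid-range.  The descriptor
  is computed on the `min(w, h)`-sided square patch at the image center
  (no keypoint detection, no scale space, fixed upright orientation),
  after Gaussian smoothing with σ = 1 px; 4×4 blocks × 8 orientation
  bins weighted by gradient magnitude; L2-normalize → clamp at 0.2 →
  re-normalize, with the all-zero-gradient patch mapping to the zero
  vector.

## Classification

Per channel, the dictionary holds the featurized averaged target row and
column segments of each training trial (15 trials → 30 templates).  The
k-NN rule (k = 3 by default; the source states no k) sums the distances
to the k nearest templates per candidate class and takes the argmin,
ties to the lowest class id for reproducibility.  MP1 ranks candidate
classes by the matching-pursuit residual of the *unit-normalized*
candidate against the signal-template dictionary: the raw residual
scales with segment energy, and the ERP itself adds energy to the target
class, so an unnormalized argmin rewards flat non-target averages rather
than matching shape.  Normalizing the candidate (consistent with the
normalized atoms) makes the score a pure shape mismatch.  The SVM
control trains a linear maximum-margin target/non-target classifier on
z-scored averaged segments and selects the candidate with the highest
decision score per axis.  There is no multichannel fusion; accuracy is
reported channel by channel.

## Benchmarking

Cross-validation scrambles the trial order (each trial's internal
sequence structure is preserved), builds dictionaries from the first 15
trials and tests on the remaining 20, for each requested number of
sequences entering the average; accuracies are means over repeats (100
in full runs; the test suite and acceptance script use 1–20 repeats,
which the feature cache makes cheap because averaged segments and their
features are split-independent).  A letter counts as correct only when
both row and column are correct.  The optional competition runner
replays the identical pipeline on externally supplied matrix-speller
recordings (240 Hz, 15 sequences, 42 training / 31 test letters),
remapping the competition's stimulus-code convention (1–6 = columns) and
its character layout onto the package's; it never downloads data, and a
synthetic stand-in generator in the same file layout exercises the path
offline.

## Numerical and degenerate-input choices

Filters: zero-phase, even padding (above).  MP stops early when the
correlation is exactly zero.  PE defines `0·log(1/0) = 0`.  Plot
rendering clips rounded rows into the image.  Degenerate inputs
(constant segments for SHCC/SIFT/raw, zero-norm templates, empty
dictionaries, G ≥ N, out-of-matrix letters, band edges at or above
Nyquist, upsampling requests) raise `ValueError` at the operator level;
the classification pipeline excludes flat candidate segments for every
method rather than erroring, which also makes noiseless sessions decode
perfectly.

## Problem sizes

The default study conditions are 35 trials × 10 sequences × 8 channels
at 250 Hz.  The test suite and acceptance script exercise the full
35-trial session at 4 channels and smaller 6–12-trial sessions at 1–2
channels with 1–20 cross-validation repeats — sizes chosen to keep the
suite quick while leaving every counting identity and statistical effect
(averaging gain, latency-noise degradation, chance-level nulls)
measurable.

## Known limitations

* The background model is stationary and channel-independent; no ocular
  or muscle artifacts, so the 70 µV rejection path is exercised only by
  synthetic spikes.
* Synthetic templates share one canonical shape family; real P300
  latency and topography vary more across subjects, so absolute
  accuracies here exceed what mixed-subject recordings give.
* Single-channel decoding only; no multichannel fusion.
* The competition runner expects recordings already converted to the
  documented MATLAB key layout and evaluates at the recording's full
  sequence count only.
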