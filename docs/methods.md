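# Methods

## Problem and scope

`megdecode` reconstructs and classifies auditory stimuli — spoken words and
environmental sounds — from trial-averaged (evoked) MEG responses. Two linear
decoding models embody two hypotheses about cortical encoding:

* the **convolution (lagged) decoder** assumes the neural response follows
  the stimulus in time: each time-varying stimulus feature `s_f(t)` (a
  spectrogram band, the amplitude envelope, a phoneme indicator) is
  reconstructed from response samples in a lag window after `t`,
  `ŝ_f(t) = Σ_x Σ_τ g_f(τ, x) r(t + τ, x)` with lags `τ ∈ [lag_min,
  lag_max]` enumerated on the 10-ms grid;
* the **regression (static) decoder** assumes no time-locking: each
  non-time-varying feature (an FFT bin, an MPS cell, a semantic entry) is
  reconstructed from the whole response window,
  `ŝ_f = Σ_x Σ_t w_f(t, x) r(t, x)`.

Comparing the two on the same data asks whether time-locked encoding carries
information beyond time-averaged summaries.

## Stimulus representations

Audio is low-pass filtered at 8 kHz (Blackman–Harris FIR), resampled to
16 kHz and RMS-normalized (default target 0.05 full-scale; the absolute
level is arbitrary, only equality across items matters). All spectral
representations share one filter bank: 128 raised-cosine band-pass filters
with centers log-spaced from 180 to 7246 Hz, each spanning one inter-center
spacing to either side on the log-frequency axis. This is a deliberate
approximation of a cochlear filter bank: band count, center spacing, frame
geometry and band selectivity are contractual; exact transfer functions are
not.

* **FFT spectrum** — whole-sound power in the 128 bands.
* **Auditory spectrogram** — band magnitudes in 10-ms frames integrated over
  16-ms Hann windows (frame `t` covers `[10t, 10t+16)` ms); a sound of
  duration `d` ms has `floor(d / 10)` frames.
* **Amplitude envelope** — the across-band mean of the spectrogram.
* **Modulation power spectrum (MPS)** — the log-compressed, mean-removed
  spectrogram is 2-D Fourier transformed over (log-frequency, time);
  Gaussian transfer functions select 4 spectral scales (0.5, 1, 2, 4
  cycles/octave) × 4 temporal rates (1, 3, 9, 27 Hz), separately for upward
  and downward ripples; filtered magnitudes are averaged over time and the
  two directions, leaving 128 × 4 × 4 = 2048 values. Gaussian half-widths
  grow as the square root of the channel center (0.4·√scale, 0.8·√rate), so
  channels stay selective while an unmodulated input loads the slowest rate
  channel most. Log-compression before filtering is the default and is
  configurable.
* **Phoneme tracks** — binary phoneme × frame matrices from time-aligned
  segmentations; a frame is assigned the phoneme whose half-open interval
  `[start, end)` covers the frame midpoint (deterministic and
  boundary-stable). Phonemes with fewer than 10 instances corpus-wide are
  dropped; the retained inventory is ordered alphabetically. Filtered-out
  phonemes leave all-zero columns, preserving the timing of retained ones.
* **Complexity measures** — per-frame spectral flatness (geometric /
  arithmetic mean, with a 1e-12 floor before the log); the spectral
  structure index is the population SD of the per-frame flatness series
  (variance available via `statistic="var"`), silent frames skipped with a
  logged count.
* **Semantic vectors** — concatenation of questionnaire scores (Q = 99) and
  corpus-embedding coordinates (D = 300); these are inputs (or synthetic),
  never trained here.

## Evoked-response contract

The pipeline order is fixed: average trials (rejecting any trial whose
absolute amplitude exceeds 3000 units), baseline-correct to the 300-ms
prestimulus window, anti-alias and decimate to the 10-ms grid, and — inside
each training fold only — z-score every (channel, time-bin) cell across
items with population-SD convention. Held-out items are transformed with
training-fold statistics; a flag-free design choice that makes leakage
impossible by construction. Zero-variance cells map to 0. Whole-set
standardization is available by fitting the scaler on all items, but
per-fold is the default.

Feature standardization mirrors this: FFT and spectrogram per band (frames
pooled across items), MPS per (band, scale, rate) cell, semantic entries per
entry; phoneme tracks are categorical and pass through untouched.

## Ridge machinery

Both decoders are ridge regressions solved through one SVD of the design
matrix, which makes the primal weights, the dual (Gram-form) coefficients,
fitted values and closed-form leave-one-out errors all cheap across a
regularization grid. The public `kernel_ridge_solve` implements the dual
form literally — `α = (R Rᵀ + λI)⁻¹ S`, weights `Rᵀα` — with a condition
-number warning and trace-scaled jitter (1e-10) for badly conditioned Gram
matrices (the condition check is skipped above 512 rows, where forming it
would dominate runtime).

Per decoded feature `f`, `λ_f` is selected from a grid (default 10 points,
log-spaced 1e-3…1e6) by minimizing closed-form leave-one-out error within
the training data; ties resolve to the smallest λ. For the convolution
decoder the leave-one-out unit is one stimulus — all its frames leave
jointly, via the block identity `e_I = (I − H_II)⁻¹ (y_I − ŷ_I)` — because
frames within an item are strongly dependent and row-level LOO would be
optimistic. A shared-λ fast path is available.

Numerical choices: systems above 512 rows evaluate LOO errors in single
precision — the quantity only ranks λ candidates spaced decades apart —
while small systems keep the identity exact to double precision (verified
against explicit refits at 1e-8). Trained decoders store weights factored
as `basis @ coef` (right singular vectors × spectral coefficients), so
high-dimensional regression designs never materialize a full weight matrix
unless `weights` is asked for.

## Evaluation

**Leave-two-out pairwise classification.** For each admissible pair, the
decoder and both scalers are re-fit on the remaining items; the two held-out
items are reconstructed, time-varying features truncated to the shorter
item, and the pair scored 1 if
`sim(s1,p1) + sim(s2,p2) > sim(s1,p2) + sim(s2,p1)` (Pearson correlation on
flattened features), 0 if reversed, 0.5 on an exact tie (unbiased under
label exchange). Similarity is computed on the standardized feature scale —
the scale the decoder is trained on. Pairs with undefined correlations are
skipped and counted; accuracy is the mean outcome over evaluated pairs.
Item-level schemes enumerate all `C(n,2)` pairs; category-level schemes
constrain pairs to different categories and optionally the same speaker.

**Reconstruction fidelity** is leave-one-out: train on n−1 items,
reconstruct the held-out item, report the Pearson correlation with its true
(standardized, flattened) features.

**Sweeps.** The lag sweep evaluates the convolution decoder per lag window
(default: 0–420 overview; 20–100 … 340–420 in 80-ms steps, windows
inclusive of both endpoints so adjacent windows share one boundary lag; and
the backward −80–0 control). The time-window sweep evaluates the regression
decoder in twenty 50-ms windows over 0–1000 ms.

**Inference.** Permutation tests shuffle which response belongs to which
item and re-run the entire evaluation (λ re-selected per permutation — an
honest null); `p = (1 + #{null ≥ observed}) / (1 + n_perm)`, defaults 200
(convolution) / 1000 (regression). A pooled variant draws one dataset at
random per permutation run. P values across datasets combine with Fisher's
method (χ² = −2Σln p on 2k df; zeros must be clamped explicitly, e.g. to
1/(n_perm+1)); time courses are corrected with Benjamini–Hochberg FDR at
α = 0.01 (via statsmodels). Model comparisons use a two-sided Wilcoxon
signed-rank test: zero differences dropped, average ranks for ties, exact
sign-flip enumeration (a rank-permutation null, valid under ties) for
n ≤ 25 and the tie-corrected normal approximation beyond; the Z statistic
is always reported.

## Synthetic experiments

The generator emulates the study's structure: 44 items per sound class, 6
semantic categories (6–8 items each), words spoken by 8 speakers with at
most one word per (speaker, category) cell; durations from truncated
normals — words N(810, 180²) ms, environmental sounds N(920, 230²) ms, both
clipped to [300, 1500] ms.

* **Word-like audio**: concatenated 50–150-ms harmonic segments (phoneme
  proxies with formant-pair spectral envelopes, prototype-dependent noise
  fraction and per-segment intensity varying over [0.4, 1]) under a
  quasi-rhythmic 3–5-Hz syllabic envelope — raised-cosine bumps at jittered
  intervals with independent per-syllable amplitudes, rhythmic but not
  periodic, like natural speech — with per-speaker base pitch
  (100 + 15·speaker Hz). Segment boundaries and prototype labels are
  drawn first from a pool guaranteeing ≥ 10 instances per prototype when
  feasible, so the phoneme-frequency filter retains the full 15-symbol
  inventory at study scale; annotations reuse the exact synthesis
  boundaries.
* **Environmental-sound-like audio**: filtered-noise textures with a
  category-specific stationary spectrum (mixture of log-frequency
  Gaussians) and weak 1–2.5-Hz amplitude modulation.
* **Semantic vectors**: category centroids iid N(0, between_sd²) plus item
  noise N(0, within_sd²); defaults 1.0 / 0.2 give clearly separable
  categories.

**Encoding regimes.** Epochs span −300…2000 ms at 10 ms.

* `time_locked`: a causal TRF maps the (band-standardized) spectrogram to
  the response at lags inside the support (default 100–180 ms): per-channel
  Gaussian latency profiles (SD 25 ms, centers drawn inside the support)
  times band-smooth random amplitudes, mixed (50/50 in response RMS by
  default) with an overall-intensity component — a per-channel gain on the
  stimulus envelope with the same latency profile — since auditory evoked
  responses track stimulus amplitude, the strongest tracking phenomenon in
  this paradigm. Features first pass through a causal
  exponential-moving-average adaptation stage (τ = 200 ms), so the response
  tracks change around the running stimulus level, as adapting auditory
  cortex does. Prestimulus activity is exactly zero without noise.
* `time_averaged`: a canonical evoked waveform (gamma-like transient
  peaking at 100 ms plus a sustained plateau decaying after ~900 ms) is
  scaled per channel by a static readout of the item's standardized MPS —
  its leading principal-component scores. The readout is deterministic
  given the stimulus set, which keeps the regime's decodability stable
  across simulation seeds; items with identical MPS (e.g. time-reversed
  spectrograms) produce identical noiseless responses.

Noiseless responses are jointly scaled to unit RMS, then iid Gaussian
sensor noise of SD `noise_sd` is added, making `noise_sd` a noise-to-signal
ratio. The default `noise_sd = 12` was set by the prescribed calibration:
the value at which MPS-regression leave-two-out accuracy under the
time-averaged regime is closest to 0.70 at the 24-item / 10-channel
evaluation scale (grid scan over {10, 12, 14, 16} × 6 seeds). Temporally
correlated noise is not modeled; neither are head geometry, leadfields or
inter-channel covariance — passing tests show the pipeline recovers planted
structure under these idealized conditions, not that real MEG attains any
particular accuracy.

**What the contrast shows.** Under `time_locked`, the convolution decoder
at the matched 100–180-ms window beats MPS-regression by 30–70 accuracy
points; under `time_averaged` that advantage vanishes (on average the
convolution decoder falls somewhat below MPS-regression, mirroring the
reversal the static code implies). The dissociation is evaluated at the
matched lag window — the window a lag sweep identifies as optimal — and
with the convolution decoder on a 4-point λ grid (1…1e6) for runtime;
regression keeps the full default grid (checked insensitive to the
difference).

## Problem sizes

Test-suite and acceptance-script analyses are scaled to desk hardware as
the package's own evaluation sizes: the regime dissociation uses 24 items ×
10 channels × 10 seeds; lag-sweep recovery 12 items × 10 seeds; permutation
calibration 20 items × 50 permutations; the acceptance script 16 items.
Full-scale runs (44 items, 56+ channels, 200/1000 permutations) use the
same code paths through `SimulationConfig` and `ExperimentConfig`.

## Known limitations

* Per-(channel, time-bin) standardization across stimuli — the pipeline's
  normalization contract — applies a time-varying rescale to the responses
  that a single convolution kernel cannot absorb when item durations vary:
  cells covered by only a few long items have their waveforms flattened by
  the z-score. Pairwise classification is unaffected (it needs ranking, not
  waveform fidelity), but leave-one-out reconstruction fidelity of the
  envelope saturates near r ≈ 0.85 even on noiseless simulations (the same
  decoder reaches 0.97 on unstandardized responses). Real recordings are
  gentler: ongoing background activity keeps every cell's across-item SD
  bounded, so the degenerate flattening does not arise there.
* Pairwise classification of time-varying features admits a *static*
  information channel: a reconstruction that carries only the item's
  time-averaged band profile already separates spectrally distinctive
  items (an oracle classifying by profile alone is perfect on these
  stimuli). Reconstructions from any lag window — including the backward
  −80–0 control — inherit some of that profile information whenever the
  simulated SNR is high enough for lag-resolved decoding, so the backward
  window sits at ~0.6–0.75 here rather than exactly at chance. At real-data
  SNR this channel is weak (the original control sat at 55%); the planted
  -lag *peak* at the true TRF support is the robust causal signature.
* The cochlear front-end and modulation filters are principled
  approximations, not a bit-exact reproduction of any toolbox; absolute MPS
  values are not comparable across implementations.
* The convolution decoder is not optimized for categorical targets; phoneme
  tracks are decoded as continuous series and classified by correlation.
* Time-varying modulation features, audio resynthesis of reconstructions,
  source modeling and anatomical parcellation are out of scope; channel
  groups stand in for cortical parcels.
* The permutation-calibration band (mean of 50 nulls within ±2 points of
  chance) is a ~1.3-SE check at 20 items: null accuracies correlate through
  shared items, so their SD is ~0.11 regardless of decoder.
* Wilcoxon p values for n > 25 use the normal approximation without
  continuity correction.
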