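# Methods

## Task simulator

Stimuli are drawn uniformly from 8 alternatives; independently, with
probability 1/8, a trial's stimulus is overwritten with the stimulus *N*
positions back in the *presented* sequence (trials with fewer than *N*
predecessors skip the overwrite).  This reproduces the
76.56% / 23.44% = (7/8)² / 1−(7/8)² non-match/match split exactly in the
limit; the overwrite may target an already-forced trial, which the
implementation resolves by propagating the most recent unforced draw
within each congruence lane mod *N* (an O(n) vectorized scan).  Whether
a forced match may land on a trial whose random draw already matched is
not observable from the printed probabilities; independence is assumed,
which is what the (7/8)·(7/8) product implies.

A default session is 3 modes × 3 levels × 1 block × 100 trials = 900
trials, levels ascending within mode, mode order counterbalanced by a
Latin-square rotation over participant index.  Task accuracy is
TP/(TP+FP+FN); with no matches and no responses the ratio is undefined
and returned as NaN rather than 0.  Note a finite-block subtlety: the
first *N* trials of a block can never match, so the respond-all policy's
expected accuracy is (n−N)/n × 23.4375%, fractionally below the
asymptotic ceiling.

Response and rating models are calibration conveniences, not ground
truth: per-level hit/false-alarm probabilities default to
0.97/0.85/0.65 and 0.01/0.04/0.10 (mirroring the qualitative
performance drop with load), and subjective ratings are discretized
clipped normals with level means 2.0/3.9/5.9 on the 1–7 scale.

## Epoch synthesizer

Each 3-s, 250-Hz epoch is, per channel, a sum over the six analysis
bands of one sinusoid at the band-centre frequency (snapped to the
nearest 250/512-Hz Welch bin centre) with a per-trial random phase,
plus broadband noise band-limited to 1–40 Hz (time-domain SD 0.3 by
default).  The sinusoid amplitude is calibrated through the mean-over-
bins band-power convention, A² / 2 = exp(g) · n_bins · Δf, so that the
*extracted* log band power approximates the controlled Gaussian draw
g ~ N(baseline + slope·N, noise_sd²).  Controlling the log makes effect
sizes additive through the pipeline's log transform, and the
calibration makes slope recovery through the Welch stage a real test
(the end-to-end regression slope of extracted log power on level
recovers the generating slope to within sampling error).

Default ground truth plants slope 0.35 (gamma) and 0.20 (beta) at ten
lateral/occipital sites of the 32-channel montage, with per-feature
trial-to-trial SD 0.25 and a small per-channel baseline jitter (SD
0.15) on 1/f-shaped per-band baselines.  Relevance rules may be
restricted to specific task modes, which is how the orthogonal
"mode-specific signature" condition for the cross-variant transfer
experiment is constructed.  What the synthesizer deliberately omits:
1/f continuum spectra, volume conduction / channel correlation, EMG and
ocular artifacts, nonstationarity within blocks.  Passing tests
therefore demonstrate the *pipeline's* correctness and the qualitative
behaviour of GP-ARD on band-power-like data — not reproduction of human
EEG results.

## Feature extraction

Welch PSD with Hamming windows of 500 samples, 250 overlap, 512-point
FFT, density scaling with window-power correction, one-sided doubling
(DC/Nyquist undoubled), no detrending; a 750-sample epoch yields
exactly two full segments (offsets 0 and 250).  Band power is the
*mean* of PSD bins whose centre frequency lies in the closed band
interval; bins between the gapped band edges (e.g. 3.4 Hz) belong to no
band.  Band powers are natural-log transformed; z-scoring uses training
rows only (population SD), zero-variance features are zeroed and
logged.  Feature order is channel-major and survives a bit-exact CSV
round-trip (`%.17g` writing, round-trip float parsing).

## GP regression core

Zero-mean GP, squared-exponential ARD kernel, Gaussian likelihood.
NLML = ½ yᵀ(K+σ_n²I)⁻¹y + ½ log|K+σ_n²I| + (n/2) log 2π with analytic
gradients w.r.t. (log ℓ_d, log σ_f², log σ_n²); the length-scale block
is computed as row/column sums of (K∘M) plus one dense product, O(n²d)
overall.  Optimization is deterministic L-BFGS-B in log space from
ℓ=10, σ_f²=1, σ_n²=1 with a budget of 100 objective evaluations
(`maxfun`; gradient evaluations are counted with their objective, and
line-search trials consume budget — the budget semantics are pinned
here rather than guessed from any external library's counting).  If the
optimizer fails to improve on the initial point, the initialization is
kept, so final NLML ≤ initial NLML always holds.  Proposals that
overflow or produce non-PD covariance evaluate to +∞ and are rejected
by the line search.

Numerics: Cholesky with escalating jitter (10⁻¹⁰ × mean diagonal, ×10
per retry, 3 retries, then a hard error); predictions always go
through the cached factor, never an explicit inverse; negative
predictive variances from round-off are clamped to 0 and logged.
Both the latent variance and the observation variance (+σ_n²) are
stored; plotted ±2σ intervals use the observation variance.

Feature-subset prediction slices the retained columns of the training
inputs and their trained length scales *without refitting* — the
operational scenario is a reduced montage at test time after full-cap
calibration — with `refit=True` exposing the alternative.

Recovery behaviour (measured by the test suite): with n = 300 samples
of a 5-feature GP prior draw (ℓ ∈ [1, 2], σ_f² = 1, σ_n² = 0.1),
trained log length scales land within 0.5 of truth in every dimension;
with 2 relevant of 8 features, the two shortest trained length scales
identify the planted pair in ≥ 18/20 seeds.

## Evaluation protocol

Blocked 5-fold CV: every block is split into 5 contiguous partitions
(earlier partitions absorb any remainder); fold *i* tests partition *i*
of every block; test trials within 5 within-block positions of any
training trial are removed from the test set only.  Buffer distance is
within-block index distance — blocks are separated by breaks, so trials
in different blocks are never buffered against each other.  For a clean
100-trial block this retains 15 test trials for edge partitions and 10
for interior ones, with 80 training trials per fold.  The plan is fully
deterministic, so it takes no seed.

sMSE divides by the *population* variance of the true test values; this
is the convention under which the constant-mean predictor scores
exactly 1.  Pooled metrics concatenate all folds' (truth, prediction)
pairs; per-fold metrics are reported alongside and their mean is close
to the pooled value on balanced folds.  Discretization rounds to the
nearest training label with ties to the smaller label.  Subjective-
label runs give every trial its block's single 1–7 rating.

The feature sweep retains ⌊p·F/100⌋ shortest-length-scale features per
fold (training-fold ranking only) for p = 1…100; percentages that floor
to zero features are skipped, and the 100% point equals the full model
by construction.  ANOVA-based selection for the ARD-vs-ANOVA comparison
is likewise computed on training folds only.  Montage subsets ship with
channel lists of 9/16/9/5 sites (54/96/54/30 features); the two
commercial-headset lists are approximate mappings of those devices onto
the laboratory montage (exact vendor montages differ in a few sites)
and are fully user-overridable.  The cross-variant matrix trains fold
*i* on one variant's training rows and tests on fold *i* retained test
rows of another, 3 × 3 cells of pooled sMSE.

## Problem sizes and defaults in the test suite

The suite exercises the full pipeline at 6 channels (36 features),
60-trial blocks (540 trials/session) and the stock GP budget — sizes
chosen so planted effects (slope 0.35, noise SD 0.25) are comfortably
detectable while a full run stays fast; the stimulus-model checks use
10⁶ trials.  At full scale (32 channels, 900 trials) a two-method
pipeline run takes on the order of minutes per participant.

## Known limitations

- Exact GPR is O(n³)/O(n²d); no sparse approximation is provided.
- The synthesizer's narrowband-plus-noise signal model has no
  between-feature correlation beyond shared level dependence, so
  collinearity-driven phenomena (e.g. large ANOVA-vs-ARD efficiency
  gaps) are milder here than in real EEG.
- Only the squared-exponential ARD kernel and Gaussian likelihood are
  implemented.
- Null-data sMSE concentrates near, but can fluctuate around, 1 (the
  GP may fit small spurious structure in a finite sample).
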