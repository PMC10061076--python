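# Methods

`ecoglearn` studies how the size and recency of the training set affect
decoders that reconstruct intended 3D hand-translation directions from
electrocorticography (ECoG) during motor imagery. Because clinical ECoG
studies of this kind are private, the package pairs the full analysis stack
with a synthetic study generator that plants every property the analysis
later tries to detect. This note describes the models, the generator, the
numerical choices and what the synthetic results do and do not show.

## Decoding problem and metric

Each analysis window is a tensor `X ∈ R^(channels × bands × steps)` of
band-power features and carries a label `y ∈ R³`, the unit vector from the
current hand position to the target. Decoders predict a direction `ŷ` and are
scored by cosine similarity, `CS = ŷ·y / (‖ŷ‖‖y‖)`: 1 for a perfect
direction, 0 for an orthogonal one, −1 for the opposite one. CS is
scale-invariant, so predictions are never normalized. The reported value of
an experiment is the unweighted mean CS over test epochs. Zero-norm
predictions are defined to score 0 (with a warning) so that training and
evaluation remain total functions.

## Feature extraction

Raw multichannel signal is convolved (FFT convolution) with complex Morlet
atoms placed exactly at the configured band centers (10–150 Hz in 10 Hz
steps at full scale). The atom at frequency `f` has Gaussian envelope
`σ_t = n_cycles/(2πf)` with `n_cycles = 7` by default — a common compromise
between time and frequency resolution; the analysis depends on band
*ranking*, not on exact magnitudes, so this parameter is deliberately
uncritical. Every 100 ms a 1 s window is cut, the modulus is averaged over
ten 100 ms fragments, and the label, state and gate flag are read at the
window end (causal alignment). Windows that would need samples beyond the
session are not emitted; windows whose hand and target coincide are dropped
rather than given a fabricated label. Features are moduli of complex
coefficients, hence non-negative, and scale linearly with the raw signal.

Connection-loss artifacts are detected as flatline runs (zero derivative on
any channel for ≥ 50 ms) or extreme amplitudes (beyond 8 robust standard
deviations from the channel median) and repaired by per-channel linear
interpolation in the raw-signal domain; segments touching a session boundary
hold the nearest valid value. Epochs whose gate prediction (which limb state
the online classifier believed) disagrees with the true state are removed,
mirroring how mismatched samples corrupt closed-loop data.

## Decoders

**Multilinear (REW-NPLS).** A tensor-input linear model trained pseudo-online
on 15 s chunks (150 epochs at the 0.1 s hop). The state consists of
exponentially weighted first and second moments of the flattened inputs and
outputs. After each chunk the model re-extracts up to `F_max` PLS factors
from the centred scatter matrices; each factor's input weight vector is
constrained to rank one across the tensor modes (`w = w₁⊗w₂⊗w₃`, found by
SVD-initialized alternating least squares on the cross-covariance tensor),
and both covariances are deflated by the factor's score direction. The
algebra is arranged so that, with forgetting factor λ = 1, the recursive
moment-domain fit is *exactly* the batch N-way PLS on the concatenated data;
the test suite verifies this against an independent data-domain
implementation to 1e-6. The number of factors used for prediction is chosen
by recursive validation: before a chunk is absorbed, every candidate factor
count is scored on that still-unseen chunk and the cumulative squared error
decides. λ defaults to 1 for offline experiments (every design here
retrains from scratch, so nothing old needs forgetting); `F_max` defaults to 20 at full scale and 5–10 in the
desk-scale experiments, where the moment matrices are (channels·bands·steps)²
and dominate memory. The prediction tensor has channels·bands·steps·3
entries — 28,800 at full scale — counted without the bias, matching the
convention used for model-capacity comparison.

**MLP.** Flatten (9,600 inputs at full scale) → two blocks of
affine–batch-norm–ReLU–dropout with 50 units each → affine to 3. 482,953
trainable parameters with affine batch-norm (2 per feature).

**CNN+LSTM with multiple trajectories (MT).** Each implant's channels are
arranged on its 8×4 electrode grid (row-major). A weight-shared conv stack
runs per implant and per time step: conv 3×3 (height-valid, width-preserving
padding) to 32 maps, ReLU, batch-norm, dropout; conv 3×3 (unpadded) to 64
maps, ReLU, dropout. Per-step features from the implants are concatenated
(2·64·4·2 = 1,024) and fed to two stacked LSTMs (hidden 50, then hidden 3),
whose second layer's hidden state *is* the output: a 3-vector per each of
the 10 window steps. Each LSTM carries separate input-hidden and
hidden-hidden bias vectors; with that convention the model has exactly
238,772 trainable parameters, which the suite asserts. Training maximizes
the per-step mean CS against the window label broadcast over steps; scalar
evaluation uses the final (most recent) step.

The deep decoders are trained with Adam (lr 0.001, L2 weight decay 0.01
added to the gradients of weights, not of batch-norm scales/shifts), batch
size 200, dropout 0.5, early stopping on the chronological last 10% of the
training data, best-validation weights restored. All randomness (init,
shuffling, dropout) flows from a single seed, so a training run is exactly
reproducible. The layers' backward passes are hand-derived and verified
against central differences in the test suite.

## Experiment designs

All designs operate on a chronologically ordered epoch collection with
session boundaries and report dataset size in minutes (epoch count × hop).
Train/test disjointness is asserted in every run.

- **Forward increase (FI):** train on sessions 0..k−1, test on the following
  `test_window` sessions (22 at full scale), k = 1..21.
- **Backward increase (BI):** train on the k sessions ending just before a
  fixed anchor (the 21st session at full scale), test on the fixed last 22
  sessions.
- **Random increase (RI):** sample epochs without replacement from the first
  22 sessions, test on the BI tail; each size repeated 10 times with
  distinct seeds.
- **Dataset translation:** slide a 6-session training window over the study,
  testing on the following 6 sessions (43 sessions → 32 steps); an OLS trend
  of CS against the window start separates data-shift effects from
  dataset-size effects.

Learning curves are fit to (size, CS) points as `CS(l) = a − b·l^(−c)` by
bounded Trust Region Reflective least squares (`a ∈ [−1,1]`, `b, c > 0`)
with multi-start over a coarse (b, c) grid, because the objective is
multimodal in those parameters; the best-SSE start wins and a brute-force
grid search provides an independent optimum check in the tests. `c` is
unit-sensitive, so the size unit (minutes) is recorded in the fit object.
Curves are fitted to repeat means by default. With positive `b` and `c` the
fitted curve is strictly increasing and `a` is the asymptotic performance.
A fit with `b` pinned at its lower bound is flagged degenerate (flat data).
Six-point extrapolation from a single noisy observation per size leaves the
asymptote estimate with a sampling error of roughly twice the per-point
noise; averaging the repeated evaluations the random-increase design
produces shrinks it by about the square root of the repeat count.

## Data-quality diagnostics

Every tenth epoch is flattened and embedded in 2D with UMAP (seeded;
neighbors 15, min-dist 0.1 — common defaults, recorded in the report). A
linear SVM (C = 1) is fit per session on that session's embedding
coordinates and its *training* accuracy is the state-separability indicator
(no cross-validation: the quantity of interest is cluster overlap, not
generalization); a linear trend over sessions summarizes drift.

Local intrinsic dimensionality uses the expected simplex skewness (ESS)
estimator on 100-point nearest-neighbor neighborhoods: vectors are taken
from the neighborhood centroid, and the mean sine of pairwise angles
weighted by the product of vector norms has, under isotropy in dimension n,
the closed-form expectation
`g(n) = exp(2·lnΓ(n/2) − lnΓ((n+1)/2) − lnΓ((n−1)/2))`, strictly increasing
in n; inverting g on the observed statistic gives a fractional dimension
estimate. Degenerate neighborhoods (duplicates collapsing all norms) are
skipped and flagged. Global ID uses TwoNN: with μ the ratio of second- to
first-nearest-neighbor distances, uniform sampling of a d-manifold gives
`F(μ) = 1 − μ^(−d)`; d is the origin-constrained slope of −log(1−F) against
log μ after discarding the largest 10% of ratios and deduplicating exact
repeats. Both estimators are calibrated in the suite on known manifolds
(5-D hypercube rotated into 50-D → mean ESS ID in [4, 6]; 2-D disk → TwoNN
in [1.8, 2.2]; 10-ball → [8.5, 11.5], reflecting TwoNN's known high-d
underestimation). Session IDs are averaged over each training window and
Pearson-correlated with decoder CS.

## Synthetic study generator

One session is built from three layers:

1. **Kinematics.** Targets appear at unit distance in uniformly random
   directions from the current hand position; the hand moves toward the
   target at constant speed with Gaussian angular jitter (10°). Uniform
   target directions make chance-level CS ≈ 0. Trial counts jitter by ±1
   around the per-session mean.
2. **Signal.** Each channel sums band-limited carriers (cosines at the band
   centers with random phases) whose amplitudes encode the planted
   structure: a baseline; cosine directional tuning `snr(s)·(p_c·d(t))·g_cf`
   with unit preferred directions `p_c` and per-band gains `g_cf`; a
   left/right state-pattern offset scaled by the separability schedule; and
   a diversity term — a smooth K(s)-dimensional mixture over pattern
   prototypes (low-passed unit-variance Gaussian processes, variance held
   constant across K) that spreads the session over a K-dimensional
   submanifold and is the monotone control knob for ESS local ID. Amplitudes
   are rectified at zero; 1/f background noise is added.
3. **Imperfections.** Gate predictions equal the true state except for
   100 ms blocks flipped at the session's error rate (default falling from
   8% to 2% across the study); 0–2 connection-loss events per session
   flatline all channels for 0.2–0.6 s and are recorded as ground truth.

Schedules (tuning gain, separability, diversity, gate error, artifact rate)
are arrays indexed by session; the defaults ramp so that later sessions are
"better" in every respect, emulating long-term co-adaptation. Per-session
seeds derive deterministically from the master seed, so studies are
bit-reproducible.

**Desk-scale preset.** The qualitative end-to-end analyses run on a reduced
study (`desk_scale_params`): 14 sessions of six 5 s trials, one 8×4 implant
(32 channels), six bands 10–60 Hz at 150 Hz sampling, tuning-gain ramp
0.3→1.8, separability ramp 0.1→1.6, background noise chosen so that desk-
scale decoding spans CS ≈ 0.1–0.94 rather than saturating at the metric
ceiling — the operating regime in which dataset-size effects are visible at
all. The experiment designs shrink proportionally (FI/BI to 6 training
sessions with 4-session test windows, translation window 3+3).

## What the synthetic results show — and what they do not

Passing the end-to-end suite shows that the *pipeline* behaves as the
analysis assumes: learning curves rise and saturate for all three decoder
families; training on recent sessions of an adapting study beats training on
early ones at equal size; a sliding training window yields a positive
performance trend; planted separability ramps appear in the embedding
diagnostics; and the ID estimators respond monotonically to the planted
diversity knob. None of this certifies biological realism: the generator has
no volume conduction, no electrode-level correlation structure, no
non-stationary noise, stationary cosine tuning, and kinematics that are a
stand-in (the virtual-environment geometry of a real study is not
reconstructed). Quantitative values from the synthetic study (absolute CS
levels, trend slopes) are properties of the chosen schedules, not
predictions about any patient.

## Numerical choices and degenerate inputs

- Rank-one ALS: SVD-derived deterministic initialization, sign fixed by the
  largest-magnitude entry, relative tolerance 1e-12, ≤ 500 iterations.
- PLS deflation stops early when the residual cross-covariance or score
  variance falls below 1e-14 of its original scale; constant inputs raise a
  degenerate-covariance error.
- Batch-norm uses ε = 1e-5 and momentum 0.1; evaluation uses running stats.
- Trend fits on constant responses return slope 0, R 0, p 1 by convention.
- Learning-curve bounds are enforced at 1e-9 above zero for b and c; a fit
  at the b bound is flagged rather than silently reported.
- Cosine similarity clips to [−1, 1] to absorb floating-point overshoot.

## Known limitations

- The recursive decoder stores a dense (channels·bands·steps)² scatter
  matrix: ~737 MB at the full 9,600-feature scale. Fine at desk scale;
  a memory-aware reformulation would be needed for full-scale online use.
- The numpy deep-learning stack is single-threaded BLAS-bound; it is sized
  for the desk-scale study, not for GPU-scale experiments.
- UMAP embeddings are seeded but not canonical: different UMAP versions may
  produce different (equally valid) embeddings; separability conclusions
  should be read per-run.
- ESS inversion saturates at n = 1e6; statistics at or above the isotropic
  limit map to that cap (never observed on real neighborhoods).
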