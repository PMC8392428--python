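# Methods

This note documents the models, numerical choices, and design decisions
behind `epitensor`, and what the synthetic experiments do and do not show.

## Pipeline model

**Band filter.** Band splitting is a brick-wall Fourier filter: FFT each
channel, zero every bin outside the band, inverse-transform. It has exactly
zero phase distortion and can only remove energy (Parseval), at the cost of
edge ringing; since the downstream quantities are windowed correlations
rather than waveforms, ringing is acceptable. Shared band edges are
assigned to the lower band (`[f_lo, f_hi)`, gamma closed at 60 Hz), so the
five bands partition 0.5–60 Hz without double counting; the DC bin is
excluded everywhere. Filtering is applied to the whole segment before
windowing.

**Networks.** Each 8-s window (4-s step) yields a Pearson correlation
matrix, binarized at `Th = 1 − (1 − α)^(1/(L−1))`. The edge rule thresholds
the correlation *magnitude* (`|r| > Th`) by default: strong negative
coupling is physiologically a connection. The literal signed rule
(`r > Th`) remains available as `binarize_rule="signed"`. Self-loops are
excluded (`a_ii = 0`), otherwise node degree would count every node as its
own neighbor. Zero-variance (flat) channels get correlation 0 with all
others — they become isolated nodes instead of raising, which is the robust
behavior on clinical EDF files with flat leads.

The parameter `L` counts disjoint window sections: a 45-min segment has 337
disjoint 8-s sections, which is the config default. Note that α = 0.95 and
L = 337 give Th ≈ 0.009, so nearly every correlation in real EEG exceeds
the threshold and the networks are close to complete; `L` is deliberately
configurable because the threshold's useful range depends on the
correlation scale of the data at hand (see the synthetic experiment below).

**CP decomposition.** The ALS core fits `X ≈ Σ_r λ_r a_r∘b_r∘c_r` by
cycling exact least-squares updates of A, B, C on the mode-n unfoldings
(Kolda convention, `X_(1) = A (C ⊙ B)ᵀ`). Because every sub-step is an
exact least-squares solve, the reconstruction error is non-increasing per
sweep — this is asserted in tests with 1e-12 slack for floating-point
noise. Details:

- initialization: entries uniform on [0, 1) from the run seed (nonnegative
  init suits binary tensors); one run per R (no restarts by default).
- convergence: stop when the relative error changes by < 1e-6, or after
  200 sweeps.
- error: computed in factor space
  (`‖X‖² − 2⟨X, X̂⟩ + ‖X̂‖²`), so no dense reconstruction per sweep.
- normalization: columns are scaled to unit norm at the end, norms absorbed
  into λ; exactly-zero columns keep λ_r = 0.
- rank search: R grows by 1 from 1 until the relative error is < 0.05;
  R_max = 100 guards termination (raises with the full error trace if
  exhausted). A zero tensor returns R = 1 with error 0 by convention.
- singular Gram matrices fall back to the pseudoinverse.

**Partially-fixed features.** With A and B frozen, the CP objective is
quadratic in C, so the "decomposition" of every subsequent tensor is one
linear solve of `X_(3) ≈ C (B ⊙ A)ᵀ`; no iteration. The unnormalized
solution equals `F = C_normalized·diag(λ)` directly, and the feature is its
column mean (length R). Rank deficiency of the Khatri–Rao product is
handled by the pseudoinverse and logged.

*Reference selection.* The factors to freeze come from one reference
tensor drawn from the training set. The default rule takes the first
tensor of the first **pre-ictal** training segment (catalog order), not
simply the first training tensor: the frozen channel basis must be rich
enough to represent both classes, and when inter-ictal coupling is weak
its networks can be nearly empty — the rank search then stops at a small R
and the degenerate basis loses the class signal (observed directly: R ≈ 7
from a near-empty reference versus R ≈ 20 from a pre-ictal one, with
ten-fold accuracy collapsing from ≈1.0 to ≈0.7). In the
leave-one-segment-out protocol the rule is applied per fold to that fold's
training segments only, so the held-out segment never influences its own
basis. `reference_rule="first"` restores the plain first-tensor rule and
`reference_index` pins an explicit choice.

**ELM.** Logistic sigmoid activation (the standard choice), M = 100 hidden
neurons by default, input weights uniform on [−1, 1], biases on [0, 1];
features are standardized with training-fold statistics only. Output
weights use the ridge normal equations with the M ≤ N / M > N branches
(equal by the push-through identity, asserted to 1e-8). The ridge
parameter is selected from a grid (2⁻¹⁰…2¹⁰, powers of 4) by the PRESS
statistic — exact leave-one-out residuals `(y_i − ŷ_i)/(1 − HAT_ii)` from
the hat-matrix diagonal, pooled over both one-hot outputs; candidates with
leverage ≈ 1 are skipped. Ties take the smaller E. Prediction is the
argmax of the two network outputs, ties toward inter-ictal.

**Alarm and evaluation.** The alarm counter increments on label 2, resets
on label 1, and triggers at 30 consecutive detections (configurable). For
tensor features the stream advances one tensor per step, so the step
seconds are `stride × step_s` (12 s at num = 3); for per-window baseline
features the step is 4 s. Prediction time `T = s·(n+1)` reads `n` as the
number of stream positions *remaining* at the alert (the other reading —
positions before the trigger — is noted but not implemented). Mean
prediction time averages over correctly predicted pre-ictal segments only.
Ten-fold cross-validation is stratified and **segment-grouped**: all rows
of one recording stay on one side of every split. Plain row-level folds
would let the classifier recognize the held-out row's source segment from
its training-set siblings — with per-segment coupling structure that
recognition is equivalent to knowing the label, and even a label-free null
would score far above chance. Grouping makes the protocol a test of
generalization to unseen recordings.

## Synthetic data

Each segment is `x_c(t) = κ(t) Σ_s m[c,s]·source_s(t) + σ·η_c(t)`:
five unit-variance latent oscillators (sinusoid at 2, 6, 11, 22, 45 Hz
plus narrowband noise, one per canonical band), mixed into 23 channels.
Mixing rows are nonnegative and near-uniform (1 + 0.3·N(0,1), clipped at
0.1, row-normalized): coupling is broad rather than a per-segment lottery
of channel subsets, and with unit rows the shared-signal variance per
channel is exactly κ², so `coupling_strength` has the same meaning in
every segment. κ(t) drifts linearly when `drift_rate ≠ 0` (clipped to
[0, 1]). Channel noise is white with σ = 0.5 by default. Amplitudes are
scaled to ±100 µV before EDF writing so 16-bit quantization behaves as for
real scalp EEG.

The canonical experiments (module `epitensor.experiments`) use 8 + 8
segments of 10 min each — enough windows (149) for 49 tensors per segment
at num = 3 while keeping a full run in tens of seconds on one CPU:

- **separable**: inter-ictal κ = 0.2 stationary vs pre-ictal κ = 0.8 with
  drift −5·10⁻⁴/s (0.8 → 0.5 over the segment), gamma band, num = 3.
- **null**: the same catalog with the class difference removed (both
  classes from the inter-ictal spec).

The experiment threshold uses L = 6 (Th ≈ 0.451), placed mid-scale
relative to the generator's correlation distribution: strongly coupled
pairs (κ ≈ 0.8, gamma-band noise floor σ²_γ ≈ 0.06) reach r ≈ 0.7, weakly
coupled pairs stay near 0.1, so pre-ictal networks are dense and
inter-ictal networks sparse-to-empty. The literal L = 337 would put
Th ≈ 0.009 below the correlation noise floor and make both classes nearly
complete graphs.

Under the null, grouped cross-validation is systematically *below* 0.5:
holding out a class-1 segment leaves class 2 overrepresented in training,
and with no signal the classifier leans to the training majority — the
opposite class of the held-out segment. This leave-cluster-out imbalance
bias is a property of the protocol, not leakage (leakage shows up as
accuracy *above* chance); chance bands for the null should use the number
of segments, the independent units, not the number of feature rows.

**What the synthetic study does not show.** The generator has no spikes,
artifacts, channel dropouts, volume-conduction structure, or realistic
1/f spectra; classes differ by a single global coupling parameter, which
is far cleaner than pre-ictal physiology. Passing the synthetic
experiments demonstrates that the pipeline recovers a designed coupling
difference end-to-end — not that it attains any particular performance on
clinical recordings.

## Degenerate inputs and conventions

- zero tensor: relative error 0 by convention, rank search returns R = 1,
  features are exactly zero.
- flat channels: isolated nodes (correlation 0), logged.
- clustering coefficient: C_i = 0 when k_i ≤ 1 (the formula divides by
  zero there).
- catalog records that cannot supply the configured 23-name channel list
  are skipped with a warning, keeping all matrices 23×23.
- EDF writing requires whole seconds at an integer rate (one-second data
  records); physical ranges are per-channel min/max, so the quantization
  step is (max−min)/65535.

## Known limitations

- The frozen-factor basis is a random-restart ALS solution of one tensor;
  features are only comparable within one reference fit (train and predict
  must share it, which the pipeline enforces per fold).
- The rank search refits ALS from scratch at every R; no warm starting.
- Leave-one-segment-out refits the reference per fold, so feature
  dimension R can differ across folds (each fold trains its own
  classifier, so this is consistent, but fold metrics are not
  feature-space-comparable).
- Binary networks only; no weighted variants downstream of binarization.
- The ten-fold protocol needs at least `n_splits` segments (groups); small
  catalogs reduce the fold count.
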