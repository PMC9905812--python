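# Methods

`hemocae` predicts a patient's post-treatment thrombin-generation curve
`y` from the pre-treatment curve `x` and a normalized drug dose `c`, and
provides the optimization machinery that makes small conditional
autoencoders trainable and deep ones initializable on limited clinical
data. This note documents the models, the training procedures, the
synthetic data generator, and the numerical choices, in that order.

## Models and cost functions

All models are dense sigmoid networks over curves normalized to [0, 1]
(the data are normalized concentrations, so a bounded output activation is
the natural choice; activations were an open design point and sigmoid is
used everywhere, with linear layers available for tests and fixtures).

* **AE** — encoder/decoder pair reconstructing its input through a code
  `h`. Cost: `J = MSE(r, x) + λ Σ|h_i|`, the L1 term encouraging sparse
  codes.
* **CAE** — conditional autoencoder answering `p(y | x, c)`. The code is
  a function of `x` alone — architecturally, the dose enters only the
  supervised head, concatenated to the code — so `h` is exactly
  `p_encoder(h | x)` and the reconstruction path is dose-independent.
  Hybrid cost: `J = MSE(r, x) + MSE(ŷ, y) + λ Σ|h_i|`; the unregularized
  variant drops the λ-term.
* **DCAE** — x-encoder stack to `h_x`, mirrored x-decoder, conditional
  link `(h_x, c) → h_y`, y-decoder stack to the prediction. A simple CAE
  is the depth-1 member of this family (empty y-decoder, the link maps
  straight to the output).

NRMSE — root-mean-square error divided by the range of the reference
vector — is the reported error metric throughout; for batches the per-row
NRMSE is averaged, each row normalized by its own range. NRMSE is
invariant to common shifts and positive common rescalings of reference
and prediction.

## Per-unit learning rates (ALRAO) and the SGD loop

Every unit (hidden and output) draws its own learning rate log-uniformly
between two bounds; the rate applies to the unit's incoming weights and
bias. This removes the global learning rate from the tuning burden — only
the two bounds remain, and the incremental optimizer selects even those by
a grid search. The original ALRAO recipe's output-layer model averaging
(parallel output copies) is not implemented; output units are treated
like hidden units. Training is plain mini-batch SGD (batch 32) with early
stopping on a validation score (default: the cost itself, NRMSE for
fine-tuning) and best-snapshot return; a non-finite loss raises a
divergence error naming the epoch.

**Learning-rate scale.** The reconstruction and supervised terms are MSE
values *averaged over curve dimensions* (180 points at full scale). The
gradients are therefore ~d times smaller than with summed errors, and the
useful per-unit rate range sits around 1–30 rather than the 1e-4–1e-1
range familiar from sum-of-squares conventions. The default grid for the
bound search spans order-of-magnitude pairs `(10^a, 10^b)`, `a < b` in
{−2 … 1}; measured on the latent-factor recovery task, rates ≤ 0.1 cannot
reach the documented recovery accuracy in any reasonable epoch budget,
while bounds of (1, 10) solve it in a few hundred epochs.

## Conditional pre-training

Deep conditional models are initialized in three steps:

1. **Parallel pre-training.** The x-side and y-side stacks are trained
   greedily, one sparse single-hidden-layer AE per level, each
   reconstructing the previous level's codes. The two sides share no
   randomness, so their results are independent of execution order. For
   the y-side only the decoder parameters are exported into the final
   model; the y-encoders are kept solely to produce `h_y` code targets.
2. **Supervised conditional link.** A CAE answering
   `p(h_y | h_{x,n-1}, c)`: its hidden layer is the top code `h_x`, its
   decoder starts as a copy of the reconstruction parameters learned in
   step 1 (keeping the gradient chain into the x-stack intact; the copy
   remains trainable — an open point resolved in favor of adaptability),
   and its encoder and head start Glorot-random. Trained on the hybrid
   cost.
3. **Copy + joint fine-tuning.** All parameters are copied into one DCAE
   — the assembled forward pass equals the block-wise composition exactly,
   which the tests assert at machine precision — and fine-tuned jointly on
   the *unregularized* cost. The sparsity penalty is kept during steps 1–2
   only: pre-training itself acts as the regularizer, so the λ-term is
   dropped from the joint objective.

Equal epoch budgets are used across the three steps (an open design point;
there is no evidence for asymmetric budgets at this scale).

## Incremental width optimization

A single AE/CAE is optimized jointly in parameters and width:

* **Initialization** starts overcomplete (width ≥ input dimension). Each
  candidate pair of rate bounds gets a freshly initialized model and a
  short training run; the winner's model is kept and its training
  *completed* on the full base with early stopping (the grid run is part
  of initialization, not discarded).
* **Growth** adds at most one unit per iteration, trained for one epoch on
  the poorly discriminated subset `B` — samples whose cost strictly
  exceeds the mean cost (strict, so a perfectly uniform loss yields no
  growth) — with all other parameters frozen and a freshly sampled rate.
  The trigger: the mean cost on `B` improved by < 1% over the last
  `window` (12) iterations *and* validation improved within that window.
  Stagnation is only judged on iterations since the last structural
  change, since a fresh unit needs a full window before its effect is
  measurable.
* **Pruning** fires when validation rises for several consecutive
  iterations while training still falls. Per-unit activation degrees
  (mean |h| over the validation set) are clustered by affinity
  propagation (damping 0.7, preference = median similarity; duplicate
  degrees are deduplicated before message passing, which otherwise
  oscillates on ties); the cluster whose exemplar has the lowest degree is
  deleted, with 1 ≤ ΔM ≤ L−1 enforced by sparing the strongest unit. The
  deletion is reverted bitwise if validation degrades.
* Growth and pruning are mutually exclusive within an iteration, and the
  loop early-stops on validation patience, returning the best snapshot.

For conditional models the stopping criterion and `B` use the hybrid
cost, while over/underfit detection uses the unsupervised reconstruction
task only (the code is dose-independent, so reconstruction is the
capacity signal).

## Incremental depth optimization

Depth grows greedily, evaluating each candidate as a whole model:

* **Unsupervised (deep AEs).** Incremental AE on the data; then per
  iteration: incremental AE on the current codes, unfold all layers into
  one deep AE, fine-tune jointly, accept only on strict validation
  improvement; first rejection restores the saved model and stops.
* **Conditional (DCAEs).** Phase 0 is a simple incremental CAE. The
  x-phase deepens the x-side: an incremental AE learns a deeper code of
  `p(x)`; an incremental CAE *warm-started from that AE* (its encoder and
  decoder and their rates carried over, head fresh) re-links `(h_x, c)`
  to the output; the blocks are unfolded into a DCAE and fine-tuned
  jointly; acceptance is strict improvement of validation prediction
  NRMSE. The y-phase then deepens the y-side: a new incremental AE on the
  current `h_y` codes supplies the deeper code (its decoder joins the
  y-side stack, its encoder only produces code targets), and the link
  layer is retrained to map `(h_x, c)` to the new code. Every rejection
  restores the previous DCAE bitwise and ends its phase.

Candidate fine-tuning uses a fixed epoch cap with early stopping,
identical across candidates for fairness, with moderate rate bounds
(0.5–5) so the pre-trained structure is refined rather than overwritten.
Acceptance tolerance is zero: any non-improvement stops the phase.

## Synthetic dose–response data

The generator emulates an in-vitro dose-titration study on severe
hemophilia-A-like plasmas. Each plasma has a latent phenotype: severity
(baseline peak height, uniform in (0.05, 0.4] by default — severe to
moderate), lag time (2–8 min), rise duration (3–10 min), tail
time-constant (2–8 min) and a Hill slope (0.8–2). The clean curve is a
gamma-variate (zero through the lag, peak at the time-to-peak,
exponential-like tail) whose sampled maximum is rescaled exactly to the
dose-dependent peak height

    peak(c) = severity + (1 − severity) · c^s / (c^s + 0.5^s),

a saturating response with half-maximal dose 0.5; the lag shortens
proportionally to the same response. Peak height is therefore exactly
monotone in dose at zero noise, and dose 0 reproduces the baseline.

Defaults mirror the application scale: 180 samples over 60 min, doses on
a uniform grid over (0, 1], dose 1 ↔ 125% FVIII (so c ≈ 0.669 is an
83.62% injection), additive Gaussian noise of sd 0.01 (clipped to [0, 1])
— one noise draw per plasma for the baseline (it is measured once and
reused across the plasma's triplets) and a fresh draw per dose for `y`.
Curves are normalized by the *global* dataset maximum, not per curve, so
the across-dose peak-height ordering survives normalization. Splits are
disjoint at the plasma level. With 73/19/23 plasmas and 17 doses each the
dataset has 1,241/323/391 triplets — approximating, not matching, an
uneven-dose in-vitro design whose per-plasma dose lists are unknown.

What the generator does *not* emulate: mechanistic coagulation kinetics,
inhibitor-positive phenotypes, assay calibration drift, heteroscedastic
or correlated measurement noise, and plasmas whose curve family deviates
from the single-peak gamma-variate shape. Passing tests therefore show
that the optimization algorithms behave as specified on data with this
structure; they do not certify clinical accuracy on real assays.

## Reduced-scale benchmark

The five-approach comparison (incremental CAE; random-search CAE;
conditional incremental DCAE; random-search DCAE with Glorot init and the
regularized cost; random-search DCAE with conditional pre-training and
the unregularized cost; plus a conditional GAN baseline) runs at desk
scale: T = 60, 20/6/6 plasmas, 8 doses per plasma, ten seeded reruns, and
trial-count budgets (5 trials per random search) instead of wall-clock
matching, so results are hardware-independent; a seconds-based budget
mode that matches the measured duration of the incremental reference is
also provided. Per-trial training runs 800 epochs: long enough that good
random draws genuinely converge and poor ones genuinely fail, which is
what separates the random-search spread from the incremental approaches'
repeatability. Random-search trials that diverge count against the budget
and are discarded.

The expected qualitative pattern — incremental approaches repeat tightly
while random searches spread; the conditional incremental DCAE beats the
simple incremental CAE; pre-trained random search beats and repeats
tighter than Glorot random search — is asserted by the acceptance tests.
Absolute error values on synthetic data are not comparable to any
in-vitro figure.

## Numerical choices and limitations

* Sigmoid saturation is clipped at |z| = 500 before exponentiation; the
  induced error is below float64 resolution.
* L1 subgradient at exactly zero activation is taken as 0 (`np.sign`).
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; every pipeline is bit-reproducible
  given its seed, and snapshots/restores are bitwise.
* Early-stopping patience defaults: 10 epochs (plain fits), 25 iterations
  (incremental loop); both are conventions, not tuned constants.
* The GAN baseline is a deliberately small MLP pair (noise dim 8,
  alternating 1:1 updates, non-saturating generator loss) used for
  qualitative comparison only; GAN training at this scale is sensitive to
  its learning rate and can mode-collapse, which the trainer flags.
* Momentum/Adam, convolutional or recurrent layers, GPU execution, and
  streaming/online operation are out of scope.
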