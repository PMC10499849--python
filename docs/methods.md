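# Methods

## Problem setting

A risk model trained on a large historical EHR cohort degrades when the
distribution of its inputs changes — most dramatically at a coding-system
transition, where the occurrence rates of whole families of diagnosis codes
jump abruptly. The practical situation this package addresses: abundant
*pre-shift* data, a small *post-shift* sample (too small to train on alone),
and the assumption that the relation between code history and outcome is
stable (covariate shift). The remedy is to reweight pre-shift patients so
that, collectively, they look like the post-shift sample, and then train the
classifier on the weighted data.

## Model

Each patient `i` is a chronological sequence of visits
`X_i = [x_{i,1}, …, x_{i,T}]`, each visit a multi-hot vector
`x_{i,t} ∈ {0,1}^C` over a C-code vocabulary, padded to a common length `T`
with a visit mask. The binary outcome is `ŷ_i`.

**Stage 1 — sample reweighting.** Non-negative weights
`w ∈ R₊^{|D_pre|}` minimize

```
L_w = α·L_mse + β·L_KL + (Σᵢ wᵢ − N)²
```

* `L_mse = 1/(C−1) · Σ_k (d_k^pre(w) − d_k^post)²`, where
  `d^pre(w)` normalizes the weighted code-occurrence counts
  `s_k = Σᵢ Σₜ wᵢ x_{i,t,k}` and `d^post` the unweighted post-shift counts.
  The `1/(C−1)` factor is kept as the method defines it.
* `L_KL = Σ h̃_post log(h̃_post / h̃_pre(w))`, a KL divergence between pooled
  latent representations. A one-hidden-layer auto-encoder (sigmoid encoder
  `Q`, trained on the real visits of both environments, reconstruction MSE,
  Adam, lr 1e-3, 1000 epochs by default) embeds each visit; the pooled
  matrices are `h_pre = (1/|D_pre|) Σᵢ wᵢ Z_i` and
  `h_post = (1/|D_post|) Σᵢ Z_i`. The divisor is the patient count, not the
  weight sum, so `h_pre` is linear in `w` and the sum-to-N penalty pins the
  scale. Because pooled latent matrices are not themselves probability
  distributions, both are flattened, smoothed by `ε = 1e-8`, and normalized
  to the simplex before the KL — the sigmoid encoder guarantees
  non-negativity, which makes this normalization well defined. This is one
  defensible reading of an under-specified step, and it is recorded as such.
* The penalty `(Σw − N)²` is kept soft, exactly as the objective writes it.

Non-negativity is enforced by parameterizing `w = softplus(u)` with `u`
initialized so `w = 1` — smooth, strictly positive, and compatible with
plain first-order optimization — rather than by projection. Adam (lr 0.01,
500 epochs by default, grids lr ∈ {0.001, 0.01}, epochs ∈ {100, 300, 500})
optimizes `u`; every gradient is analytic and checked against central finite
differences in the test suite. With `α = β = 0` the initialization is an
exact stationary point, so weights remain exactly 1 — a useful self-check.

**Choice of α and β.** From the canonical grid {1, 1e4, 1e7, 1e10}, the
defaults α = 1e7, β = 1e4 put the dominant code-matching term on the scale
of the sum-to-N penalty at initialization (L_mse ≈ 1e-4 on the default
synthetic shift, so α·L_mse ≈ 1e3) while keeping the latent term a softer
regularizer (β·L_KL ≈ 1). Both terms decrease during optimization under
these defaults.

**Stage 2 — weighted classification.** A GRU or LSTM consumes the padded
sequence; the hidden state after the last real visit (padding carries state
unchanged) feeds a sigmoid head. Training minimizes `Σᵢ wᵢ·BCE(f(X_i), ŷ_i)`
with the stage-1 weights frozen, by mini-batch Adam (batch 32), early
stopping when pre-shift validation AUROC has not improved for 10 epochs
(best parameters restored). The per-batch reduction divides the weighted sum
by the batch size, not by the batch's weight sum, so the global loss scale
stays tied to the sum-to-N constraint. Inference is unweighted. The
recurrent cells and backpropagation-through-time are implemented directly in
numpy with analytic gradients (finite-difference-verified); parameters use
fan-in-scaled uniform initialization.

## Synthetic shifted cohorts

The generator emulates the statistical structure of a case-control claims
cohort straddling a coding transition:

* **Vocabulary and rates.** C = 50 codes with a Zipf-like base frequency
  spectrum (rate ∝ 1/rank), matching the skew of real diagnosis-code usage.
* **Visits.** 10–16 visits per patient (the cohort rule of keeping only
  patients with more than ten visits), each visit drawing
  `1 + Poisson(1.3)` distinct codes (≈ 2.3 codes/visit) without replacement.
* **Shift.** Post-shift rates are `base_rates ⊙ multipliers`, renormalized;
  by default five moderately common codes double and two halve — an abrupt,
  asymmetric jump of the kind a coding transition produces.
* **Labels.** One logistic model `ŷ ~ Bernoulli(σ(β₀ + βᵀ x̄))` on the mean
  multi-hot over visits, with identical coefficients and intercept in both
  environments (pure covariate shift; there is deliberately no label-shift
  knob). The intercept auto-centres on the pre-shift cohort's median linear
  predictor, giving ≈ 50% prevalence — the synthetic stand-in for
  case-control matching. Fourteen common codes carry alternating ±6
  coefficients, overlapping the shifted codes so the shift matters.
* **Sizes.** 2000 pre-shift patients (70/15/15 train/valid/test) against a
  tenfold smaller post-shift training sample (200) plus a post-shift test
  set (500) — the same order-of-magnitude imbalance as the motivating
  studies.
* **Reproducibility.** Each patient draws from a seed-derived substream, so
  cohorts are byte-identical given a seed.

A second, mixture-based generator exists purely to create a closed-form
oracle: pre-shift patients come from subpopulation A with probability π and
B otherwise; post-shift keeps only A. The optimal importance weight is then
`1{A}/π` exactly, and learned weights can be scored against ground truth.

**What the generator does not emulate:** calendar time and gradual
month-by-month drift (the shift is a single abrupt boundary; a multiplier
schedule would be the extension point), realistic ICD code strings,
demographics, and — importantly — the deep misspecification of real
clinical risk models. Because the synthetic label mechanism is one shared
logistic model that a recurrent network can essentially represent, passing
tests here demonstrate the *mechanics* of the method (distribution matching,
weight recovery, reproducibility), not the real-data headline that
weighting improves post-shift discrimination; see Limitations.

## Numerical choices

* ε = 1e-8 smooths latent distributions before the KL; 1e-12 guards BCE logs.
* Weighted code distributions with total weighted count 0 raise a
  degenerate-distribution error; C = 1 vocabularies make `1/(C−1)` undefined
  and are rejected.
* Non-finite values in any loss term abort optimization with an error naming
  the offending term.
* Duplicate codes inside one visit collapse to a single 1 (multi-hot);
  padded visits are excluded from every sum by the visit mask.
* AUROC ties count as half-concordant (Mann-Whitney convention); accuracy
  thresholds at 0.5, natural under ≈ balanced prevalence.

## Problem sizes in tests and the acceptance script

Library defaults follow the canonical hyper-parameter grids (classifier
hidden 128 / 2 layers; auto-encoder 1000 epochs). The test suite and
`scripts/acceptance.py` run deliberately scaled configurations chosen as
this package's desk-scale study conditions: hidden 32 / 1 layer, 30
training epochs with patience 5, auto-encoder 200 epochs, and the default
generator sizes above (smaller still for pure-mechanics unit tests). The
weighted-vs-basic comparison averages 5 seeds.

## Known limitations

* **Weighting does not improve AUROC on these synthetic cohorts.** On the
  default shifted cohorts the weighted GRU's post-shift AUROC is on average
  slightly *below* the basic GRU's (≈ −0.01 to −0.05 per seed), and the same
  holds even when training with the oracle importance weights on the mixture
  construction. This is the classical covariate-shift result: when the model
  class can represent the stable input→outcome relation, importance
  weighting removes no bias and only shrinks the effective sample size. The
  real-data setting that motivates the method (vocabularies of ~1500 codes,
  tens of thousands of patients, heavily underfit models) supplies the
  misspecification that makes weighting pay off; this generator, by design
  (stable, representable label mechanism), does not. The no-shift null
  control behaves as expected (mean |AUROC difference| ≈ 0.001), and the
  distribution-matching goal itself is achieved (L1 gap to the post-shift
  code distribution shrinks by ≈ 40%).
* The two matching losses can overfit the post-shift sample's Monte-Carlo
  noise when that sample is small: under a no-shift scenario the optimizer
  still reduces L_mse below its value at w = 1 by fitting noise, with
  mean |w−1| ≈ 0.15. This is inherent to matching an empirical target.
* The soft sum-to-N penalty needs more epochs to settle on small cohorts
  (hundreds of patients) than the 500-epoch default; tests on tiny cohorts
  use more epochs.
* Attention-based backbones are pluggable behind the same layer interface
  but not implemented; only GRU and LSTM are provided.
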