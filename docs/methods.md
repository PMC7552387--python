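# Methods

## The study design

The package benchmarks how two properties of a two-group cohort shape
between-group machine-learning performance gaps:

* **data inequality** — the group sample sizes n₁ (majority) and n₂
  (minority);
* **distribution discrepancy** — a marginal part (n_de features whose
  minority-group distribution is shifted, i.e. P(X) differs) and a
  conditional part (per-group effect signs β_j^k, i.e. P(Y|X) differs where
  β_j^1 ≠ β_j^2).

Four predefined study conditions cross these factors over 200 features:

| dataset | n₁   | n₂  | n_de | (n₋₋, n₋₊, n₊₋, n₊₊) | inequality | discrepancy |
|--------:|-----:|----:|-----:|----------------------|------------|-------------|
| 1       | 2184 | 320 | 20   | 64, 37, 37, 62       | yes        | yes         |
| 2       | 2184 | 320 | 0    | 100, 0, 0, 100       | yes        | no          |
| 3       | 260  | 260 | 20   | 64, 37, 37, 62       | no         | yes         |
| 4       | 260  | 260 | 0    | 100, 0, 0, 100       | no         | no          |

Counts of 100/0/0/100 make the two effect vectors identical (no conditional
discrepancy); 64/37/37/62 leaves 74 of 200 positions with opposite signs.

## Synthetic cohort generator

Feature counts are negative-binomial: per-feature baseline means are
log-normal (natural-log mean 5, sd 1, i.e. typical counts in the tens to
hundreds), dispersion φ = 0.1 via gamma–Poisson mixing (φ = 0 degenerates
to Poisson). Each of the n_de differentially expressed features multiplies
the minority group's mean by a fold change of 2, direction (up/down) random
per feature. Counts are transformed log2(count + 1) and standardized
feature-wise (population sd) over the pooled cohort. Because every
downstream model consumes standardized inputs, results are insensitive to
the baseline-mean scale; the fold change of 2 gives an easily detectable
but not overwhelming marginal shift (the two-group t-test detects
essentially all DE features at these sample sizes).

The four (β¹, β²) sign combinations are dealt to feature positions by a
uniform random permutation, independent of which features are DE — no
structure links the two because none is asserted by the data model. Labels
come from the logistic score z_i = σ(Σ_j β_j^k x_ij): sample i in group k
is positive iff z_i exceeds the group's class-quantile threshold c^k. The
default quantile is 0.5 (per-group median), which balances the classes —
the least-informative choice, and one that keeps AUROC well defined even in
small CV folds. Labels are generated from the same standardized matrix the
classifiers see, so no hidden covariate shift is introduced between label
generation and learning. Labels are {−1, +1} at the data model and mapped
to {0, 1} wherever cross-entropy is computed.

Everything is driven by one seeded generator: an identical config (seed
included) reproduces the cohort bit for bit.

**Parameter estimation** inverts the construction on any two-group cohort:
n₁/n₂ by counting; n_de as the number of features with permutation t-test
p < 0.05 between groups (B = 1000 label permutations shared across
features, Welch statistic, smoothed p = (1 + #{|t*| ≥ |t|})/(1 + B)); and
the β combination counts from per-group multivariate logistic fits, each
coefficient mapped to +1 iff it exceeds the vector's median. The logistic
fits carry a small ridge penalty (λ ≈ 1e−4) because an unpenalized fit is
ill-posed when features rival samples. On generated cohorts
(n₁ = n₂ = 500) the recovered combination counts sit within a few features
of the truth; the n_de estimate is inflated by the α-level false positives
among the null features (≈ α · (p − n_de)), which is inherent to the
estimator, not a defect.

### What the generator does and does not emulate

It emulates the statistical skeleton of a two-group expression cohort:
overdispersed counts, a minority group, a controllable fraction of shifted
features, and group-specific outcome laws. It does not emulate gene–gene
correlation, batch effects, missingness, label noise (labels are a
deterministic threshold of z), or survival-time dichotomization. Passing
tests therefore demonstrate that the *schemes* behave as claimed under
controlled inequality/discrepancy — not that any particular real cohort
shows these gaps.

## Networks and training

The classifier is a pyramid network: input (one node per feature), fully
connected 128, dropout, fully connected 64, dropout, single logistic output;
ReLU on hidden layers. The loss is cross-entropy plus L1 and L2 weight
penalties; per batch of m samples we minimize

    ( Σᵢ CE(yᵢ, ŷᵢ) + λ₁·Σ|W| + λ₂·‖W‖₂² ) / m

so the data/penalty ratio equals the summed formulation's and only the
learning-rate scale changes. Defaults: lr 0.01, lr decay 0 (schedule
lr/(1 + decay·epoch) when used), batch 20, 100 epochs, Nesterov momentum
0.9, dropout 0.5, λ₁ = λ₂ = 0.001. The L2 term is the squared norm (the
standard weight-decay reading); a flag switches to the unsquared global
norm. Penalties cover connection weights only, never biases. Predictions
are clipped to [1e−7, 1 − 1e−7] inside the cross-entropy.

Implementation notes:

* Forward/backward passes are hand-written NumPy; analytic gradients of the
  full regularized loss (including the L1 subgradient, sign(0) = 0) are
  validated against central finite differences at relative tolerance 1e−5.
* Nesterov momentum uses the standard reformulated update
  v ← μv − η∇(w), w ← w + μv − η∇(w), which tracks the lookahead point
  implicitly; a fused numba kernel applies penalty gradient and update in
  one pass over the weights (a pure-NumPy path computes identical updates
  when numba is unavailable).
* Dropout is inverted dropout (activations scaled by 1/(1−p) during
  training), equivalent to scaling weights by (1−p) at inference; inference
  is a plain deterministic forward pass.
* Training arithmetic is single precision; weight initialization (uniform
  Glorot), batch shuffling and dropout masks all draw from one seeded
  generator, so a fixed seed gives bit-identical weights. An epoch is one
  pass over shuffled data with the final partial batch kept. Divergence
  (non-finite loss) raises an error naming the epoch; there is no early
  stopping.
* With no hidden layers and zero penalties the trainer reduces to logistic
  regression and matches an independent convex solver's coefficients.

The stacked denoising autoencoder has five layers (input → 128 → 64 → 128 →
input), ReLU hidden activations and a linear output (it reconstructs
standardized, signed data). Each presentation masks a fraction (corruption
level 0.3) of input entries to zero; the loss is mean squared
reconstruction error against the uncorrupted input; training is plain SGD
(lr 0.01, batch 32, 500 epochs) — momentum is left off here because the
reconstruction objective converges without it at these sizes.

## Transfer learning

1. **Fine-tuning**: pretrain the pyramid network on the source group
   (lr 0.01, batch 20, 100 epochs), then continue training *all* weights on
   the minority training samples at lr 0.002, batch 10, 100 epochs (the cap
   for this stage is a config knob; it mirrors the pretraining length).
2. **SDA transfer**: pretrain the autoencoder on unlabeled source +
   minority *training* features (never the test fold), keep the encoder,
   insert dropout (0.5) after each hidden layer, append a fresh logistic
   output, and fine-tune on the labeled minority training samples
   (lr 0.002, batch 10, 100 epochs).
3. **CCSA domain adaptation**: one 100-unit ReLU embedding g with dropout
   0.5 before the logistic head h, trained on
   L = (1−γ)·L_C + γ·(L_SA + L_S), where L_SA averages ½d² over same-label
   cross-domain embedding pairs and L_S averages ½max(0, m−d)² over
   different-label pairs (d = Euclidean distance, margin m = 0.3). Inputs
   must be row-L2-normalized (checked to 1e−6) so embedding distances are
   comparable. Per epoch the source set is walked in shuffled batches of 20
   while minority batches cycle an independently shuffled ordering; every
   batch contributes *all* its source × target pairs, with each loss
   normalized by its own pair count — an exhaustive, deterministic pairing
   that matches the 1/n normalization most directly. L_C is the mean
   binary cross-entropy over the concatenated batch. γ defaults to 0.25
   (the customary weighting for this loss family; exposed in the config),
   lr 0.01, momentum 0.9, 100 epochs. A kind of pair absent from a batch
   contributes zero and is logged. The alignment terms use the
   dropout-free embeddings; gradients of the full objective are
   finite-difference-checked like the classifier's.

`transfer_best` runs all three, evaluates each on the minority test fold by
AUROC and returns the maximum (ties and failed methods resolve by the fixed
order fine-tune, SDA, CCSA). Selecting on the test fold is optimistic by
construction; it is retained because the suite's role is to bound what
transfer can recover, and the per-method scores are all logged.

## Cross-validation, AUROC and gaps

Fold plans are threefold, stratified by (outcome × group) for the mixture
scheme and by outcome within one group for the independent scheme. Each
stratum is shuffled and dealt round-robin from a random starting fold, so
per-stratum fold sizes differ by at most one; strata smaller than three
samples are assigned the same way with a warning. Every sample is tested
exactly once per run, always by a model that never saw it in training.

AUROC is computed by the rank (Mann–Whitney) formula with ties counted ½,
and is exactly the fraction of (positive, negative) pairs ranked correctly.
Per run, the fold AUROCs are averaged (three folds → one value per
experiment per run); a pooling flag is deliberately absent — fold-level
averaging keeps each fold's class balance intact. Medians over runs give
A_Mixture0 … A_Transfer, the per-scheme gaps, and

    G  = (A_Mixture1 + A_Independent1)/2 − (A_Mixture2 + A_Independent2)/2
    G̃ = (A_Mixture1 + A_Independent1)/2 − A_Transfer

Gap calls use the 0.05 AUROC threshold. The minority independent model
trains with batch 4 when the minority is less than half the majority's size
(too few samples for batch-20 updates), and batch 20 under equal group
sizes.

A master seed deterministically spawns every per-run, per-fold and
per-model seed, so a suite run is reproducible end to end.

## Problem sizes and numerical choices

The shipped study drivers and the acceptance script run the mixture and
independent schemes with 10 repeated partitions on the two large-cohort
conditions (2504 samples) and 20 on the equal-size conditions (520
samples); medians are stable at these counts and the whole four-dataset
sweep completes in roughly ten minutes on one CPU. The transfer scheme is
available through the same suite (`schemes=(..., "transfer")`) but is an
order of magnitude slower because of autoencoder pretraining, so the
drivers leave it opt-in.

Remaining numerical conventions: population (ddof 0) sd for
standardization; zero-variance features standardize to zeros with a flag;
top-k selections break score ties by ascending feature index; sample
filtering drops rows with *strictly more* than the missing-fraction cutoff;
the permutation t-test defaults to the Welch statistic (safer under unequal
group sizes; a flag selects the pooled variant).

## Known limitations

* Labels are noise-free functions of the features, so absolute AUROCs run
  higher than typical clinical-omics values; the gap *pattern*, not the
  absolute level, is the object of study.
* With equal group sizes the per-scheme gap still carries cohort-level
  sampling noise of roughly ±0.03–0.05 AUROC (each generated cohort has an
  intrinsically "easier" group by chance; verified by group-swap
  experiments, which flip the gap's sign exactly). Calls near the 0.05
  threshold on such cohorts can go either way across generator seeds.
* The CCSA pairing weight γ and the fine-tuning epoch cap are not pinned by
  the protocol being modeled; both are exposed configuration with the
  defaults above.
* Only two groups per run are modeled; additional minorities are handled by
  relabeling the target group.
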