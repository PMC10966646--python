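# Methods

## The problem

In structure-based drug discovery, labeling a compound with a binding
affinity — by assay or by relative binding free energy (RBFE) calculation —
is expensive (~8 GPU hours, ~$20 per compound for RBFE), while candidate
libraries run to thousands of compounds. Active learning (AL) spends a fixed
labeling budget in cycles: train a surrogate on what has been labeled, let it
choose the next batch, repeat. The questions this package is built to answer
are operational: which batch schedule, which acquisition strategy, and how
much label noise the loop tolerates, all at a *fixed total budget* so that
protocols are compared at equal cost (360 compounds by default).

## The surrogate

Compounds are featurized as binary Morgan fingerprints (radius 4, the
diameter-8 "ECFP8" convention, hashed to 4096 bits). The surrogate is exact
Gaussian-process regression with the Tanimoto kernel

    k(x, x') = sigma_f^2 * |x ∧ x'| / |x ∨ x'|,

the natural positive-semidefinite similarity for bit sets. Labels are
standardized to zero mean and unit sd over the training set; the model is
y ~ GP(m, k) + N(0, sigma_n^2) in that standardized space, and predictions
are mapped back to pK units.

Hyperparameters (sigma_f^2, sigma_n^2, m) are fit by gradient ascent on the
per-point log marginal likelihood: fixed initialization (amplitude 1.0,
noise 0.1, mean 0.0), 200 iterations, learning rate 0.1, amplitude and noise
parameterized in log space and the noise floored at the 1e-6 jitter level.
These mirror common GP-toolkit defaults and make every fit bit-reproducible.
Because the Tanimoto Gram matrix does not change during optimization, its
eigendecomposition is computed once and each gradient step costs O(n^2);
the final factorization is a Cholesky of K + sigma_n^2 I with jitter
escalation 1e-6 → 1e-4 before a hard error.

Two reporting conventions worth knowing:

* the predictive variance is for the latent function (sigma_n^2 is not
  added). Acquisition ranks are identical either way; add sigma_n^2 times
  the label variance if you need an observation-scale variance;
* with a single training point the standardized label is zero, so the
  prediction at that point equals the label and the shrinkage factor
  sigma_f^2/(sigma_f^2 + sigma_n^2) only becomes visible with >= 2 points.

Any other surrogate can be slotted in through the two-method contract
`fit(fingerprints, labels)` / `predict(fingerprints) -> (mean, variance)` —
e.g. an ensemble or dropout neural regressor.

## Acquisition and protocols

Three pure strategies per cycle: **random** (uniform without replacement),
**exploit** (highest posterior mean), **explore** (highest posterior
variance; variance rather than sd — a monotone transform with no effect on
the batch). Ties break by ascending compound id so selection is a pure
function of its inputs. No hybrid/UCB rules and no diversity-based initial
selection: the protocol catalogue evaluates pure phases.

Named protocols, all summing to the 360-compound budget and all starting
with one random batch of 60:

| name | phases |
|---|---|
| random-exploit | random 60x1, exploit 30x10 |
| random-explore-exploit | random 60x1, explore 30x2, exploit 30x8 |
| random-random-exploit | random 60x2, exploit 30x8 |
| batch-size-20 | random 60x1, explore 20x3, exploit 20x12 |
| batch-size-30 | random 60x1, explore 30x2, exploit 30x8 |
| batch-size-60 | random 60x1, explore 60x1, exploit 60x4 |
| batch-size-120 | random 60x1, explore 60x1, exploit 120x2 |

The second random batch of random-random-exploit is implemented as one cycle
of 60 rather than two of 30; at cycle granularity the metrics are
insensitive to the split. If the pool is smaller than the budget the final
batch shrinks and the log is flagged `truncated`.

Campaign loop per cycle: select batch (the model-based strategies use the
posterior computed at the end of the previous cycle) → reveal noisy labels →
retrain the surrogate from scratch on all acquired compounds (no warm start;
the GP is stateless) → predict on the remaining pool → append metrics.

## Metrics

Retrieval is scored against the **noiseless** ranking: the active set is the
top r fraction (r = 2%, 5%) of the pool by true potency with
k = round-half-up(r * N_tot) members, and with N_acq compounds acquired,
Recall = TP/k and F1 = 2 TP/(N_acq + k) (from TP + FP = N_acq and
TP + FN = k). The integer k in Recall's denominator lets it reach exactly 1.
The random-acquisition expectation E[TP] = r * N_acq gives the baseline
curve. Round-half-up is the single convention that reproduces the published
per-dataset top-k counts except one cell (0.02 x 4535 = 90.7 is printed as
90 there; we report 91 and do not treat the 90 as normative, since no single
rounding rule yields both that cell and the others).

Regression metrics (R2 = 1 - SS_res/SS_tot, Spearman rho with average ranks
on ties, RMSE) are computed during AL on the remaining (unacquired) pool
against true potency — the natural inference set, though it shrinks and
becomes potency-imbalanced late in exploitative campaigns. A constant
observed vector makes R2/rho undefined; they are reported as NaN with RMSE
still returned.

The single-batch benchmark cuts the shuffled pool into 5 disjoint 20% train
partitions, scores each model on the untrained 80%, and reports fold means
with 95% t-based confidence half-widths; top-k Recall there selects the
predicted top k within each test side.

## Label noise

Noise emulates a stochastic labeling method: eps ~ N(0, (c * sigma_pool)^2)
with multiplier c in {0, 0.5, 1, 1.5, 2} and sigma_pool the pool's potency
sd, so absolute noise levels track each pool's dynamic range. The noise is
drawn once per compound per campaign (`redraw_noise = false`): a measured
label does not change between cycles. Training uses noisy labels; retrieval
is always scored against the noiseless active sets. Systematic
(nonzero-mean, substructure-targeted) noise is out of scope.

## Synthetic pools

The generator emulates the *regimes* that shape AL outcomes, not any real
chemistry. Each of K clusters owns core fingerprint bits (a scaffold, shared
by all members) and substituent bits switched on independently with
probability 1/2 (R-group combinations). Potency is additive:

    potency = cluster_effect + sum_b (bit_b - 1/2) beta_b + eps,

so the pooled variance decomposes as cluster_effect_sd^2 +
(substituent_bits/4) substituent_effect_sd^2 + residual_sd^2. The generator
is variance-targeted: cluster effects are drawn Gaussian, sorted so the
`active_cluster_fraction` lowest-numbered clusters carry the largest
effects, then rescaled so their size-weighted sd is exactly
cluster_effect_sd (likewise each cluster's beta vector is rescaled to its
nominal mean square). Without this, a scenario with 8 clusters would see its
pooled sd fluctuate ±25% from seed to seed; with it the pooled sd lands
within a few percent of nominal, which is what the presets promise.

Presets (pooled sd targets chosen to match realistic affinity spreads of
~1.4 pK units for large pools and ~0.9 for a small diverse one):

| preset | n | clusters | pooled sd | character |
|---|---|---|---|---|
| congeneric | 2000 | 8 (2 active) | 1.41 | dense scaffold clusters, top binders in 1-2 of them |
| heterogeneous | 2250 | 150 of 13-15 | 1.40 | many small congeneric series |
| small-diverse | 600 | 60 | 0.90 | weak cluster signal; budget covers >half the pool |

Pool sizes for the two large presets sit at ~2000 compounds, large enough
that the 360-compound budget is a realistic <20% of the pool while keeping a
full campaign around a second of CPU time.

What the generator does **not** emulate: real substructure distributions and
hashed-bit collisions, activity cliffs (the additive model is deliberately
smooth), assay floor/ceiling effects, multiple assay minima, and
inter-cluster chemical relatedness. Passing campaign-level tests on these
pools therefore demonstrates that the pipeline's machinery behaves correctly
under the intended regimes — smooth structure–activity signal with cluster
structure — not that any particular recall level transfers to a real
library, where cliffs and feature noise will lower it.

## Free-energy conversion

RBFE outputs arrive as ddG (kJ/mol) against a reference compound with known
absolute dG_ref; with dG = RT ln K_i and pKi = -log10 K_i,

    pKi = -(dG_ref + ddG) * 1000 / (R T ln 10),

R = 8.314 J/(mol K), default dG_ref = -47.778 kJ/mol (the reference
inhibitor of the kinase dataset this conversion was introduced for), default
T = 298.15 K. The temperature is a standard-condition convention, not a
property of the data, and is overridable.

## Numerical and design choices

* Seed policy: one master seed per campaign spawns independent streams for
  the random cycles and the noise draw (`numpy.random.SeedSequence`), so a
  campaign is exactly reproducible and changing the noise realization cannot
  perturb the initial batch.
* Tanimoto of two all-zero vectors is defined as 1 (constant kernel
  diagonal); all-zero fingerprints also trigger a warning at featurization.
* Tanimoto matrices are computed by float32 matrix products (popcounts are
  exact small integers there) with the final division in float64, keeping
  the production posterior within ~1e-15 of a naive dense solve.
* Exact bit positions of the hashed fingerprints are toolkit-defined; tests
  assert properties (determinism, chirality sensitivity, kekulization
  invariance), not specific indices.
* Campaign metrics at cycle t use the model trained on everything acquired
  through cycle t; selection at cycle t uses the model from cycle t-1.

## Problem sizes

The shipped analyses and checks run the full pipeline at the preset sizes:
campaigns on the 2000-compound congeneric pool (11-16 cycles, three seeds),
the 5-fold benchmark at 400-compound training sets, and the noise sweep over
{0, 0.5, 1, 1.5, 2} (the three-point grid {0, 1, 2} where only the decay
direction is at issue). A single campaign takes roughly a second of CPU
time, so the complete analysis suite runs in a couple of minutes.

## Known limitations

* The message-passing-network branch of surrogate modeling is not included;
  the surrogate contract is where it would plug in.
* Exploration uses global posterior variance only; no diversity or
  clustering-based selection.
* The regression trajectory is measured on a shrinking, increasingly
  potency-truncated remainder set; late-cycle R2/rho are pessimistic for
  exploitative protocols by construction.
* Real-data ingestion expects curated CSV (unique ids, one potency column);
  assay deduplication and unit harmonization are upstream concerns.
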