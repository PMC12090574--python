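# Methods

## Problem setting

The input is a compendium of individual DNA-methylation-array samples:
an N×M matrix of beta values in [0, 1] (fraction of methylated copies per
CpG probe) with a species and tissue label per sample. Coverage of the
S×T species-tissue grid is incomplete and imbalanced. The target of
inference is the *combination mean sample*: the expected probe profile of
one species in one tissue. The package imputes combination mean samples
for unobserved grid cells, provided the target species is observed in at
least one other tissue and the target tissue in at least one other
species — outside that regime there is no cross-signal to borrow.

## Conditional VAE

Encoder and decoder are mirrored fully connected networks. The encoder
input is the sample concatenated with its two-hot label (M + S + T wide);
two separate linear heads after the last hidden layer emit the posterior
mean μ and log-variance σ over the Z-dimensional latent space. The
decoder input is the latent vector concatenated with the label
(Z + S + T wide); its linear output layer emits M logits and beta values
are their sigmoid. Training minimizes binary cross-entropy of the logits
against the continuous beta targets (a valid Bregman loss whose minimizer
is the conditional mean — exactly the quantity imputed) plus the analytic
Gaussian KL to the N(0, I) prior, using the reparameterization
z = μ + exp(σ/2)·ε with one Monte-Carlo draw per sample per step
(configurable). Reductions: BCE summed over probes, KL summed over latent
dimensions, both averaged over the batch, which keeps the
reconstruction/regularization balance independent of batch size.

Imputation draws z from the prior (never from encoding an individual, so
the output is individual-agnostic) and decodes with the target label.
The latent-stability report quantifies the consequence of the single
draw: on trained models the median per-probe variance across 20 replicate
draws of one key is about three orders of magnitude below the median
variance across different keys, so the label, not the latent draw,
determines the output.

### Numerical choices

* The network is plain NumPy with hand-derived gradients; a finite-
  difference check (1e-4 relative) in the test suite and acceptance
  script guards the backward pass.
* BCE is evaluated in logit form, `softplus(ℓ) − x·ℓ`, which cannot
  overflow; its gradient is `sigmoid(ℓ) − x`.
* Weights are Glorot-uniform from a seeded generator; biases start at
  zero. Identical seeds reproduce initialization, shuffling, latent
  draws, and therefore training bit-exactly.
* Adam with configurable learning rate and epsilon (the grid-search
  dimensions include both); non-finite losses abort with a diagnostic
  rather than training through NaNs.

### Defaults and tunables

| parameter | default | why |
|---|---|---|
| hidden_dims | (1024, 512) | the full-compendium architecture; synthetic runs use (64,) |
| activation | tanh | selected architecture's activation |
| latent_dim Z | 8 | small enough that the prior draw barely perturbs output |
| learning_rate | 1e-3 | Adam default scale |
| optimizer_epsilon | 1e-4 | part of the searched grid |
| epochs / batch_size | 200 / 64 | converged on every fixture tested; no early stopping |
| mc_samples L | 1 | an effective, cheap MC approximation |

Hyperparameter selection is by grid search: each grid point is trained on
the training combinations and scored by the mean sample-wise Pearson r of
its imputations against held-out validation combination means; ties keep
the earliest grid point.

## Baselines

Species / tissue / global baselines average the training individuals
sharing the target species / tissue / anything. The logistic baseline
fits one L2-penalized logistic regression per probe on the two-hot
features, duplicating each sample into a positive instance weighted by
beta and a negative instance weighted by 1 − beta, so the predicted
class-1 probability is the predicted methylation level. The objective is
`Σ weighted log-loss + λ‖W‖²` with the intercept unpenalized; the
delegated solver's constant is converted (C = 1/(2λ)) and the fitted
parameters are verified against the analytic stationarity condition in
tests. The λ sweep {1, 2, 4, 8, 16} is supported and scored the same way
as the CVAE grid.

## Evaluation

* Sample-wise agreement: per-combination Pearson r and MSE across probes;
  probe-wise agreement: per-probe r and MSE across combinations. On a
  complete evaluation grid the two mean MSEs are the same grand mean of
  squared errors — an identity the tests assert to 1e-12.
* Pearson r is undefined for constant vectors; such entries are flagged
  and excluded from r summaries (with counts) while their MSE still
  counts.
* Probe variances (inter-combination, mean inter-tissue, mean
  inter-species) are computed on combination means — never on raw
  individuals, so replicate counts cannot skew them — as population
  variances (divide by n). Quartile stratification is rank-based with
  ties broken by probe id; group sizes differ by at most one, remainders
  to the lower quartiles.
* Species/tissue signal AUCs classify unordered sample pairs as
  same-species (or same-tissue) by their pairwise correlation,
  Mann-Whitney ties counted ½.
* Paired method comparisons report the fraction of keys where one method
  beats the other and a two-sided Wilcoxon signed-rank p-value with zero
  differences dropped.

## Cross-validation protocol

Folds partition the eligible combinations (species in >1 tissue, tissue
in >1 species) uniformly at random with a seed. Within a fold, 20% of
the non-test combinations are drawn as validation; any validation
combination lacking a same-species and a same-tissue combination in the
candidate training set is moved to training, and if fewer than 10% of the
non-test combinations survive in validation the draw is retried with the
next derived seed (bounded retries; a star-shaped grid errors out with
the best attempt reported). All individuals of a test combination are
excluded from training. By default the per-fold final model is trained on
the training combinations only (a flag rejoins validation). A test key is
scored only when same-species different-tissue and same-tissue
different-species data remain in the final training set, and this filter
is applied identically to the CVAE and every baseline.

## Lifespan regression

Log maximum lifespan (natural log; r is base-invariant, MSE is not, and
the base is recorded in the report) is regressed on combination mean
profiles with ordinary least squares and evaluated leave-one-species-out.
With more probes than species the system is underdetermined and the
minimum-norm least-squares solution is used. Tissue-agnostic mode
averages rows to one per species; tissue-specific mode holds out all rows
of a species at once and evaluates per tissue, restricted to tissues
predicted in at least three species.

## Synthetic study conditions

The generator produces probe p, species s, tissue t logit-scale means
`b_p + u_{s,p} + v_{t,p} + w_{s,t,p}` with independent Gaussian effects,
then individuals as the sigmoid of the mean plus Gaussian noise. Defaults
(logit scale): baseline sd 1.2 (wide, roughly bimodal beta values like
real arrays), species sd 0.6 and tissue sd 0.6 (comparable species and
tissue signal), interaction sd 0.1 (signal that no mean baseline can
capture), individual noise sd 0.4 (within-combination replicate
correlations near 0.98, matching the high reproducibility of real
replicates). Observed cells are drawn uniformly subject to every species
and tissue remaining covered; per-cell individual counts are geometric
with mean 3 to mimic opportunistic collection. The default evaluation
fixture is S=20, T=6, M=300 at 80% observed coverage, which a single CPU
cross-validates in seconds; signal-AUC analyses use a 20×10 grid so that
the species:tissue ratio (and hence the fraction of identical-row pairs
produced by the mean baselines) resembles real compendia.

What the generator does **not** emulate: probe-level mappability biology
(the mappability mask generator is random and for interface testing
only), phylogenetic correlation between species effects, batch or
platform effects, and beta-value heteroscedasticity near the boundaries.
Passing tests therefore demonstrate correct inference under an additive
logit model with exchangeable species — not performance on real arrays.

Synthetic lifespans are linear in the species-average methylation of a
few signal probes (standardized, plus optional noise, then
exponentiated). Recovery tests use a fixture with more species (30) than
probes (12) so noiseless LOSO regression is exactly determined and must
achieve r ≈ 1; the no-signal null uses the same shape and stays within
sampling bounds of zero.

## Known limitations

* The CVAE is a point imputer; the probabilistic latent space is not used
  for uncertainty quantification.
* Combination means are imputed from one latent draw, matching the
  individual-agnostic procedure; averaging draws would shrink the small
  residual draw-to-draw variability further but is not done.
* Grid search retrains from the same seed per point; scores are
  comparable but share initialization randomness.
* Underdetermined lifespan regressions rely on the minimum-norm
  convention; with M ≫ n the predictions are shrunk and r, not MSE, is
  the meaningful statistic.
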