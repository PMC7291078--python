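# Methods

## Model

scSDAE treats dropout imputation as masked matrix reconstruction under a
manifold assumption: expression profiles of single cells lie near a
low-dimensional nonlinear manifold, so a bottlenecked autoencoder that
reconstructs cells well at observed entries will produce sensible values at
the unobserved (zero) entries. The network is a symmetric stack of dense
layers — encoder widths (n, d₁, …, d_k), mirrored decoder — with ReLU on
hidden layers and no activation on the bottleneck or the output. The
reference architecture is n-500-500-2000-10; smaller problems use
proportionally smaller stacks (see "Problem sizes" below).

Three loss variants are implemented, all per cell and averaged over the
minibatch:

* `scsdae` — MSE over observed entries plus α × mean |output| over zero
  entries. The L1 term penalizes the *number and size* of imputed values,
  which preserves true zeros and mildly shrinks imputed expression.
* `sdae` — MSE over all entries (the classical denoising autoencoder loss).
* `sdae0` — MSE over observed entries only; identical to `scsdae` with
  α = 0, which the test suite asserts down to bit-identical training
  trajectories.

A cell with no zero entries contributes no penalty term; a cell with no
observed entries cannot occur after filtering but would contribute no MSE
term. The α = 1 default suits log-CPM single-cell matrices; α = 0.001 is
the preset for dense bulk-derived benchmarks, where the zeros are all
simulated dropouts and should not be trusted as evidence of non-expression.
Values of α in (0.1, 1) are a reasonable range to explore on real data.

## Training procedure

1. **Greedy layer-wise pretraining.** Layer i is trained as a
   one-hidden-layer denoising autoencoder on the previous layer's *clean*
   activations: input corrupted by zero-masking at rate 0.2, target clean.
   The first autoencoder minimizes the variant loss; the inner ones
   minimize plain MSE (their inputs are hidden activations, where zero is
   not special). After training, the encoder is applied to the uncorrupted
   input to produce the next layer's data.
2. **Fine-tuning.** The pretrained layers are stacked (the forward pass at
   this point exactly equals the composition of the pretrained layers — an
   invariant under test) and trained end to end on uncorrupted input under
   the variant loss.
3. **Masked imputation.** Only zero entries receive network output;
   observed values are copied through unchanged. Negative outputs at zeros
   are clamped to 0 by default (`clip_nonnegative`), since log-CPM
   expression is non-negative; the flag can be disabled.

Numerical and procedural choices:

* "Iterations" are minibatch gradient steps, not epochs. Minibatches are
  drawn by seeded shuffling with cycling; batch size defaults to 256 and is
  reduced to the cell count for smaller matrices.
* Corruption applies zero-masking independently per entry. Restricting it
  to observed entries would be behaviourally identical (zeros are fixed
  points of the mask), so the `corrupt_observed_only` flag is cosmetic.
* Weights are Glorot-uniform, biases zero, all float64, seeded through a
  `SeedSequence` hierarchy so a single integer seed fixes initialization,
  corruption and batch order. With a fixed BLAS thread count, training is
  bit-reproducible.
* Adam uses learning rate 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e-7.
* The training loop aborts with a diagnostic (`NumericalError`, CLI exit
  code 3) if the loss becomes non-finite.
* The subgradient of |·| at 0 is taken as 0 (`np.sign`).

## Preprocessing

Cells with no expressed gene and genes expressed in no cell are removed
(cells first, then genes; a second pass is asserted to be a no-op, which
holds for non-negative data). Normalization is log(CPM + 1); the log base
is natural by default and configurable, since toolkits differ and the
choice only rescales the matrix. Zero counts map to exactly zero normalized
values, which is what makes the zero mask well defined. Non-integer
non-negative inputs (microarray-style intensities) are accepted unchanged.

## Synthetic evaluation designs

* **Bulk-like trajectory + logistic capture dropout.** Per-gene log
  profiles are Gaussian-smoothed white noise along a latent sample order
  (kernel width 0.15 × n samples, amplitudes 0.5–2 on the log scale, base
  abundances log-uniform over 10–10⁴), giving the banded sample–sample
  correlation structure of a developmental time course. Dropout follows a
  logistic capture model — P(captured) = σ(intercept + slope·log value) —
  with the intercept solved by bisection so the expected zero fraction hits
  the target within 1e-4 (realized rates land within ±2% for matrices of
  ≥10⁵ entries). This emulates the *structure* of a real time-course
  compendium, not any particular organism; real data can be substituted
  through the same readers. It does not emulate count noise or batch
  effects, so success here shows recovery of smooth low-rank structure
  under value-dependent dropout, nothing more.
* **Two-group negative binomial.** 1000 cells in two balanced groups × 500
  genes, base means log-uniform on [10³, 10⁴], NB size 0.5, half the genes
  DE at fold change 3 with alternating direction (so library sizes stay
  balanced; fold change and dispersion are configurable, as the design
  leaves them open). DE–DE gene pairs covary through the group structure
  and constitute the "true" gene–gene correlations for FDR/TPR analysis.
* **Spike-in marker genes.** Five artificial genes appended to a
  normalized background: ~N(0, 0.1) in one group (negatives clamped to 0,
  so its zeros are *true* zeros) and ~N(2, 0.1) in the other; positive
  spiked values are then zeroed at the rate that brings the spiked columns
  to the target zero fraction (default 50%). The background is a two-group
  NB matrix with means log-uniform on [1, 100] (~25% zeros after log-CPM),
  chosen to emulate the sparsity of a real single-cell matrix — on a
  near-dense background the per-cell penalty weight α/#zeros would be
  unrealistically large and the experiment would not resemble single-cell
  conditions.

All simulators record truth, observed matrix, dropout mask, labels and DE
flags, never mark a true zero as a dropout, and are exactly reproducible
from a seed.

## Metrics

* CMD = 1 − tr(R₁R₂)/(‖R₁‖_F‖R₂‖_F) on sample–sample correlation matrices
  (Pearson by default; the gene set defaults to all genes, with a
  top-variable-genes helper).
* Gene–gene detection: Spearman correlations with midrank ties; p-values by
  exact permutation enumeration for n ≤ 8 cells and the t-approximation
  otherwise (exact enumeration beyond n = 8 costs ≥ 9! permutations per
  pair and is not practical); Bonferroni threshold α_fw / C(G, 2).
  Zero-variance genes are reported as not significant, with a warning.
* FDR/TPR: a detected pair is a true positive iff both genes are DE; FDR
  uses the FP/max(1, FP+TP) convention so empty detection gives 0.
* DE power: per-gene Kruskal–Wallis across groups,
  Benjamini–Hochberg at 5% FDR; sensitivity/specificity against the DE
  flags. Genes constant across all cells get p = 1.
* Per-group MAE over spiked columns; the total is the entry-weighted mean
  of the group MAEs.
* ARI delegates to scikit-learn's adjusted Rand score (cross-checked in the
  tests against brute-force pair counting). Clustering itself is out of
  scope; ARI compares externally supplied labelings.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipelines at scaled
sizes chosen to keep a complete run at a few minutes on one CPU: the
downsampling design at 206 × 2000 with a (n, 64, 16) stack, 200 pretraining
steps per layer and 400 fine-tuning steps; the NB design at its native
1000 × 500; the spike-in design at 740 cells. These sizes are large enough
for the qualitative contrasts (imputed-vs-observed CMD, scSDAE-vs-SDAE0
false positives) to be stable across seeds; the stochastic end-to-end tests
therefore assert majorities over 5 seeds rather than single runs.

## Limitations

* The benchmark conclusions are about the synthetic designs above; none of
  them models UMI sampling, batch structure, or cell-type hierarchies.
* The numpy training loop is single-node and CPU-oriented; the reference
  architecture on tens of thousands of genes trains in minutes-to-hours,
  not seconds.
* α trades false positives in true-zero regions against recovery of
  dropouts (visible directly in the spike-in per-group MAEs); there is no
  automatic selection — the defaults follow the recommendations above.
* Checkpoints store weights and configuration, not the training data;
  reloading reproduces forward passes exactly but not optimizer state.
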