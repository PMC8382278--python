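# Methods

This note documents the model, the numerical and design choices, and what
the synthetic benchmark does and does not demonstrate.

## Data model and preprocessing

An intra-chromosomal Hi-C contact map is a dense symmetric non-negative
matrix `C` (`N×N`) with a fixed bin size; "resolution" means effective read
depth, while the matrix dimension is its *scale*. The enhancement task maps
a 16×-shallower, 4×-coarser-binned map to the fine map.

**SCN normalization.** The literature names the method but not an
algorithm, so the package implements iterative symmetric L1 balancing: each
iteration divides the matrix by `sqrt(s) sqrt(s)ᵀ` (`s` = row sums) and
accumulates `sqrt(s)` into the bias `b`; iteration stops when every
non-empty row sums to 1 within `tol` (default 1e-6) or after `max_iter`
(default 300, `converged=False` on the best estimate). At the fixed point
the normalized map equals `C ⊘ (b bᵀ)` exactly, making the reversion the
elementwise product `X̃_ij = X_ij b_i b_j` — the two published forms of the
reversion disagree in the direction of division, so the package fixes the
convention by the round-trip identity, which is tested to 1e-8 relative
error. All-zero rows (unmappable bins) are excluded with bias 1; an
all-zero matrix raises a degenerate-input error.

**Divide and merge.** The fine map is tiled into non-overlapping blocks of
side `n/2` (trailing bins dropped, not padded); diagonal blocks `(i,i)` and
`(j,j)` are merged with their off-diagonal block `(i,j)` into one symmetric
`n×n` target. Coordinates are 0-based half-open; the genomic distance of a
pair is start-to-start, `(j−i)·(n/2)·bin_size`, and pairs beyond 2 Mb are
omitted (TADs are mostly < 1 Mb, and most significant interactions lie
inside them). The matched coarse input covers the identical span at side
`m = n/4`. Assembly back to chromosome scale copies uniquely covered
entries and averages multiply covered ones (the simplest
symmetric-consistent combiner); uncovered entries are zero and reported in
a coverage mask. `n` must be divisible by 8 so that both tilings and the
×4 pooling are exact.

## Network

All layers run on `r1hic.autodiff`, a compact vectorized reverse-mode
engine over numpy float64 (elementwise ops, matmul, shape surgery,
reductions, the needed nonlinearities, and convolution built from shifted
slices and matmuls). Gradients of every primitive are verified against
central finite differences in the test suite; computation is
single-threaded and bit-reproducible.

**Rank-1 block.** Decomposition uses a `(1, N)` vector kernel
(`N·c_in·c_out` parameters, asserted in tests), weighting forms
`V = U w wᵀ`, and reconstruction emits channels `v_k v_kᵀ`. Because
`V = U w wᵀ` makes every column proportional to the single vector `Uw`,
the block's summed reconstruction has rank ≤ 1 regardless of `c_out`; its
rank budget is therefore 1, and the training oracle compares it against
the best rank-1 truncated eigendecomposition (the Perron structure of a
non-negative symmetric matrix makes the optimum attainable under the
non-negativity activation). Non-negativity of `V` is enforced by an
absolute-value activation (softplus available as a config option).

**Generator.** G1 extracts rank-1 features from space-to-depth
rearrangements of the input at factors 2 and 4 (branch parameters
unshared); the summed reconstructions `approx2`/`approx4` are trained
against average-pooled truths. The published wiring of the combination
stage exists only in an unavailable supplement, so this package's
combination block is an explicitly labeled replacement with three standard
super-resolution ingredients:

* the multi-scale features are lifted back to the input scale by sub-pixel
  blocks and concatenated with a 1×1-projected copy of the raw input tile
  (so fine detail that the rank-1 bottleneck discards can reach the
  output);
* the output is a *residual correction* to a learned-scale
  nearest-neighbor upsample of the input; the correction head is
  zero-initialized, so training starts exactly at the scaled passthrough
  and moves away only where it lowers the loss;
* activations are internally rescaled to O(1) — inputs ×m, output ÷4m —
  because row-normalized entries scale as 1/side; without this the output
  nonlinearity operates in its vanishing-gradient tail.

Ablations at desk scale showed that without these the generator converges
to a blurry conditional mean whose stratum-adjusted correlation falls
below the nearest-neighbor baseline. Each upsampling block is a
convolution, a ×2 pixel shuffle, and an average with the transpose, so the
final `4m×4m` output is exactly symmetric; the output activation is an
absolute value (softplus and ReLU are options — ReLU proved fragile: under
adversarial pressure the whole output can die at zero with no recovery
gradient, and softplus attenuates small values exponentially, defeating
the passthrough).

**Discriminator.** Rank-1 features are extracted from the candidate and
its ×2/×4/×8 space-to-depth views; a cascade of convolutional blocks
(leaky ReLU, 2×2 max-pool, 3×3 convolution, widths 16/32/64 by default)
concatenates finer features with the next coarser scale and ends in a
fully connected sigmoid head. The layer sizes are the package's own
defaults (the original sizes are not public); everything is overridable
through `NetworkConfig`.

## Losses

`ℓ_G1 = Σ w_k [MSE + DSSIM]` with `w_k = f_k²/Σf_j²`; SSIM uses a uniform
7×7 window, valid window positions, unbiased covariance and a dynamic
range of 1 (entries are row-normalized to [0, 1]) — it matches the
scikit-image reference to 1e-6 and is differentiable through the autodiff
engine. `ℓ_G2 = α₀·MSE + α₁·(−log D)` with α₀ = 10, α₁ = 0.1;
`ℓ_D = −log D(real) − log(1 − D(fake))`. Probabilities are clipped at 1e-7
before any logarithm.

## Training

Each step runs three separate backpropagations: ℓ_G1 → G1 blocks,
ℓ_G2 → G2 path (gradients blocked from G1; a config switch restores joint
flow), ℓ_D → discriminator on the real target and the detached prediction,
in that order, one discriminator step per generator step. The optimizer is
Adam at 1e-3 for all three groups (the canonical default; no optimizer is
prescribed by the method's description).

**Adversarial schedule.** A desk-scale run of a few hundred steps cannot
approach a GAN equilibrium: trained jointly from the start, the saturated
discriminator's `−log D` gradient (spikes of order 1/p) destroys the
pixel-loss solution. `fit` therefore supports the usual two-phase schedule
— `adv_warmup_epochs` of pixel-loss-only training for G2, then adversarial
fine-tuning with the G2 step decayed by `adv_lr_factor` (default 0.01,
chosen from a cross-seed stability sweep). The discriminator trains
throughout. `TrainConfig.toy_profile()` packages the desk-scale setting:
30 epochs, batch size 1, 25 warmup + 5 adversarial epochs.

**Prediction.** A raw coarse map is normalized internally, tiled, enhanced,
and stitched; if a fine-map bias vector is supplied (the evaluation
setting) the output is de-normalized with it, otherwise a surrogate is
derived from the input's own bias — each coarse bias spread over its four
fine bins (÷4) and scaled by `sqrt(ratio)` to undo the depth difference.

## Synthetic data

`SyntheticSpec` defines a Poisson field
`λ_ij ∝ (1+|i−j|)^(−α) · enrichment^[same TAD] · (1 + loop strength)`
scaled to a total expected depth; counts are drawn on the upper triangle
and mirrored. Defaults — 512 bins at 10 kb, α = 1, eight equal TADs with
enrichment 3, depth 2×10⁶ — give a map in which decay, domain structure
and thinning effects are clearly resolved at desk scale. Low-resolution
twins are produced by binomial thinning (each read kept with probability
1/ratio — exact read-subsampling semantics, integer-preserving; diagonal
entries thinned once) followed by 4× sum-pool coarsening.

The generator emulates distance decay, block TADs, focal loops and
sampling noise. It does **not** emulate A/B compartment checkerboards,
mappability/GC bias fields (the SCN bias it removes is therefore mild),
translocations, or fragment-level ligation artifacts. Passing tests
demonstrate that the implementation is correct and that the architecture
can exploit multi-scale structure at small scale; they do not certify
enhancement quality on real chromosomes, which requires full-scale
training.

## Evaluation metrics

* **Banded MAE/MSE** over the ≤ 2 Mb band and the prediction's coverage
  mask (matching the band the model predicts).
* **SCC**: per-diagonal Pearson correlations combined with weights
  `n_d · sd_a(d) · sd_b(d)`; constant strata are skipped with a warning;
  optional pre-smoothing (`smooth_h`) applies a mean filter of window
  `2h+1` to both maps, off by default.
* **Reproducibility score**: both maps become row-stochastic transition
  matrices, powered to t ∈ {1, 2, 3}; the score is 1 minus the mean L1
  difference per non-empty node, averaged over t (identical maps score 1).
* **TAD boundaries**: a diamond insulation profile (window 10 bins);
  z-scored local minima below −1 are called, with a minimum separation
  keeping the deepest minimum per cluster. This caller is a deliberately
  simple stand-in for the heavier published callers.
* **Shift-tolerant Jaccard**: one-to-one matching within a 5-bin tolerance
  via a sorted greedy sweep (optimal in one dimension, verified against
  exhaustive matching); `J = matched / (|A|+|B|−matched)`.

## Problem sizes

The shipped profiles are sized for a single CPU: 512-bin chromosomes,
`n = 128` submatrices (`m = 32`), 16 training pairs, 30 epochs. All sizes
scale up through configuration (`n = 400`/`m = 100` reproduces the
published tiling).

## Known limitations

* The rank-1 weighting `V = U w wᵀ` ties all channels to one direction;
  a per-channel weighting (`V = U diag(w)`) would give a true rank-c_out
  budget but would depart from the published formula.
* The GAN phase at desk scale is a stabilized fine-tune, not an
  equilibrium; adversarial benefits (sharper textures) only emerge at
  full scale.
* The discriminator's layer sizes and the combination-block wiring are
  package choices, not reconstructions of the original supplement.
* The surrogate prediction bias (no ground-truth bias supplied) assumes
  uniform within-coarse-bin bias and exact depth scaling.
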