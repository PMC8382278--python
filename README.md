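# r1hic

Super-resolution of Hi-C contact maps with a rank-1 factorization GAN.

High-resolution Hi-C contact matrices require billions of sequenced read
pairs, so most cell types only have shallow, noisy maps. `r1hic` predicts a
fine-resolution intra-chromosomal contact matrix from a low-resolution one
(16x fewer reads, 4x coarser bins) with a generative adversarial model
built around the structure of the data: a Hi-C matrix is symmetric and
non-negative, so instead of treating it as a photograph, the network
decomposes it into **non-negative rank-1 matrix features** at several
scales and re-assembles an enhanced map from them with sub-pixel
(pixel-shuffle) convolutions. The package is aimed at computational
genomicists who want a self-contained, CPU-scale, fully testable
implementation: it ships a synthetic Hi-C generator (distance decay, TADs,
focal loops, Poisson counts, binomial read thinning) and a metric suite
(banded MAE/MSE, stratum-adjusted correlation, random-walk reproducibility,
TAD-boundary Jaccard), so every component runs and is verified without any
external data download.

## The model

**Decomposition & reconstruction block.** For an input tensor
`X ∈ R^{N×N×c_in}`, a convolution with kernel shape `(1, N)` (a vector
kernel sliding in one direction, `N·c_in·c_out` parameters) produces rank-1
feature vectors `U = [u_1 … u_cout]`. A weighting layer scales them as
`V = U w wᵀ` with a learnable `w`, and after an absolute-value activation
each output channel is reconstructed as the outer product
`X̂_::k = v_k v_kᵀ` — symmetric, entrywise non-negative, and of numerical
rank ≤ 1 by construction.

**Generator.** Part G1 rearranges the `m×m` input with space-to-depth
layers (factors 2 and 4) and extracts rank-1 features at each scale; their
summed reconstructions are trained against average-pooled ground truths
with the multi-scale loss

```
ℓ_G1 = Σ_k w_k [ MSE(Î_k, I_k) + DSSIM(Î_k, I_k) ],   w_k = f_k² / Σ_j f_j²
```

(for `f = [2, 4]`, `w = [0.2, 0.8]`; DSSIM = (1−SSIM)/2). Part G2 lifts the
multi-scale features back with sub-pixel convolutions, combines them with a
projection of the input tile, and runs two upsampling blocks (each ×2
spatial, each symmetrized by averaging with the transpose), so the output
side is 4× the input — a 16× resolution enhancement. G2 minimizes

```
ℓ_G2 = α₀ · MSE(I_SR, I_HR) + α₁ · (−log D(I_SR)),   α₀ = 10, α₁ = 0.1
```

with gradients blocked from flowing into G1 (the two losses are
backpropagated separately). The **discriminator** extracts rank-1 features
from the candidate and its ×2/×4/×8 downscaled views, passes them through
a cascade of convolutional blocks (leaky ReLU, max-pool, 3×3 convolution)
and a sigmoid head, and is trained with
`ℓ_D = −log D(I_HR) − log(1 − D(I_SR))`.

Preprocessing follows the sequential-component-normalization (SCN)
convention: iterative symmetric balancing factors the counts as
`C = X ∘ (b bᵀ)` with unit row sums in `X`; predictions are de-normalized
by the exact reversion `X̃_ij = X_ij · b_i · b_j`. Chromosome matrices are
cut into symmetric `n×n` submatrices (two diagonal half-blocks merged with
their off-diagonal block) within a 2 Mb genomic-distance band, and
predictions are stitched back by averaging overlaps.

The neural layers run on a small vectorized reverse-mode automatic
differentiation engine over numpy float64 (`r1hic.autodiff`); every
gradient is verified against finite differences in the test suite.

## Worked example

The five pipeline stages are exposed both as a library and as the `r1hic`
command. The toy profile (512-bin chromosome at 10 kb, 2×10⁶ read pairs,
16× thinning) runs end to end in a few minutes on one CPU:

```sh
r1hic simulate   --seed 1 --bins 512 --depth 2e6 --ratio 16 --out-dir runs/sim
r1hic preprocess --hr runs/sim/hr.npz --lr runs/sim/lr.npz --sub-size 128 \
                 --out-dir runs/prep
r1hic train      --dataset runs/prep/dataset.npz --epochs 30 --seed 0 \
                 --out-dir runs/train
r1hic predict    --model runs/train/model_final.npz --lr runs/sim/lr.npz \
                 --out-dir runs/pred
r1hic evaluate   --pred runs/pred/prediction.npz --truth runs/sim/hr.npz \
                 --out-dir runs/eval
```

The same computation through the library (as performed by
`scripts/acceptance.py --seed 1`) prints:

```
toy_overfit_mse_model        3.88e-06     # pixel MSE of the prediction
toy_overfit_mse_nn_baseline  2.01e-03     # MSE of nearest-neighbor upsampled input
toy_overfit_scc_model        0.720        # stratum-adjusted correlation vs truth
toy_overfit_scc_nn_baseline  0.551        # same for the baseline
chromosome_scc               0.639        # assembled chromosome-scale prediction
chromosome_disco             0.807        # random-walk reproducibility score
chromosome_tad_boundary_jaccard  1.0      # insulation boundaries, 5-bin tolerance
```

Reading: after the 30-epoch desk-scale run the model's prediction is ~500×
closer to the true fine map in pixel error than simply upsampling the
input, and correlates better with it along every distance stratum; the
boundaries of the simulated TADs are recovered exactly.

Contact maps are exchanged as NPZ or dense TSV dumps and single-resolution
`.cool` (HDF5) files; bias vectors export as BED-like TSV.

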