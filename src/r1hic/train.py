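"""Adversarial training loop and end-to-end prediction.

Each optimization step performs three separate backpropagations, one per
parameter group:

1. the rank-1 extraction loss ``l_G1`` (multi-scale MSE + DSSIM against the
   average-pooled ground truths) updates the G1 decomposition blocks;
2. the enhancement loss ``l_G2 = alpha0 * MSE + alpha1 * (-log D(sr))``
   updates the G2 path, with gradients blocked from flowing into G1 (a
   config switch re-enables joint flow);
3. the discriminator loss ``l_D = -log D(hr) - log(1 - D(sr))`` updates the
   discriminator on the real target and the detached prediction.

Updates use Adam; the whole fit is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Parameter, Tensor
from .hicdata import (
    BiasVector,
    ContactMap,
    SubmatrixPair,
    assemble_prediction,
    enumerate_block_pairs,
    _merge_blocks,
    scn_denormalize,
    scn_normalize,
)
from .losses import LossWeights, loss_d, loss_g1, loss_g2
from .network import HiCGan, NetworkConfig

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train_step", "fit", "predict"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The adversarial weights default to ``alpha0 = 10`` and ``alpha1 = 0.1``;
    300 epochs is the full-scale setting — desk-scale runs use far fewer.
    The Adam step size defaults to 1e-3 for all three parameter groups.
    """

    epochs: int = 300
    batch_size: int = 4
    lr_g1: float = 1e-3
    lr_g2: float = 1e-3
    lr_d: float = 1e-3
    alpha0: float = 10.0
    alpha1: float = 0.1
    seed: int = 0
    checkpoint_every: int = 0  # epochs; 0 disables
    run_dir: str | None = None
    block_g1_gradients: bool = True
    dssim_window: int = 7
    # Adversarial schedule: the enhancement path is pretrained with the
    # pixel loss alone for `adv_warmup_epochs`, then the adversarial term is
    # switched on with the G2 step size decayed by `adv_lr_factor` — the
    # usual GAN fine-tuning schedule; the discriminator trains throughout.
    adv_warmup_epochs: int = 0
    adv_lr_factor: float = 0.01

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.lr_g1, self.lr_g2, self.lr_d) <= 0:
            raise ValueError("learning rates must be positive")
        if self.adv_warmup_epochs < 0 or self.adv_lr_factor <= 0:
            raise ValueError("invalid adversarial schedule")

    @classmethod
    def toy_profile(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale training profile: 30 epochs on a handful of
        submatrices, single-sample batches, 25 pixel-loss warmup epochs
        followed by 5 adversarial fine-tuning epochs."""
        base = dict(epochs=30, batch_size=1, adv_warmup_epochs=25, seed=seed)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainHistory:
    """Per-step loss records."""

    records: list[dict] = field(default_factory=list)

    def append(self, rec: dict) -> None:
        rec = dict(rec, step=len(self.records))
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records])

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


class Adam:
    """Adaptive-moment optimizer over an explicit parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack(batch: list[SubmatrixPair], attr: str) -> np.ndarray:
    return np.stack([getattr(p, attr) for p in batch])


def train_step(
    batch: list[SubmatrixPair],
    model: HiCGan,
    optimizers: dict[str, Adam],
    weights: LossWeights,
    block_g1_gradients: bool = True,
    dssim_window: int = 7,
) -> dict:
    """One three-part optimization step on a batch; returns the loss record."""
    G, D = model.generator, model.discriminator
    lr_in = _stack(batch, "lr_input")
    hr = _stack(batch, "hr_target")
    down2 = _stack(batch, "lr_down2")
    down4 = _stack(batch, "lr_down4")

    out = G.forward(lr_in, detach_features=block_g1_gradients)
    # (1) rank-1 extraction loss -> G1 parameters.  With the gradient block
    # on, G2 consumed detached copies, so this backward touches G1 only; the
    # approximations themselves always stay attached to G1.
    lg1 = loss_g1(
        [out.approx2, out.approx4], [Tensor(down2), Tensor(down4)],
        f=model.config.gen_factors, window=dssim_window,
    )
    optimizers["g1"].zero_grad()
    lg1.backward()
    optimizers["g1"].step()

    # (2) enhancement + adversarial loss -> G2 parameters
    p_fake = D.forward(out.sr)
    lg2 = loss_g2(out.sr, Tensor(hr), p_fake, weights)
    optimizers["g2"].zero_grad()
    optimizers["d"].zero_grad()  # D saw sr; discard its gradients here
    if not block_g1_gradients:
        optimizers["g1"].zero_grad()
    lg2.backward()
    optimizers["g2"].step()

    # (3) discriminator loss on the real target and the detached prediction
    p_real = D.forward(hr)
    p_fake_d = D.forward(out.sr.detach())
    ld = loss_d(p_real, p_fake_d)
    optimizers["d"].zero_grad()
    ld.backward()
    optimizers["d"].step()

    rec = {
        "loss_g1": lg1.item(),
        "loss_g2": lg2.item(),
        "loss_d": ld.item(),
        "p_real": float(np.mean(p_real.data)),
        "p_fake": float(np.mean(p_fake_d.data)),
    }
    if not all(np.isfinite(v) for v in rec.values()):
        raise FloatingPointError(f"non-finite loss encountered: {rec}")
    return rec


def make_optimizers(model: HiCGan, config: TrainConfig) -> dict[str, Adam]:
    return {
        "g1": Adam(model.generator.g1_params(), lr=config.lr_g1),
        "g2": Adam(model.generator.g2_params(), lr=config.lr_g2),
        "d": Adam(model.discriminator.params(), lr=config.lr_d),
    }


def fit(
    dataset: list[SubmatrixPair],
    config: TrainConfig,
    net_config: NetworkConfig | None = None,
) -> tuple[HiCGan, TrainHistory]:
    """Train a fresh model on the dataset; bit-reproducible given the seed."""
    if not dataset:
        raise ValueError("dataset must be non-empty")
    m = dataset[0].m
    net_config = net_config or NetworkConfig(m=m, seed=config.seed)
    if net_config.m != m:
        raise ValueError(f"network expects m={net_config.m}, dataset has m={m}")
    model = HiCGan(net_config)
    optimizers = make_optimizers(model, config)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    for epoch in range(1, config.epochs + 1):
        adversarial = epoch > config.adv_warmup_epochs
        weights = LossWeights(
            f=net_config.gen_factors,
            alpha0=config.alpha0,
            alpha1=config.alpha1 if adversarial else 0.0,
        )
        if config.adv_warmup_epochs and epoch == config.adv_warmup_epochs + 1:
            optimizers["g2"].lr = config.lr_g2 * config.adv_lr_factor
        order = rng.permutation(len(dataset))
        for lo in range(0, len(dataset), config.batch_size):
            batch = [dataset[i] for i in order[lo : lo + config.batch_size]]
            rec = train_step(
                batch, model, optimizers, weights,
                block_g1_gradients=config.block_g1_gradients,
                dssim_window=config.dssim_window,
            )
            history.append(dict(rec, epoch=epoch))
        if (
            config.checkpoint_every
            and config.run_dir
            and epoch % config.checkpoint_every == 0
        ):
            os.makedirs(config.run_dir, exist_ok=True)
            model.save(os.path.join(config.run_dir, f"checkpoint_{epoch:04d}.npz"))
    if config.run_dir:
        os.makedirs(config.run_dir, exist_ok=True)
        model.save(os.path.join(config.run_dir, "model_final.npz"))
        history.to_jsonl(os.path.join(config.run_dir, "history.jsonl"))
        with open(os.path.join(config.run_dir, "train_config.json"), "w") as fh:
            json.dump(asdict(config), fh, indent=2)
    return model, history


def predict(
    model: HiCGan,
    lr_map: ContactMap,
    hr_bias: BiasVector | None = None,
    normalized: bool = False,
    max_distance_bp: int = 2_000_000,
    ratio: int = 16,
    batch_size: int = 4,
) -> tuple[ContactMap, np.ndarray]:
    """Enhance a whole low-resolution chromosome map.

    The map is SCN-normalized (unless already normalized), cut into
    symmetric ``m x m`` submatrices on the distance band, run through the
    generator, and the ``4m x 4m`` predictions are stitched back into a
    ``4N x 4N`` fine-binned map.  If an ``hr_bias`` (estimated from ground
    truth at the fine binning) is given the output is denormalized with it;
    otherwise a surrogate bias is derived from the input map's own bias:
    each coarse-bin bias is spread over its four fine bins (divided by 4,
    since coarsening sums 4x4 fine entries) and scaled by ``sqrt(ratio)`` to
    undo the depth difference.

    Returns the predicted map and its coverage mask.
    """
    m = model.config.m
    if normalized:
        norm, lr_bias = lr_map, None
    else:
        norm, lr_bias = scn_normalize(lr_map)
    half = m // 2
    nblocks = norm.N // half
    pairs = [
        p
        for p in enumerate_block_pairs(norm.N, half, norm.bin_size, max_distance_bp)
        if p[1] < nblocks
    ]
    if not pairs:
        raise ValueError(f"map with {norm.N} bins too small for m={m}")
    preds: list[tuple[tuple[int, int], np.ndarray]] = []
    for lo in range(0, len(pairs), batch_size):
        chunk = pairs[lo : lo + batch_size]
        tiles = np.stack(
            [_merge_blocks(norm.counts, half, i, j) for (i, j) in chunk]
        )
        sr = model.generator.forward(tiles).sr.data
        preds.extend(zip(chunk, sr))
    N_hr = 4 * nblocks * half
    bin_hr = lr_map.bin_size // 4
    assembled, mask = assemble_prediction(
        preds, N_hr, bin_size=bin_hr, chrom=lr_map.chrom
    )
    if hr_bias is None and lr_bias is not None:
        b_hr = np.repeat(lr_bias.b[: nblocks * half], 4) * (np.sqrt(ratio) / 4.0)
        hr_bias = BiasVector(b=b_hr, converged=lr_bias.converged,
                             iterations=lr_bias.iterations)
    if hr_bias is not None:
        counts = scn_denormalize(assembled.counts, hr_bias)
        assembled = ContactMap(assembled.chrom, assembled.bin_size, counts)
    return assembled, mask
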