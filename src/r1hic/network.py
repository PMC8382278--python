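"""Neural architecture for contact-map super-resolution.

The model is a generative adversarial pair built around a *rank-1
decomposition and reconstruction block* that respects the two structural
properties of a Hi-C matrix — symmetry and non-negativity:

* **decomposition**: a convolution with kernel shape ``(1, N)`` (the kernel
  is a vector spanning the full matrix width, sliding in one direction only)
  maps an ``N x N x c_in`` tensor to rank-1 feature vectors
  ``U = [u_1 ... u_cout]``, with exactly ``N * c_in * c_out`` parameters;
* **weighting**: ``V = U w w^T`` with a learnable weight vector ``w``;
* **reconstruction**: channel ``k`` of the output is the outer product
  ``v_k v_k^T`` — symmetric and, after the non-negativity activation on
  ``V``, entrywise >= 0 and of numerical rank <= 1 by construction.

The generator has two parts.  G1 downscales the low-resolution input by
average pooling (factors 2 and 4), rearranges each view with a
space-to-depth layer and extracts rank-1 features whose summed
reconstructions (``approx2``, ``approx4``) are trained against the pooled
ground truths.  G2 recombines the multi-scale features (sub-pixel upsampling
back to the input scale, channel concatenation, 1x1 convolution) and runs
two upsampling blocks — each a convolution followed by a pixel shuffle (x2)
and an average with the transpose — so the output side is 4x the input
(a 16x resolution enhancement), symmetric and ReLU-non-negative.

The discriminator extracts rank-1 features from the candidate matrix and
its 2/4/8-downscaled views, runs them through a cascade of convolutional
blocks (leaky ReLU, max pool, 3x3 convolution; finer features concatenated
with the next coarser scale) and ends in a fully connected sigmoid head that
scores the probability the candidate is real data.

Tensors are channels-last ``(batch, H, W, C)`` float64 numpy arrays wrapped
in autodiff tensors; everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Parameter, Tensor, astensor, concatenate

__all__ = [
    "NetworkConfig",
    "Rank1Bundle",
    "GeneratorOutput",
    "Rank1Block",
    "Generator",
    "Discriminator",
    "HiCGan",
    "conv2d",
    "space_to_depth",
    "depth_to_space",
    "avgpool_downscale",
    "subpixel_upsample",
]


# ---------------------------------------------------------------------------
# Functional layers
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, kernel: Tensor, bias: Tensor | None = None,
           padding: str = "same") -> Tensor:
    """2D convolution on a channels-last ``(B, H, W, Cin)`` tensor with a
    ``(kh, kw, Cin, Cout)`` kernel, stride 1."""
    x = astensor(x)
    kh, kw, cin, cout = kernel.shape
    if x.shape[-1] != cin:
        raise ValueError(f"input has {x.shape[-1]} channels, kernel expects {cin}")
    if padding == "same":
        if kh != kw or kh % 2 == 0:
            raise ValueError("'same' padding needs an odd square kernel")
        if kh > 1:
            x = x.pad2d(kh // 2, axes=(1, 2))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    B, H, W, _ = x.shape
    hout, wout = H - kh + 1, W - kw + 1
    out = None
    for di in range(kh):
        for dj in range(kw):
            patch = x[:, di : di + hout, dj : dj + wout, :]
            w = kernel[di, dj]  # (Cin, Cout)
            term = patch.reshape(B * hout * wout, cin) @ w
            out = term if out is None else out + term
    out = out.reshape(B, hout, wout, cout)
    if bias is not None:
        out = out + bias
    return out


def space_to_depth(x: Tensor, r: int) -> Tensor:
    """Rearrange ``(B, H, W, C) -> (B, H/r, W/r, C*r^2)`` losslessly."""
    x = astensor(x)
    B, H, W, C = x.shape
    if H % r or W % r:
        raise ValueError(f"factor {r} does not divide spatial size {(H, W)}")
    y = x.reshape(B, H // r, r, W // r, r, C)
    y = y.transpose(0, 1, 3, 2, 4, 5)
    return y.reshape(B, H // r, W // r, r * r * C)


def depth_to_space(x: Tensor, r: int) -> Tensor:
    """Pixel shuffle, the exact inverse of :func:`space_to_depth`."""
    x = astensor(x)
    B, H, W, C = x.shape
    if C % (r * r):
        raise ValueError(f"channel count {C} not divisible by r^2={r * r}")
    c = C // (r * r)
    y = x.reshape(B, H, W, r, r, c)
    y = y.transpose(0, 1, 3, 2, 4, 5)
    return y.reshape(B, H * r, W * r, c)


def avgpool_downscale(x, f: int):
    """Average-pool an ``N x N`` matrix (or ``(B, H, W[, C])`` tensor) over
    ``f x f`` blocks; symmetric input yields symmetric output."""
    if isinstance(x, Tensor) or np.ndim(x) > 2:
        t = astensor(x)
        squeeze = False
        if t.ndim == 3:  # (B, H, W)
            t = t.reshape(*t.shape, 1)
            squeeze = True
        B, H, W, C = t.shape
        if H % f or W % f:
            raise ValueError(f"factor {f} does not divide spatial size {(H, W)}")
        y = t.reshape(B, H // f, f, W // f, f, C).mean(axis=(2, 4))
        return y.reshape(B, H // f, W // f) if squeeze else y
    x = np.asarray(x, dtype=np.float64)
    n, m = x.shape
    if n % f or m % f:
        raise ValueError(f"factor {f} does not divide matrix side {(n, m)}")
    return x.reshape(n // f, f, m // f, f).mean(axis=(1, 3))


def _maxpool2(x: Tensor) -> Tensor:
    B, H, W, C = x.shape
    y = x.reshape(B, H // 2, 2, W // 2, 2, C)
    return y.max(axis=4).max(axis=2)


def symmetrize(x: Tensor) -> Tensor:
    """Average a ``(B, H, W, C)`` (or ``(B, H, W)``) tensor with its spatial
    transpose; the result equals its transpose exactly."""
    return (x + x.swapaxes(1, 2)) * 0.5


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``m`` is the low-resolution input side (must be divisible by 8 so the
    multi-scale branches and the discriminator cascade tile evenly);
    ``c_out`` is the channel count of every decomposition block;
    ``gen_channels`` the working width of the enhancement path;
    ``disc_widths`` the convolutional widths of the discriminator cascade.
    """

    m: int = 100
    c_out: int = 8
    gen_channels: int = 8
    disc_widths: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    activation: str = "abs"  # non-negativity activation on V: abs | softplus
    final_activation: str = "abs"  # output non-negativity: abs | softplus | relu
    gen_factors: tuple[int, ...] = (2, 4)
    disc_factors: tuple[int, ...] = (1, 2, 4, 8)
    input_skip: bool = True  # feed the raw input tile into the combination block
    residual_skip: bool = True  # predict a correction to a scaled NN-upsample
    seed: int = 0

    def __post_init__(self):
        if self.m % 4:
            # the x4 branch tiles m; the discriminator's x8 space-to-depth
            # and cascade tile 4m — both need m divisible by 4
            raise ValueError("m must be divisible by 4")
        if self.activation not in ("abs", "softplus"):
            raise ValueError("activation must be 'abs' or 'softplus'")
        if self.final_activation not in ("softplus", "relu", "abs"):
            raise ValueError("final_activation must be 'softplus', 'relu' or 'abs'")
        if min(self.c_out, self.gen_channels, *self.disc_widths) < 1:
            raise ValueError("channel widths must be positive")


@dataclass
class Rank1Bundle:
    """Feature tensors of one decomposition & reconstruction block."""

    U: Tensor      # (B, N, c_out) rank-1 feature vectors
    w: Tensor      # (c_out,) learnable weights
    V: Tensor      # (B, N, c_out) weighted, non-negative features
    X_hat: Tensor  # (B, N, N, c_out), channel k = outer(v_k, v_k)

    @property
    def approx(self) -> Tensor:
        """Summed reconstruction ``sum_k v_k v_k^T`` as a (B, N, N) matrix."""
        return self.X_hat.sum(axis=-1)


@dataclass
class GeneratorOutput:
    sr: Tensor       # (B, 4m, 4m) super-resolution prediction
    approx2: Tensor  # (B, m/2, m/2) rank-1 approximation of the x2 view
    approx4: Tensor  # (B, m/4, m/4) rank-1 approximation of the x4 view


# ---------------------------------------------------------------------------
# Parameterized blocks
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Minimal parameter container."""

    def named_params(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.named_params().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.named_params().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def params(self) -> list[Parameter]:
        return list(self.named_params().values())


class Rank1Block(Module):
    """Decomposition & reconstruction block (see module docstring)."""

    def __init__(self, N: int, c_in: int, c_out: int,
                 rng: np.random.Generator, activation: str = "abs"):
        self.N, self.c_in, self.c_out = N, c_in, c_out
        self.activation = activation
        # (1, N) decomposition kernel: N * c_in * c_out shared parameters
        self.kernel = Parameter(_he_init(rng, (N * c_in, c_out), N * c_in))
        self.w = Parameter(rng.normal(1.0, 0.1, size=c_out))

    @property
    def num_decomposition_params(self) -> int:
        return self.kernel.size

    def forward(self, x) -> Rank1Bundle:
        x = astensor(x)
        B, N, N2, c_in = x.shape
        if N != self.N or N2 != self.N or c_in != self.c_in:
            raise ValueError(
                f"expected input (B, {self.N}, {self.N}, {self.c_in}), got {x.shape}"
            )
        U = x.reshape(B, N, N * c_in) @ self.kernel          # (B, N, c_out)
        ww = self.w.reshape(self.c_out, 1) @ self.w.reshape(1, self.c_out)
        V = U @ ww                                           # (B, N, c_out)
        V = V.abs() if self.activation == "abs" else V.softplus()
        cols = V.transpose(0, 2, 1).reshape(B * self.c_out, N, 1)
        outer = cols @ cols.swapaxes(1, 2)                   # (B*c_out, N, N)
        X_hat = outer.reshape(B, self.c_out, N, N).transpose(0, 2, 3, 1)
        return Rank1Bundle(U=U, w=self.w, V=V, X_hat=X_hat)


class _Conv(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: str = "same"):
        self.padding = padding
        self.kernel = Parameter(_he_init(rng, (k, k, c_in, c_out), k * k * c_in))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.kernel, self.bias, padding=self.padding)


class SubpixelUpsample(Module):
    """Upsampling block: convolution to ``c_out * r^2`` channels, pixel
    shuffle by ``r``, then an average with the transpose to enforce exact
    output symmetry."""

    def __init__(self, c_in: int, c_out: int, r: int, k: int,
                 rng: np.random.Generator):
        self.r = r
        self.conv = _Conv(c_in, c_out * r * r, k, rng)

    def forward(self, x: Tensor) -> Tensor:
        return symmetrize(depth_to_space(self.conv.forward(x), self.r))


def subpixel_upsample(x, kernel: Tensor, r: int, bias: Tensor | None = None) -> Tensor:
    """Functional form: convolve, pixel-shuffle by ``r``, symmetrize."""
    h = conv2d(astensor(x), kernel, bias)
    return symmetrize(depth_to_space(h, r))


class Generator(Module):
    """Two-part generator: multi-scale rank-1 extraction (G1) followed by
    sub-pixel enhancement to 4x the spatial side (G2)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        m, c, g = config.m, config.c_out, config.gen_channels
        k = config.kernel_size
        # --- G1: one decomposition block per downscale factor (unshared)
        self.rank1_blocks = [
            Rank1Block(m // r, r * r, c, rng, config.activation)
            for r in config.gen_factors
        ]
        # --- G2: bring each scale back to side m, combine, then upsample x4
        self.scale_up = [
            SubpixelUpsample(c, g, r, 1, rng) for r in config.gen_factors
        ]
        # combination block: rank-1 features lifted back to side m, plus
        # (optionally) a projection of the raw input tile so fine-scale
        # detail that the rank-1 bottleneck discards can reach the output
        n_groups = len(config.gen_factors) + (1 if config.input_skip else 0)
        if config.input_skip:
            self.input_proj = _Conv(1, g, 1, rng)
        self.combine = _Conv(g * n_groups, g, 1, rng)
        self.up1 = SubpixelUpsample(g, g, 2, k, rng)
        self.up2 = SubpixelUpsample(g, g, 2, k, rng)
        self.head = _Conv(g, 1, 1, rng)
        if config.residual_skip:
            # zero-init the correction head: the generator starts exactly at
            # the scaled nearest-neighbor passthrough and training can only
            # move away where it reduces the loss
            self.head.kernel.data[:] = 0.0
            # the output is a learned correction to a nearest-neighbor
            # upsample of the input; with the internal O(1) rescaling the
            # expected passthrough coefficient is 1 (a coarse entry pools
            # 4x4 fine entries but its normalized rows are 4x shorter)
            self.skip_scale = Parameter(np.array(1.0))

    def g1_params(self) -> list[Parameter]:
        return [p for blk in self.rank1_blocks for p in blk.params()]

    def g2_params(self) -> list[Parameter]:
        g1 = {id(p) for p in self.g1_params()}
        return [p for p in self.params() if id(p) not in g1]

    def forward(self, lr, detach_features: bool = False) -> GeneratorOutput:
        """Run the generator on a ``(B, m, m)`` (or ``m x m``) input.

        With ``detach_features=True`` the enhancement path G2 receives the
        rank-1 reconstructions as constants, so gradients of the G2 loss
        cannot flow into G1 parameters (the two losses are backpropagated
        separately).
        """
        x = astensor(lr)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        m = self.config.m
        if x.shape[1] != m or x.shape[2] != m:
            raise ValueError(f"expected input side {m}, got {x.shape[1:]}")
        x4 = x.reshape(*x.shape, 1)  # (B, m, m, 1)
        approxes: list[Tensor] = []
        feats: list[Tensor] = []
        for r, blk in zip(self.config.gen_factors, self.rank1_blocks):
            bundle = blk.forward(space_to_depth(x4, r))
            approxes.append(bundle.approx)
            feats.append(bundle.X_hat)
        if detach_features:
            feats = [f.detach() for f in feats]
        # Row-sum-normalized entries scale as 1/side, so the enhancement
        # path works on activations rescaled to O(1) (inputs times m, output
        # divided by 4m); this keeps the output nonlinearity in its linear
        # regime instead of the vanishing-gradient tail.
        scale = float(m)
        lifted = [up.forward(f * scale) for up, f in zip(self.scale_up, feats)]
        if self.config.input_skip:
            lifted.append(self.input_proj.forward(x4 * scale))
        h = self.combine.forward(concatenate(lifted, axis=-1))
        h = self.up1.forward(h)
        h = self.up2.forward(h)
        pre = self.head.forward(h)
        if self.config.residual_skip:
            # exact nearest-neighbor upsample: replicate the single channel
            # r^2 times and pixel-shuffle
            nn_up = depth_to_space(concatenate([x4 * scale] * 16, axis=-1), 4)
            pre = pre + self.skip_scale * nn_up
        pre = symmetrize(pre)
        # softplus/abs keep the output non-negative with gradients that never
        # vanish; relu is available but can leave the whole output dead at
        # zero under adversarial pressure
        act = self.config.final_activation
        if act == "softplus":
            sr = pre.softplus()
        elif act == "abs":
            sr = pre.abs()
        else:
            sr = pre.relu()
        sr = sr * (1.0 / (4.0 * scale))
        sr = sr.reshape(sr.shape[0], 4 * m, 4 * m)
        return GeneratorOutput(sr=sr, approx2=approxes[0], approx4=approxes[1])


class Discriminator(Module):
    """Multi-scale rank-1 feature extractor with a convolutional cascade and
    a fully connected sigmoid head scoring P(input is real)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed + 1)
        S = 4 * config.m
        if S % max(config.disc_factors) or S % (2 ** (len(config.disc_widths) + 1)):
            raise ValueError("input side incompatible with the cascade depth")
        c = config.c_out
        self.rank1_blocks = [
            Rank1Block(S // r, r * r, c, rng, config.activation)
            for r in config.disc_factors
        ]
        widths = config.disc_widths
        k = config.kernel_size
        self.convs = []
        c_cur = c
        for i, w in enumerate(widths):
            self.convs.append(_Conv(c_cur, w, k, rng))
            # after each block the features are concatenated with the next
            # coarser scale's rank-1 features (while one is available)
            c_cur = w + (c if i + 1 < len(config.disc_factors) else 0)
        self.final_conv = _Conv(c_cur, widths[-1], k, rng)
        side = S // (2 ** (len(widths) + 1))
        self.fc_w = Parameter(
            _he_init(rng, (side * side * widths[-1], 1), side * side * widths[-1])
        )
        self.fc_b = Parameter(np.zeros(1))

    def forward(self, x) -> Tensor:
        """Score a ``(B, S, S)`` or ``S x S`` candidate; returns (B,) values
        strictly inside (0, 1)."""
        x = astensor(x)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        S = 4 * self.config.m
        if x.shape[1] != S or x.shape[2] != S:
            raise ValueError(f"expected input side {S}, got {x.shape[1:]}")
        x4 = x.reshape(*x.shape, 1)
        feats = [
            blk.forward(space_to_depth(x4, r)).X_hat
            for r, blk in zip(self.config.disc_factors, self.rank1_blocks)
        ]
        h = feats[0]
        for i, conv in enumerate(self.convs):
            h = conv.forward(_maxpool2(h.leaky_relu()))
            if i + 1 < len(feats):
                h = concatenate([h, feats[i + 1]], axis=-1)
        h = self.final_conv.forward(_maxpool2(h.leaky_relu()))
        B = h.shape[0]
        logits = h.reshape(B, h.size // B) @ self.fc_w + self.fc_b
        return logits.sigmoid().reshape(B)


# ---------------------------------------------------------------------------
# Model bundle with checkpointing
# ---------------------------------------------------------------------------

@dataclass
class HiCGan:
    """Generator/discriminator pair plus its config."""

    config: NetworkConfig
    generator: Generator = field(init=False)
    discriminator: Discriminator = field(init=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.config.seed)
        self.generator = Generator(self.config, rng)
        self.discriminator = Discriminator(self.config, rng)

    def named_params(self) -> dict[str, Parameter]:
        out = {f"G.{k}": v for k, v in self.generator.named_params().items()}
        out.update(
            {f"D.{k}": v for k, v in self.discriminator.named_params().items()}
        )
        return out

    def save(self, path: str) -> None:
        """Serialize parameters and config into one NPZ container."""
        arrays = {k: p.data for k, p in self.named_params().items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "HiCGan":
        with np.load(path) as z:
            cfg_raw = json.loads(bytes(z["__config__"]).decode())
            for key in ("disc_widths", "gen_factors", "disc_factors"):
                cfg_raw[key] = tuple(cfg_raw[key])
            model = cls(NetworkConfig(**cfg_raw))
            for k, p in model.named_params().items():
                p.data = z[k].copy()
        return model

    def summary(self) -> str:
        lines = [f"HiCGan(m={self.config.m})"]
        for k, p in self.named_params().items():
            lines.append(f"  {k}: {p.shape}")
        total = sum(p.size for p in self.named_params().values())
        lines.append(f"  total parameters: {total}")
        return "\n".join(lines)
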