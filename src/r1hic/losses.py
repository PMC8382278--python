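"""Loss functions of the adversarial enhancement model.

Two generator losses drive the two training objectives:

* the multi-scale rank-1 approximation loss
  ``l_G1 = sum_k w_k [ MSE(approx_k, truth_k) + DSSIM(approx_k, truth_k) ]``
  with scale weights ``w_k = f_k^2 / sum_j f_j^2`` derived from the
  downscale factor set ``f`` (``f = [2, 4]`` gives ``[0.2, 0.8]``);
* the enhancement loss ``l_G2 = alpha0 * MSE(sr, hr) + alpha1 * l_adv`` with
  ``l_adv = -log D(sr)`` (defaults ``alpha0 = 10``, ``alpha1 = 0.1``).

The discriminator minimizes ``l_D = -log D(hr) - log(1 - D(sr))``, i.e. the
sum of two binary cross-entropies — its side of the MinMax game.

DSSIM is ``(1 - SSIM) / 2 in [0, 1]``; SSIM is computed with a uniform
window (default 7x7), valid positions only and unbiased covariance, matching
the standard reference implementations.  Every function accepts numpy
arrays or autodiff tensors; with tensors the result participates in
backpropagation (SSIM included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, astensor

__all__ = [
    "LossWeights",
    "mse",
    "ssim",
    "dssim",
    "factor_weights",
    "loss_g1",
    "bce",
    "loss_adv",
    "loss_g2",
    "loss_d",
]

_EPS = 1e-7  # probability clip before any log


@dataclass
class LossWeights:
    """Scale factors, their derived weights, and loss hyperparameters."""

    f: tuple[float, ...] = (2.0, 4.0)
    alpha0: float = 10.0
    alpha1: float = 0.1
    w: tuple[float, ...] = field(init=False)

    def __post_init__(self):
        if self.alpha0 < 0 or self.alpha1 < 0:
            raise ValueError("alpha coefficients must be >= 0")
        self.w = tuple(factor_weights(self.f))


def _wrap(args, out: Tensor):
    """Return a float unless any input was a Tensor (keeps the graph)."""
    if any(isinstance(a, Tensor) for a in args):
        return out
    return out.item()


def _check_shapes(a, b):
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if tuple(sa) != tuple(sb):
        raise ValueError(f"shape mismatch: {tuple(sa)} vs {tuple(sb)}")


def mse(a, b):
    """Mean squared elementwise difference."""
    _check_shapes(a, b)
    ta, tb = astensor(a), astensor(b)
    return _wrap((a, b), ((ta - tb) ** 2).mean())


def _uniform_filter(t: Tensor, k: int) -> Tensor:
    """Mean over every full k x k window (valid positions) of a (B, H, W)
    tensor, via two separable box sums."""
    B, H, W = t.shape
    x = t.reshape(B, H, W, 1)
    kernel_row = Tensor(np.full((1, k, 1, 1), 1.0 / k))
    kernel_col = Tensor(np.full((k, 1, 1, 1), 1.0 / k))
    from .network import conv2d  # local import to avoid a cycle

    x = conv2d(x, kernel_row, padding="valid")
    x = conv2d(x, kernel_col, padding="valid")
    return x.reshape(B, H - k + 1, W - k + 1)


def ssim(a, b, window: int = 7, data_range: float = 1.0):
    """Structural similarity with a uniform window, averaged over valid
    window positions; unbiased covariance estimates."""
    _check_shapes(a, b)
    ta, tb = astensor(a), astensor(b)
    if ta.ndim == 2:
        ta = ta.reshape(1, *ta.shape)
        tb = tb.reshape(1, *tb.shape)
    if window > min(ta.shape[1], ta.shape[2]):
        raise ValueError(f"window {window} larger than image {ta.shape[1:]}")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    np_ = window * window
    cov_norm = np_ / (np_ - 1.0)
    ua = _uniform_filter(ta, window)
    ub = _uniform_filter(tb, window)
    uaa = _uniform_filter(ta * ta, window)
    ubb = _uniform_filter(tb * tb, window)
    uab = _uniform_filter(ta * tb, window)
    va = (uaa - ua * ua) * cov_norm
    vb = (ubb - ub * ub) * cov_norm
    vab = (uab - ua * ub) * cov_norm
    num = (2.0 * ua * ub + c1) * (2.0 * vab + c2)
    den = (ua * ua + ub * ub + c1) * (va + vb + c2)
    return _wrap((a, b), (num / den).mean())


def dssim(a, b, window: int = 7, data_range: float = 1.0):
    """Structural dissimilarity ``(1 - SSIM) / 2`` in [0, 1]; 0 iff equal."""
    s = ssim(a, b, window=window, data_range=data_range)
    out = (1.0 - astensor(s)) * 0.5
    return _wrap((a, b), out)


def factor_weights(f) -> np.ndarray:
    """Scale weights ``w_k = f_k^2 / sum_j f_j^2`` (sum to one)."""
    f = np.asarray(f, dtype=np.float64)
    if f.size == 0:
        raise ValueError("factor list must be non-empty")
    if np.any(f <= 0):
        raise ValueError("factors must be positive")
    sq = f**2
    return sq / sq.sum()


def loss_g1(approx, truth, f=(2.0, 4.0), window: int = 7, data_range: float = 1.0):
    """Multi-scale rank-1 approximation loss: weighted MSE + DSSIM per scale."""
    if len(approx) != len(truth) or len(approx) != len(np.atleast_1d(f)):
        raise ValueError("approx, truth and f must have equal lengths")
    w = factor_weights(f)
    total = astensor(0.0)
    for wk, ak, tk in zip(w, approx, truth):
        win = min(window, min(np.shape(ak)[-2:]))
        term = astensor(mse(ak, tk)) + astensor(
            dssim(ak, tk, window=win, data_range=data_range)
        )
        total = total + float(wk) * term
    return _wrap(tuple(approx) + tuple(truth), total)


def bce(y, x):
    """Binary cross-entropy between labels ``y`` in {0, 1} and probabilities
    ``x`` (clipped to (eps, 1-eps) before the logs)."""
    ty = astensor(y)
    tx = astensor(x).clip(_EPS, 1.0 - _EPS)
    out = -(ty * tx.log() + (1.0 - ty) * (1.0 - tx).log()).mean()
    return _wrap((y, x), out)


def loss_adv(p_fake):
    """Generator-side adversarial loss ``-log D(sr)``; labels the generated
    samples as real to pull the discriminator's output up."""
    return bce(np.ones(np.shape(p_fake)) if np.ndim(p_fake) else 1.0, p_fake)


def loss_g2(sr, hr, p_fake, weights: LossWeights | None = None):
    """Enhancement loss ``alpha0 * MSE(sr, hr) + alpha1 * (-log D(sr))``."""
    w = weights or LossWeights()
    out = w.alpha0 * astensor(mse(sr, hr)) + w.alpha1 * astensor(loss_adv(p_fake))
    return _wrap((sr, hr, p_fake), out)


def loss_d(p_real, p_fake):
    """Discriminator loss ``bce(1, D(hr)) + bce(0, D(sr))``; minimized when
    real samples score 1 and generated samples score 0."""
    ones = np.ones(np.shape(p_real)) if np.ndim(p_real) else 1.0
    zeros = np.zeros(np.shape(p_fake)) if np.ndim(p_fake) else 0.0
    out = astensor(bce(ones, p_real)) + astensor(bce(zeros, p_fake))
    return _wrap((p_real, p_fake), out)
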