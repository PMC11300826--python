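"""The three training-loss terms and their weighted combination.

* reconstruction: expected Gaussian negative log-likelihood of the next-step
  action under the decoder.
* contrastive: pulls latents with similar cognitive-measure vectors together
  and pushes dissimilar ones beyond a margin; squared target distances are
  rescaled by the batch maximum into [0, 1] so the two terms form a convex
  combination.  The reported value is the mean over ordered pairs (i != j).
* KL: closed-form divergence of the diagonal-Gaussian posterior from N(0, I).
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from cogdrive.nn.autodiff import Tensor

__all__ = [
    "reconstruction_loss",
    "contrastive_loss",
    "contrastive_loss_bruteforce",
    "kl_regularizer",
    "total_loss",
    "scale_target_distances",
]

ArrayLike = Union[Tensor, np.ndarray, list]

_LN_2PI = math.log(2.0 * math.pi)


def _as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def reconstruction_loss(actions: ArrayLike, mean: ArrayLike,
                        log_variance: ArrayLike) -> Tensor:
    """Mean (over the batch) Gaussian negative log-likelihood of the actions.

    Per sample the NLL is summed over action dimensions:
    ``0.5 * sum_k [ logvar_k + (a_k - mu_k)^2 / exp(logvar_k) + ln(2 pi) ]``.
    """
    a = np.atleast_2d(np.asarray(actions.data if isinstance(actions, Tensor)
                                 else actions, dtype=float))
    mu = _as_tensor(mean)
    lv = _as_tensor(log_variance)
    if mu.data.ndim == 1:
        mu = mu.reshape(1, -1)
        lv = lv.reshape(1, -1)
    if a.shape != mu.data.shape:
        raise ValueError(f"actions {a.shape} vs decoded mean {mu.data.shape}")
    diff = Tensor(a) - mu
    per_sample = ((lv + diff**2 * (-lv).exp()) * 0.5 + 0.5 * _LN_2PI).sum(axis=1)
    return per_sample.mean()


def scale_target_distances(y: np.ndarray) -> np.ndarray:
    """Pairwise squared distances of target vectors, rescaled by the batch
    maximum and clamped into [0, 1]."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d2 = ((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
    m = d2.max()
    if m > 0:
        d2 = d2 / m
    return np.clip(d2, 0.0, 1.0)


def contrastive_loss(
    batch_z: ArrayLike,
    batch_y: ArrayLike,
    epsilon: float = 1.0,
    distance_measure: str = "euclidean",
    rescale_targets: bool = True,
) -> Tensor:
    """Contrastive loss with continuous targets, averaged over ordered pairs.

    For each ordered pair (i, j), i != j::

        (1 - w_ij) * l(z_i, z_j)^2 + w_ij * max(0, epsilon - l(z_i, z_j))^2

    where ``w_ij`` is the (rescaled) squared distance between the subjects'
    standardized cognitive-measure vectors and ``l`` is Euclidean distance.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if distance_measure != "euclidean":
        raise NotImplementedError(f"distance_measure {distance_measure!r}")
    z = _as_tensor(batch_z)
    if z.data.ndim == 1:
        z = z.reshape(1, -1)
    B, d = z.data.shape
    if B < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    y = np.atleast_2d(np.asarray(batch_y.data if isinstance(batch_y, Tensor)
                                 else batch_y, dtype=float))
    if y.shape[0] != B:
        raise ValueError("batch_y must have one row per latent")
    w = scale_target_distances(y) if rescale_targets else np.clip(
        ((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2), 0.0, 1.0)

    zi = z.reshape(B, 1, d)
    zj = z.reshape(1, B, d)
    sq = ((zi - zj) ** 2).sum(axis=2)          # (B, B) squared distances
    dist = (sq + 1e-16).sqrt()
    hinge = (epsilon - dist).maximum(0.0)
    pair_losses = sq * (1.0 - w) + hinge**2 * w
    mask = 1.0 - np.eye(B)
    return (pair_losses * mask).sum() * (1.0 / (B * (B - 1)))


def contrastive_loss_bruteforce(
    batch_z: np.ndarray,
    batch_y: np.ndarray,
    epsilon: float = 1.0,
    rescale_targets: bool = True,
) -> float:
    """Independent double-loop reference implementation (no autodiff)."""
    z = np.atleast_2d(np.asarray(batch_z, dtype=float))
    y = np.atleast_2d(np.asarray(batch_y, dtype=float))
    B = z.shape[0]
    if B < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    d2max = 0.0
    for i in range(B):
        for j in range(B):
            d2max = max(d2max, float(((y[i] - y[j]) ** 2).sum()))
    total = 0.0
    for i in range(B):
        for j in range(B):
            if i == j:
                continue
            w = float(((y[i] - y[j]) ** 2).sum())
            if rescale_targets and d2max > 0:
                w = w / d2max
            w = min(max(w, 0.0), 1.0)
            l = math.sqrt(float(((z[i] - z[j]) ** 2).sum()) + 1e-16)
            total += (1.0 - w) * l * l + w * max(0.0, epsilon - l) ** 2
    return total / (B * (B - 1))


def kl_regularizer(mean: ArrayLike, log_variance: ArrayLike = None) -> Tensor:
    """KL( N(mu, diag(exp(lv))) || N(0, I) ), closed form, batch-averaged.

    ``0.5 * sum_i (exp(lv_i) + mu_i^2 - 1 - lv_i)``; accepts a
    :class:`~cogdrive.nn.layers.LatentEncoding` or (mean, log_variance).
    """
    if log_variance is None:  # a LatentEncoding-like object
        mean, log_variance = mean.mean, mean.log_variance
    mu = _as_tensor(mean)
    lv = _as_tensor(log_variance)
    if mu.data.ndim == 1:
        mu = mu.reshape(1, -1)
        lv = lv.reshape(1, -1)
    per_sample = ((lv.exp() + mu**2 - 1.0 - lv) * 0.5).sum(axis=1)
    return per_sample.mean()


def total_loss(l1: ArrayLike, l2: ArrayLike, l3: ArrayLike,
               alpha1: float, alpha2: float, alpha3: float) -> Tensor:
    """Weighted sum ``alpha1*L1 + alpha2*L2 + alpha3*L3``."""
    if min(alpha1, alpha2, alpha3) < 0:
        raise ValueError("loss weights must be >= 0")
    return _as_tensor(l1) * alpha1 + _as_tensor(l2) * alpha2 + _as_tensor(l3) * alpha3
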