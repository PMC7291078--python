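"""Reconstruction losses for the three autoencoder variants.

Per cell, with x the clean normalized expression vector and x' the network
output:

* ``sdae``   — plain MSE over all genes, (1/n) sum_j (x_j - x'_j)^2.
* ``sdae0``  — MSE restricted to the observed genes {j : x_j > 0}.
* ``scsdae`` — the mixture loss: observed-gene MSE plus
  alpha * mean_{j : x_j = 0} |x'_j|, an L1 penalty that keeps imputed
  values sparse so true zeros are not filled in.

Each ``loss_*`` returns the scalar loss for a single pair of vectors; the
``*_grad`` companions return d(loss)/d(x') for whole minibatches (cells x
genes arrays), already averaged over the batch, and are what the trainer
consumes.  Empty index sets contribute 0: a cell with no zeros has no
penalty term and a cell with no observed genes (impossible after
filtering) has no MSE term.
"""

from __future__ import annotations

import numpy as np

VARIANTS = ("scsdae", "sdae", "sdae0")


def _check(x: np.ndarray, x_prime: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    return x, x_prime


def loss_sdae(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean squared error over all features."""
    x, x_prime = _check(x, x_prime)
    return float(np.mean((x - x_prime) ** 2))


def loss_sdae0(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean squared error over observed (x > 0) features only."""
    x, x_prime = _check(x, x_prime)
    pos = x > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        return 0.0
    return float(np.sum((x[pos] - x_prime[pos]) ** 2) / n_pos)


def loss_scsdae(x: np.ndarray, x_prime: np.ndarray, alpha: float) -> float:
    """Observed-feature MSE plus alpha-weighted L1 on outputs at zeros."""
    x, x_prime = _check(x, x_prime)
    zero = x == 0
    n_zero = int(zero.sum())
    penalty = 0.0 if n_zero == 0 else float(np.sum(np.abs(x_prime[zero])) / n_zero)
    return loss_sdae0(x, x_prime) + alpha * penalty


# ---------------------------------------------------------------------------
# Batched losses and gradients (mean of the per-cell loss over the batch).


def batch_loss(variant: str, X: np.ndarray, X_prime: np.ndarray, alpha: float = 0.0) -> float:
    X, X_prime = _check(X, X_prime)
    X = np.atleast_2d(X)
    X_prime = np.atleast_2d(X_prime)
    if variant == "sdae":
        per_cell = np.mean((X - X_prime) ** 2, axis=1)
    else:
        pos = X > 0
        n_pos = pos.sum(axis=1)
        sq = np.where(pos, (X - X_prime) ** 2, 0.0).sum(axis=1)
        per_cell = sq / np.maximum(n_pos, 1)
        if variant == "scsdae" and alpha != 0.0:
            zero = ~pos
            n_zero = zero.sum(axis=1)
            pen = np.where(zero, np.abs(X_prime), 0.0).sum(axis=1)
            per_cell = per_cell + alpha * pen / np.maximum(n_zero, 1)
        elif variant not in ("sdae0", "scsdae"):
            raise ValueError(f"unknown variant {variant!r}")
    return float(per_cell.mean())


def batch_loss_grad(variant: str, X: np.ndarray, X_prime: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    """d(batch loss)/d(X_prime); same shape as X_prime."""
    X, X_prime = _check(X, X_prime)
    b = X.shape[0]
    if variant == "sdae":
        return 2.0 * (X_prime - X) / X.shape[1] / b
    if variant not in ("sdae0", "scsdae"):
        raise ValueError(f"unknown variant {variant!r}")
    pos = X > 0
    n_pos = np.maximum(pos.sum(axis=1, keepdims=True), 1)
    grad = np.where(pos, 2.0 * (X_prime - X) / n_pos, 0.0)
    if variant == "scsdae" and alpha != 0.0:
        zero = ~pos
        n_zero = np.maximum(zero.sum(axis=1, keepdims=True), 1)
        grad = grad + np.where(zero, alpha * np.sign(X_prime) / n_zero, 0.0)
    return grad / b
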