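"""Sequence-integration blocks: dot-product attention pooling and score heads.

The recurrent blocks (bi-directional GRUs with concatenated time gaps,
exponential memory decay, or ODE memory dynamics) live in :mod:`icurisk.nn`;
this module adds the attention mechanism that turns a variable-length set of
vectors into one fixed-size context vector, and the linear heads that reduce
a context to a scalar risk score.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module

__all__ = ["AttentionPool", "ScoreHead", "dot_attention"]


class AttentionPool(Module):
    """Scaled dot-product attention with a learned query.

    Weights are ``softmax_i( q . (K h_i) / sqrt(d) )`` over unmasked
    positions; the context is the weighted average of the inputs themselves.
    The key projection is square (the hidden width of the attended vectors is
    left unchanged). Scaling by ``sqrt(d)`` is the package default and can be
    disabled.
    """

    def __init__(self, d: int, rng: np.random.Generator, scaled: bool = True):
        self.K = Tensor.param(_orthogonal_ish(rng, d))
        self.q = Tensor.param(rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, 1)))
        self.d = d
        self.scaled = scaled

    def __call__(self, H: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Pool (B, L, d) inputs to a (B, d) context; also return (B, L) weights.

        Rows whose mask is entirely zero produce a zero context and all-zero
        weights (the documented convention for empty sequences).
        """
        B, L, d = H.shape
        keys = H.reshape(B * L, d) @ self.K
        scores = (keys @ self.q).reshape(B, L)
        if self.scaled:
            scores = scores / np.sqrt(d)
        weights = scores.masked_softmax(np.asarray(mask, dtype=float), axis=1)
        context = (weights.reshape(B, L, 1) * H).sum(axis=1)
        return context, weights


def dot_attention(H: Tensor | np.ndarray, mask: np.ndarray,
                  K: np.ndarray, q: np.ndarray,
                  scaled: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Functional attention pooling with explicit parameters (no gradients)."""
    H = H.data if isinstance(H, Tensor) else np.asarray(H, dtype=float)
    pool = AttentionPool.__new__(AttentionPool)
    pool.K = Tensor(np.asarray(K, dtype=float))
    pool.q = Tensor(np.asarray(q, dtype=float).reshape(-1, 1))
    pool.d = H.shape[-1]
    pool.scaled = scaled
    ctx, w = pool(Tensor(H), mask)
    return ctx.data, w.data


class ScoreHead(Module):
    """Affine map from a context vector to one scalar score (linear activation)."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.lin = Linear(d, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin(x)


def _orthogonal_ish(rng: np.random.Generator, d: int) -> np.ndarray:
    """Near-orthogonal square init keeps early attention logits well-scaled."""
    a = rng.normal(size=(d, d))
    u, _, vt = np.linalg.svd(a)
    return u @ vt
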