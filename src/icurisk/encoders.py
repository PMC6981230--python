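"""Time-aware code embeddings.

Three mechanisms map timestamped codes to vectors:

1. end-to-end embedding matrices, optionally with the elapsed time appended
   as an extra coordinate;
2. neural-ODE embedding dynamics: the matrix stores each code's embedding at
   elapsed time zero (the moment of ICU discharge) and the embedding of an
   event recorded t time units earlier is obtained by Euler-integrating a
   learned derivative MLP forward over [0, t];
3. medical-concept embeddings (MCE) pretrained unsupervised with a
   continuous-bag-of-words objective in which each context code's
   contribution is weighted by a learned attention value depending on the
   bucketed time difference to the target — the temporal scope of a code is
   learned together with its embedding.

Embedding width follows the fourth-root size rule ``round(2 * V**0.25)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, concat
from .nn import MLP, Module, euler_integrate

__all__ = [
    "embedding_dim", "EmbeddingMatrix", "embed", "append_time",
    "ode_evolve_embedding", "mce_train",
]


def embedding_dim(v: int) -> int:
    """Embedding width for a vocabulary of ``v`` codes: round(2 * v**(1/4)).

    The proportionality constant 2 reproduces widths 12 and 10 for combined
    vocabularies of 1,290 (diagnoses + procedures) and 618 (medications +
    vital signs) codes.
    """
    if v < 1:
        raise ValueError("vocabulary size must be >= 1")
    return int(np.rint(2.0 * float(v) ** 0.25))


class EmbeddingMatrix(Module):
    """V x d embedding table for one code stream."""

    def __init__(self, v: int, d: int | None = None,
                 rng: np.random.Generator | None = None,
                 weights: np.ndarray | None = None, stream: str = ""):
        self.v = v
        self.d = embedding_dim(v) if d is None else d
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (v, self.d):
                raise ValueError(f"weights shape {weights.shape} != ({v}, {self.d})")
            self.W = Tensor.param(weights.copy())
        else:
            rng = np.random.default_rng(0) if rng is None else rng
            self.W = Tensor.param(rng.normal(0.0, 0.1, size=(v, self.d)))
        self.stream = stream

    def freeze(self) -> "EmbeddingMatrix":
        self.W.requires_grad = False
        return self

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.W.data)
        path.with_suffix(".json").write_text(json.dumps(
            {"stream": self.stream, "v": self.v, "d": self.d}))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        W = np.loadtxt(path).reshape(meta["v"], meta["d"])
        return cls(meta["v"], meta["d"], weights=W, stream=meta["stream"])


def embed(codes: np.ndarray, mask: np.ndarray, matrix: EmbeddingMatrix) -> Tensor:
    """Look up code embeddings; padded positions come out as zero vectors."""
    E = matrix.W.take_rows(np.asarray(codes, dtype=int))
    return E * Tensor(np.asarray(mask, dtype=float)[..., None])


def append_time(vectors: Tensor, elapsed: np.ndarray, mask: np.ndarray) -> Tensor:
    """Concatenate the raw elapsed time as a final coordinate (0 when masked)."""
    t = (np.asarray(elapsed, dtype=float) * np.asarray(mask, dtype=float))[..., None]
    return concat([vectors, Tensor(t)], axis=-1)


def ode_evolve_embedding(codes: np.ndarray, elapsed: np.ndarray, mask: np.ndarray,
                         matrix: EmbeddingMatrix, dynamics: MLP,
                         n_steps: int = 10) -> Tensor:
    """Embedding of each event at its elapsed time, via Euler integration.

    The stored row is the time-zero embedding; ``n_steps`` fixed Euler steps
    integrate dy/ds = f(y) forward over [0, t] for each event's elapsed time
    t, in one rectangular batch. Events at t = 0 return the stored row
    exactly.
    """
    elapsed = np.asarray(elapsed, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed times must be non-negative")
    shape = np.shape(codes)
    E0 = matrix.W.take_rows(np.asarray(codes, dtype=int).ravel())
    Et = euler_integrate(E0, elapsed.ravel(), dynamics, n_steps)
    Et = Et.reshape(*shape, matrix.d)
    return Et * Tensor(np.asarray(mask, dtype=float)[..., None])


def _bucket(dt: np.ndarray, clip: int) -> np.ndarray:
    """Integer time-difference buckets clipped to [-clip, clip] -> [0, 2*clip]."""
    return (np.clip(np.rint(dt), -clip, clip) + clip).astype(int)


def mce_train(sequences: list[tuple[np.ndarray, np.ndarray]], v: int,
              d: int | None = None, epochs: int = 5, lr: float = 0.05,
              clip: int = 365, seed: int = 0,
              batch_sequences: int = 1) -> EmbeddingMatrix:
    """Pretrain medical-concept embeddings with time-aware attention.

    Each sequence is ``(codes, times)`` in the stream's native time unit.
    For every target position, the remaining codes form the context; a
    per-(code, integer time-difference bucket) attention scalar is
    softmax-normalised over the context, the attended average of input
    embeddings predicts the target through an output matrix, and the
    cross-entropy loss is minimised by Adam.

    Returns the average of the input and output matrices: co-occurring codes
    align across the two sides of the objective, so the averaged vectors
    carry the co-occurrence geometry (the usual word2vec-style convention).
    """
    usable = [(np.asarray(c, dtype=int), np.asarray(t, dtype=float))
              for c, t in sequences if len(c) >= 2]
    if not usable:
        raise ValueError("MCE pretraining needs at least one sequence with >= 2 codes")
    d = embedding_dim(v) if d is None else d
    rng = np.random.default_rng(seed)
    n_buckets = 2 * clip + 1
    W_in = Tensor.param(rng.normal(0.0, 0.1, size=(v, d)))
    W_out = Tensor.param(rng.normal(0.0, 0.1, size=(v, d)))
    # flat (v * n_buckets, 1) attention table for fancy (code, bucket) gather
    A = Tensor.param(np.zeros((v * n_buckets, 1)))
    opt = Adam([W_in, W_out, A], lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(usable))
        for si in order:
            codes, times = usable[si]
            L = len(codes)
            dt = times[None, :] - times[:, None]  # dt[j, i]: context i vs target j
            flat_idx = codes[None, :] * n_buckets + _bucket(dt, clip)
            logits = A.take_rows(flat_idx.ravel()).reshape(L, L)
            ctx_mask = 1.0 - np.eye(L)
            alpha = logits.masked_softmax(ctx_mask, axis=1)
            E = W_in.take_rows(codes)  # (L, d) context-code embeddings
            contexts = alpha @ E  # (L, d)
            scores = contexts @ W_out.T  # (L, v)
            shift = scores.data.max(axis=1, keepdims=True)
            lse = scores.exp_shifted(scores.data - shift).sum(axis=1).log()
            picked = scores[np.arange(L), codes]
            loss = (lse + Tensor(shift[:, 0]) - picked).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return EmbeddingMatrix(v, d, weights=0.5 * (W_in.data + W_out.data))
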