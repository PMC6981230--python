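"""Neural building blocks: linear layers, GRU cells, Euler ODE integration, dropout.

All parameters are :class:`icurisk.autodiff.Tensor` objects; modules expose
``parameters()`` so optimisers and the variational wrapper can enumerate them.
Initialisation is Glorot-uniform from an explicit ``numpy.random.Generator``,
which makes every model build reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "MLP", "GRUCell", "BiGRU",
    "euler_integrate", "dropout",
]


class Module:
    """Base class providing recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        # zero_init suits output layers fed by unstandardised covariates:
        # training starts from calibrated (zero) logits instead of saturation
        W = np.zeros((n_in, n_out)) if zero_init else _glorot(rng, n_in, n_out)
        self.W = Tensor.param(W)
        self.b = Tensor.param(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        orig_shape = x.shape
        if x.ndim > 2:
            x = x.reshape(-1, orig_shape[-1])
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        if len(orig_shape) > 2:
            y = y.reshape(*orig_shape[:-1], self.W.shape[1])
        return y


class MLP(Module):
    """Multilayer perceptron with tanh hidden activations and linear output.

    Default geometry (three hidden layers of width equal to the input) matches
    the derivative networks used for the neural-ODE blocks.
    """

    def __init__(self, dim: int, rng: np.random.Generator, n_hidden: int = 3,
                 out_dim: int | None = None, out_zero_init: bool = False):
        out_dim = dim if out_dim is None else out_dim
        self.layers = [Linear(dim, dim, rng) for _ in range(n_hidden)]
        # zero-initialised output makes the initial flow f = 0 (identity
        # dynamics), which keeps long Euler integrations stable early on
        self.out = Linear(dim, out_dim, rng, zero_init=out_zero_init)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).tanh()
        return self.out(x)


def euler_integrate(y0: Tensor, t: np.ndarray | float, f, n_steps: int) -> Tensor:
    """Integrate dy/ds = f(y) over [0, t] by the explicit Euler method.

    ``t`` may be a scalar or a per-row array of horizons (shape ``(N,)`` or
    ``(N, 1)`` for ``y0`` of shape ``(N, d)``), so a batch of events with
    different elapsed times is solved in one rectangular pass with ``n_steps``
    fixed steps each.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("integration horizon must be non-negative")
    if t_arr.ndim == 1:
        t_arr = t_arr[:, None]
    h = Tensor(t_arr / n_steps)
    y = y0
    for _ in range(n_steps):
        y = y + h * f(y)
    return y


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.shape) >= p
    return x * Tensor(keep / (1.0 - p))


class GRUCell(Module):
    """Gated recurrent unit: h' = (1 - z) * h + z * n."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.Wz = Tensor.param(_glorot(rng, n_in, n_hidden))
        self.Uz = Tensor.param(_glorot(rng, n_hidden, n_hidden))
        self.bz = Tensor.param(np.zeros(n_hidden))
        self.Wr = Tensor.param(_glorot(rng, n_in, n_hidden))
        self.Ur = Tensor.param(_glorot(rng, n_hidden, n_hidden))
        self.br = Tensor.param(np.zeros(n_hidden))
        self.Wn = Tensor.param(_glorot(rng, n_in, n_hidden))
        self.Un = Tensor.param(_glorot(rng, n_hidden, n_hidden))
        self.bn = Tensor.param(np.zeros(n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (x @ self.Wn + (r * h) @ self.Un + self.bn).tanh()
        return (1.0 - z) * h + z * n


class BiGRU(Module):
    """Bi-directional GRU over padded event sequences with three time handlings.

    ``time_mode``:
      * ``None`` — ignore inter-event gaps;
      * ``"concat"`` — append the gap to the previous event to each input;
      * ``"exp"`` — decay the memory state by ``exp(-softplus(w) * gap)``
        before each update (rates constrained positive via softplus);
      * ``"ode"`` — evolve the memory state over each gap with a learned
        derivative MLP, integrated by Euler steps.

    The forward direction reads events oldest-first; the backward direction
    most-recent-first. Gaps are recomputed per direction (gap to the previous
    event in traversal order; first gap 0).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 time_mode: str | None = None, ode_steps: int = 10,
                 time_scale: float = 1.0):
        cell_in = n_in + 1 if time_mode == "concat" else n_in
        self.fwd = GRUCell(cell_in, n_hidden, rng)
        self.bwd = GRUCell(cell_in, n_hidden, rng)
        self.time_mode = time_mode
        self.ode_steps = ode_steps
        self.time_scale = time_scale  # gaps divided by this before decay/ODE
        self.n_hidden = n_hidden
        if time_mode == "exp":
            self.decay_fwd = Tensor.param(np.zeros(n_hidden))
            self.decay_bwd = Tensor.param(np.zeros(n_hidden))
        elif time_mode == "ode":
            self.dyn_fwd = MLP(n_hidden, rng, out_zero_init=True)
            self.dyn_bwd = MLP(n_hidden, rng, out_zero_init=True)

    @staticmethod
    def gaps(elapsed: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Non-negative time gaps to the previous event in storage order.

        Events are stored chronologically with the largest elapsed time first,
        so the forward gap at position i is elapsed[i-1] - elapsed[i].
        """
        d = np.zeros_like(elapsed)
        d[:, 1:] = elapsed[:, :-1] - elapsed[:, 1:]
        return np.abs(d) * mask

    def _decay(self, h: Tensor, dt: np.ndarray, direction: str) -> Tensor:
        if self.time_mode == "exp":
            w = self.decay_fwd if direction == "fwd" else self.decay_bwd
            rate = w.softplus()
            return h * (rate * Tensor(-dt)).exp()
        if self.time_mode == "ode":
            f = self.dyn_fwd if direction == "fwd" else self.dyn_bwd
            return euler_integrate(h, dt[:, 0], f, self.ode_steps)
        return h

    def _run(self, X: Tensor, elapsed: np.ndarray, mask: np.ndarray,
             direction: str) -> tuple[list[Tensor], Tensor]:
        B, L = mask.shape
        cell = self.fwd if direction == "fwd" else self.bwd
        order = range(L) if direction == "fwd" else range(L - 1, -1, -1)
        # gaps in traversal order
        if direction == "fwd":
            dts = self.gaps(elapsed, mask)
        else:
            rev = elapsed[:, ::-1]
            dts = self.gaps(rev, mask[:, ::-1])[:, ::-1]
        h = Tensor(np.zeros((B, self.n_hidden)))
        outputs: dict[int, Tensor] = {}
        for i in order:
            m = mask[:, i][:, None]
            dt = dts[:, i][:, None] * m / self.time_scale
            if self.time_mode in ("exp", "ode"):
                h_dec = self._decay(h, dt, direction)
                h = Tensor(m) * h_dec + Tensor(1.0 - m) * h
            x = X[:, i, :]
            if self.time_mode == "concat":
                x = concat([x, Tensor(dt)], axis=1)
            h_new = cell(x, h)
            h = Tensor(m) * h_new + Tensor(1.0 - m) * h
            outputs[i] = h
        return [outputs[i] for i in range(L)], h

    def __call__(self, X: Tensor, elapsed: np.ndarray, mask: np.ndarray):
        """Return per-step outputs (B, L, 2d) and final states (B, 2d)."""
        from .autodiff import stack

        out_f, h_f = self._run(X, elapsed, mask, "fwd")
        out_b, h_b = self._run(X, elapsed, mask, "bwd")
        per_step = concat(
            [stack(out_f, axis=1), stack(out_b, axis=1)], axis=2)
        final = concat([h_f, h_b], axis=1)
        return per_step, final
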