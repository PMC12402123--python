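"""Dense and recurrent building blocks on the autodiff core.

Initialization is the classic uniform fan-in scheme, U(-1/sqrt(fan_in),
+1/sqrt(fan_in)), drawn from a caller-supplied ``numpy.random.Generator`` so
every model build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = ["Linear", "MLP", "LSTM", "Adam"]


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(max(n_in, 1))
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(n_out,)),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP(Module):
    """Feed-forward stack with tanh hidden activations and a linear head."""

    def __init__(self, n_in: int, hidden: list[int], n_out: int,
                 rng: np.random.Generator):
        sizes = [n_in] + list(hidden) + [n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class LSTM(Module):
    """Single-layer LSTM unrolled over a padded (B, T, D) input.

    Gate order in the fused weight matrix: input, forget, cell, output.
    The forget-gate bias starts at +1, the standard trick that keeps early
    gradients flowing through long sequences.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.cell = Linear(n_in + n_hidden, 4 * n_hidden, rng)
        b = self.cell.b.data
        b[n_hidden:2 * n_hidden] += 1.0

    def __call__(self, x_steps: list[Tensor]) -> list[Tensor]:
        """Run over a list of (B, D) step tensors; returns hidden states."""
        H = self.n_hidden
        B = x_steps[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for x_t in x_steps:
            gates = self.cell(concat([x_t, h], axis=1))
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs

    def parameters(self):
        return self.cell.parameters()


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
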