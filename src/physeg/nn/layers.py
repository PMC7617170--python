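"""Layers and an Adam optimiser built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, axis_matmul, conv3d

__all__ = ["Module", "Conv3d", "Linear", "Dropout", "upsample2x", "Adam"]


class Module:
    """Tiny parameter container with named sub-modules."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution with He-style initialisation."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1, dtype=np.float32):
        fan_in = cin * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, scale, size=(cout, cin, kernel, kernel, kernel))
            .astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        if self.kernel == 3:
            return conv3d(x, self.w, self.b, stride=self.stride)
        # 1x1x1: a channel-mixing matmul
        N, C, D, H, W = x.shape
        cout = self.w.data.shape[0]
        flat = x.reshape(N, C, D * H * W)
        w2 = self.w.reshape(cout, C)
        out = concat_channel_matmul(flat, w2, self.b)
        return out.reshape(N, cout, D, H, W)


def concat_channel_matmul(x_flat: Tensor, w2: Tensor, b: Tensor) -> Tensor:
    """(N, C, V) -> (N, Cout, V) via per-sample matmul."""
    N = x_flat.shape[0]
    outs = []
    for n in range(N):
        outs.append(w2.matmul(x_flat[n]).reshape(1, w2.shape[0], x_flat.shape[2]))
    from .autograd import concat

    out = concat(outs, axis=0)
    return out + b.reshape(1, -1, 1)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / cin)
        self.w = Tensor(
            rng.normal(0.0, scale, size=(cin, cout)).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class Dropout(Module):
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = ((rng.random(x.shape) < keep) / keep).astype(x.data.dtype)
        return x * Tensor(mask)


def _linear_upsample_matrix(n_in: int) -> np.ndarray:
    """(2n, n) matrix for factor-2 linear interpolation (cell-centred)."""
    n_out = 2 * n_in
    m = np.zeros((n_out, n_in))
    for j in range(n_out):
        c = (j + 0.5) / 2.0 - 0.5
        lo = int(np.floor(c))
        w_hi = c - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[j, lo_c] += 1.0 - w_hi
        m[j, hi_c] += w_hi
    return m


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def upsample2x(x: Tensor) -> Tensor:
    """Non-parametric trilinear x2 up-sampling of (N, C, D, H, W)."""
    for axis in (2, 3, 4):
        n_in = x.shape[axis]
        m = _UPSAMPLE_CACHE.get(n_in)
        if m is None:
            m = _linear_upsample_matrix(n_in)
            _UPSAMPLE_CACHE[n_in] = m
        x = axis_matmul(x, m, axis)
    return x


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
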