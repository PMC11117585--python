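"""Network layers on top of :mod:`decorrnet.autodiff`.

Layers follow the conventions of the architectures in
:mod:`decorrnet.models`: 3x3 'same' convolutions, 2x2 max-pooling,
batch normalization with running statistics, He-initialised weights.
Bias vectors and normalization parameters are flagged ``decay=False`` so the
L2 regulariser skips them.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, maxpool2d


class Parameter(Tensor):
    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)
        self.decay = decay


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    state[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):  # running stats
                    state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key in state:
                    if isinstance(v, Parameter):
                        v.data = state[key].copy()
                    elif isinstance(v, np.ndarray):
                        setattr(m, k, state[key].copy())


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Dense(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he(rng, (fin, fout), fin))
        self.bias = Parameter(np.zeros(fout), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization over axis 1 channels (2-D maps) or features (1-D).

    Composed from autodiff primitives so gradients need no bespoke backward.
    Running mean/variance (momentum 0.9) are used in eval mode.
    """

    def __init__(self, n: int, spatial: bool, eps: float = 1e-5):
        super().__init__()
        shape = (1, n, 1, 1) if spatial else (1, n)
        self.spatial = spatial
        self.eps = eps
        self.gamma = Parameter(np.ones(shape), decay=False)
        self.beta = Parameter(np.zeros(shape), decay=False)
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)
        self._acc = None    # (sum_mean, sum_var, count) during recalibration

    def start_accumulate(self):
        self._acc = [0.0, 0.0, 0]

    def finish_accumulate(self):
        s_m, s_v, k = self._acc
        if k > 0:
            self.running_mean = s_m / k
            self.running_var = s_v / k
        self._acc = None

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3) if self.spatial else (0,)
        if self.training:
            m = x.mean(axis=axes, keepdims=True)
            xc = x - m
            v = xc.square().mean(axis=axes, keepdims=True)
            if self._acc is not None:
                self._acc[0] = self._acc[0] + m.data
                self._acc[1] = self._acc[1] + v.data
                self._acc[2] += 1
            else:
                self.running_mean = 0.9 * self.running_mean + 0.1 * m.data
                self.running_var = 0.9 * self.running_var + 0.1 * v.data
            xhat = xc * ((v + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class Dropout(Module):
    """Inverted dropout; the trainer assigns ``rng`` before each forward."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0,1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0 or self.rng is None:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class ConvGRUCell(Module):
    """Gated recurrent unit with convolutional gates.

    Update/reset gates and the candidate state are 'same' convolutions over
    the channel-concatenated [input, hidden] maps:

        z = sigmoid(W_z * [x, h]),  r = sigmoid(W_r * [x, h])
        h~ = tanh(W_h * [x, r ⊙ h]),  h' = (1 − z) ⊙ h + z ⊙ h~
    """

    def __init__(self, cin: int, hidden: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wz = Conv2d(cin + hidden, hidden, k, rng)
        self.wr = Conv2d(cin + hidden, hidden, k, rng)
        self.wh = Conv2d(cin + hidden, hidden, k, rng)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concat([x, h], axis=1)
        z = self.wz(xh).sigmoid()
        r = self.wr(xh).sigmoid()
        cand = self.wh(concat([x, r * h], axis=1)).tanh()
        return (1.0 - z) * h + z * cand

    def __call__(self, frames: Tensor) -> Tensor:
        """``frames``: (N, T, C, H, W) -> final hidden state (N, hidden, H, W)."""
        n, t, c, h, w = frames.shape
        state = Tensor(np.zeros((n, self.hidden, h, w)))
        seq = frames.transpose((1, 0, 2, 3, 4))  # (T, N, C, H, W)
        for i in range(t):
            frame = _index_axis0(seq, i)
            state = self.step(frame, state)
        return state


def _index_axis0(x: Tensor, i: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(x.data)
        full[i] = g
        return ((x, full),)
    return Tensor(x.data[i], parents=(x,), backward=bw)


def flatten(x: Tensor) -> Tensor:
    return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))
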