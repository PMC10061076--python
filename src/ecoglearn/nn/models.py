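"""The two deep decoder architectures and exact parameter accounting.

With the default specs the trainable-parameter totals are 482,953 for the MLP
and 238,772 for the CNN+LSTM multiple-trajectory model; both totals are
asserted in the test suite against independent per-layer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecoglearn.nn.layers import (
    LSTM,
    Adam,
    BatchNorm,
    Conv2d,
    Dropout,
    Linear,
    ReLU,
)


@dataclass
class MlpSpec:
    """Flatten -> [affine -> batch-norm -> ReLU -> dropout] x2 -> affine."""

    input_dim: int = 9600
    hidden: tuple = (50, 50)
    output_dim: int = 3
    dropout: float = 0.5


@dataclass
class CnnLstmMtSpec:
    """Weight-shared conv stack per implant, per-step concatenation, two
    stacked LSTMs; emits a 3-vector per time step (multiple trajectories).

    Channels are mapped onto each implant's electrode grid row-major:
    channel c -> implant c // (gh*gw), row (c % (gh*gw)) // gw, col c % gw.
    """

    n_bands: int = 15
    grid: tuple = (8, 4)       # electrodes per implant, (height, width)
    n_steps: int = 10
    n_implants: int = 2
    conv_channels: tuple = (32, 64)
    lstm_hidden: int = 50
    output_dim: int = 3
    dropout: float = 0.5

    @property
    def n_channels(self) -> int:
        return self.n_implants * self.grid[0] * self.grid[1]

    @property
    def conv_out_hw(self) -> tuple:
        # conv1: 3x3, height valid / width preserved; conv2: 3x3 unpadded
        h = self.grid[0] - 2 - 2
        w = self.grid[1] - 2
        return h, w

    @property
    def lstm_input_dim(self) -> int:
        h, w = self.conv_out_hw
        return self.n_implants * self.conv_channels[1] * h * w


class _Decoder:
    """Shared plumbing: parameter list, counting, optimizer, (de)serialization."""

    layers: list

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def make_optimizer(self, lr: float, weight_decay: float) -> Adam:
        return Adam(self.params(), lr=lr, weight_decay=weight_decay)

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p.value[...] = w


class Mlp(_Decoder):
    """Flattened-tensor MLP emitting one 3D direction per epoch."""

    is_multi_trajectory = False

    def __init__(self, spec: MlpSpec | None = None, seed: int = 0):
        self.spec = spec or MlpSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.layers = []
        n_in = s.input_dim
        for h in s.hidden:
            self.layers += [Linear(n_in, h, rng), BatchNorm(h), ReLU(),
                            Dropout(s.dropout, rng)]
            n_in = h
        self.layers.append(Linear(n_in, s.output_dim, rng))

    def forward(self, x, train: bool = False):
        out = np.asarray(x, dtype=float).reshape(x.shape[0], -1)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class CnnLstmMt(_Decoder):
    """CNN over each implant grid, LSTM over time; per-step 3D outputs."""

    is_multi_trajectory = True

    def __init__(self, spec: CnnLstmMtSpec | None = None, seed: int = 0):
        self.spec = spec or CnnLstmMtSpec()
        s = self.spec
        if s.grid[0] < 5 or s.grid[1] < 3:
            raise ValueError("electrode grid too small for the two 3x3 conv layers")
        rng = np.random.default_rng(seed)
        c1, c2 = s.conv_channels
        self.conv1 = Conv2d(s.n_bands, c1, 3, 3, pad_h=0, pad_w=1, rng=rng)
        self.relu1 = ReLU()
        self.bn1 = BatchNorm(c1)
        self.drop1 = Dropout(s.dropout, rng)
        self.conv2 = Conv2d(c1, c2, 3, 3, pad_h=0, pad_w=0, rng=rng)
        self.relu2 = ReLU()
        self.drop2 = Dropout(s.dropout, rng)
        self.lstm1 = LSTM(s.lstm_input_dim, s.lstm_hidden, rng)
        self.lstm2 = LSTM(s.lstm_hidden, s.output_dim, rng)
        self.layers = [self.conv1, self.bn1, self.conv2, self.lstm1, self.lstm2]

    # -- channel grid mapping ----------------------------------------------

    def _to_grid(self, x):
        """(N, C, B, S) -> conv batch (N*implants*steps, bands, gh, gw)."""
        s = self.spec
        n = x.shape[0]
        gh, gw = s.grid
        x = x.reshape(n, s.n_implants, gh, gw, s.n_bands, s.n_steps)
        x = np.ascontiguousarray(np.transpose(x, (0, 1, 5, 4, 2, 3)))
        return x.reshape(n * s.n_implants * s.n_steps, s.n_bands, gh, gw)

    def forward(self, x, train: bool = False):
        s = self.spec
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        out = self._to_grid(x)
        out = self.conv1.forward(out, train)
        out = self.relu1.forward(out, train)
        shape = out.shape
        out = self.bn1.forward(out.transpose(0, 2, 3, 1).reshape(-1, shape[1]), train)
        out = out.reshape(shape[0], shape[2], shape[3], shape[1]).transpose(0, 3, 1, 2)
        self._bn_shape = shape
        out = self.drop1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.relu2.forward(out, train)
        out = self.drop2.forward(out, train)
        self._conv_out_shape = out.shape
        feat = out.reshape(n, s.n_implants, s.n_steps, -1)
        feat = np.concatenate([feat[:, i] for i in range(s.n_implants)], axis=2)
        out = self.lstm1.forward(feat, train)
        out = self.lstm2.forward(out, train)
        return out  # (N, steps, 3)

    def backward(self, dout):
        s = self.spec
        n = dout.shape[0]
        d = self.lstm2.backward(dout)
        d = self.lstm1.backward(d)  # (N, steps, implants*feat)
        per = d.shape[2] // s.n_implants
        d = np.stack([d[:, :, i * per:(i + 1) * per] for i in range(s.n_implants)],
                     axis=1)  # (N, implants, steps, feat)
        d = d.reshape(self._conv_out_shape)
        d = self.drop2.backward(d)
        d = self.relu2.backward(d)
        d = self.conv2.backward(d)
        d = self.drop1.backward(d)
        shape = self._bn_shape
        d = self.bn1.backward(d.transpose(0, 2, 3, 1).reshape(-1, shape[1]))
        d = d.reshape(shape[0], shape[2], shape[3], shape[1]).transpose(0, 3, 1, 2)
        d = self.relu1.backward(d)
        d = self.conv1.backward(d)
        # back through _to_grid
        gh, gw = s.grid
        d = d.reshape(n, s.n_implants, s.n_steps, s.n_bands, gh, gw)
        d = np.transpose(d, (0, 1, 4, 5, 3, 2))
        return d.reshape(n, s.n_channels, s.n_bands, s.n_steps)


def build_mlp(spec: MlpSpec | None = None, seed: int = 0) -> Mlp:
    return Mlp(spec, seed=seed)


def build_cnn_lstm_mt(spec: CnnLstmMtSpec | None = None, seed: int = 0) -> CnnLstmMt:
    return CnnLstmMt(spec, seed=seed)
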