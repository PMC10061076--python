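"""Uniform train/predict adapters shared by all experiment designs.

Every decoder consumes epochs as a ``(n, channels, bands, steps)`` tensor
with ``(n, 3)`` unit direction labels and predicts one 3D direction per
epoch.  Multiple-trajectory models emit a direction per time step internally;
their scalar evaluation uses the final (most recent) step.
"""

from __future__ import annotations

import numpy as np

from ecoglearn.nn.models import CnnLstmMt, CnnLstmMtSpec, Mlp, MlpSpec
from ecoglearn.nn.training import TrainConfig, train
from ecoglearn.rewnpls import RewNpls


class RewNplsDecoder:
    """Multilinear tensor decoder trained pseudo-online on 15 s chunks."""

    name = "rewnpls"

    def __init__(self, input_shape, f_max: int = 10, forgetting: float = 1.0,
                 chunk_size: int = 150, seed: int = 0):
        self.model = RewNpls(input_shape=input_shape, f_max=f_max,
                             forgetting=forgetting)
        self.chunk_size = chunk_size

    def fit(self, x: np.ndarray, y: np.ndarray):
        self.model.fit_pseudo_online(x, y, chunk_size=self.chunk_size)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


class MlpDecoder:
    name = "mlp"

    def __init__(self, input_shape, hidden=(50, 50), dropout: float = 0.5,
                 train_config: TrainConfig | None = None, seed: int = 0):
        input_dim = int(np.prod(input_shape))
        self.model = Mlp(MlpSpec(input_dim=input_dim, hidden=tuple(hidden),
                                 dropout=dropout), seed=seed)
        self.cfg = train_config or TrainConfig(seed=seed)
        self.history = None

    def fit(self, x: np.ndarray, y: np.ndarray):
        self.model, self.history = train(self.model, x, y, self.cfg)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.forward(x, train=False)


class CnnLstmDecoder:
    name = "cnnlstm"

    def __init__(self, input_shape, grid=(8, 4), n_implants: int | None = None,
                 dropout: float = 0.5, train_config: TrainConfig | None = None,
                 seed: int = 0):
        n_channels, n_bands, n_steps = input_shape
        per_implant = grid[0] * grid[1]
        if n_implants is None:
            n_implants = n_channels // per_implant
        if n_implants * per_implant != n_channels:
            raise ValueError(f"{n_channels} channels do not tile {n_implants} "
                             f"implants of grid {grid}")
        spec = CnnLstmMtSpec(n_bands=n_bands, grid=tuple(grid), n_steps=n_steps,
                             n_implants=n_implants, dropout=dropout)
        self.model = CnnLstmMt(spec, seed=seed)
        self.cfg = train_config or TrainConfig(seed=seed)
        self.history = None

    def fit(self, x: np.ndarray, y: np.ndarray):
        self.model, self.history = train(self.model, x, y, self.cfg)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        # final trajectory step = the decoder's estimate at the window end
        return self.model.forward(x, train=False)[:, -1, :]


def default_model_factories(input_shape, grid=(8, 4),
                            train_config: TrainConfig | None = None,
                            f_max: int = 10):
    """Factories ``name -> (seed -> decoder)`` for the three studied models."""
    def _cfg(seed):
        if train_config is None:
            return TrainConfig(seed=seed)
        from dataclasses import replace
        return replace(train_config, seed=seed)

    return {
        "rewnpls": lambda seed: RewNplsDecoder(input_shape, f_max=f_max, seed=seed),
        "mlp": lambda seed: MlpDecoder(input_shape, train_config=_cfg(seed), seed=seed),
        "cnnlstm": lambda seed: CnnLstmDecoder(input_shape, grid=grid,
                                               train_config=_cfg(seed), seed=seed),
    }
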