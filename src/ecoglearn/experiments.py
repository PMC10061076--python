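"""Dataset-size experiment designs: forward / backward / random increase and
dataset translation, with unified cosine-similarity evaluation.

All designs operate on a :class:`DatasetView` (ordered epochs with session
boundaries).  ``train_size_minutes`` reports dataset size as
``epoch_count * hop`` to match minute-scaled learning-curve axes.  Train and
test sets are disjoint by construction and asserted so.
"""

from __future__ import annotations

from dataclasses import dataclass

import zlib

import numpy as np
import pandas as pd
from scipy import stats

from ecoglearn.metrics import mean_cosine_similarity


@dataclass
class DatasetView:
    """Ordered epoch collection with session bookkeeping."""

    x: np.ndarray              # (n, channels, bands, steps)
    y: np.ndarray              # (n, 3)
    session_index: np.ndarray  # (n,)
    state: np.ndarray | None = None
    hop: float = 0.1           # seconds between epochs (size bookkeeping)

    @classmethod
    def from_epochs(cls, epochs, hop: float = 0.1) -> "DatasetView":
        if not epochs:
            raise ValueError("no epochs")
        return cls(
            x=np.stack([e.x for e in epochs]).astype(np.float32),
            y=np.stack([e.y for e in epochs]),
            session_index=np.array([e.session_index for e in epochs]),
            state=np.array([e.state for e in epochs]),
            hop=hop,
        )

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.session_index)

    @property
    def input_shape(self) -> tuple:
        return self.x.shape[1:]

    def select(self, sessions) -> tuple[np.ndarray, np.ndarray]:
        mask = np.isin(self.session_index, np.asarray(sessions))
        return self.x[mask], self.y[mask]

    def minutes(self, n_epochs: int) -> float:
        return n_epochs * self.hop / 60.0


def evaluate_cs(model, x_test: np.ndarray, y_test: np.ndarray) -> float:
    """Unweighted mean cosine similarity of a fitted model on a test set."""
    if len(x_test) == 0:
        raise ValueError("empty test set")
    return mean_cosine_similarity(model.predict(x_test), y_test)


def fit_linear_trend(xs, ys):
    """OLS trend with Pearson R and two-sided p-value.

    Constant responses give slope 0, R 0 and p 1 by convention.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(ys) == 0.0:
        return 0.0, float(ys[0]), 0.0, 1.0
    res = stats.linregress(xs, ys)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))


def _derive_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _run_rows(view, models, train_sessions, test_sessions, experiment,
              n_repeats, seed, step_key, extra=None):
    train_sessions = list(train_sessions)
    test_sessions = list(test_sessions)
    assert not set(train_sessions) & set(test_sessions), "train/test overlap"
    x_tr, y_tr = view.select(train_sessions)
    x_te, y_te = view.select(test_sessions)
    if len(x_te) == 0 or len(x_tr) == 0:
        raise ValueError(f"empty train or test split for {experiment}")
    rows = []
    for name, factory in models.items():
        for rep in range(n_repeats):
            model = factory(_derive_seed(seed, step_key, rep, zlib.crc32(name.encode()) % 997))
            model.fit(x_tr, y_tr)
            cs = evaluate_cs(model, x_te, y_te)
            row = {
                "experiment": experiment,
                "model_name": name,
                "repeat": rep,
                "train_size_minutes": view.minutes(len(x_tr)),
                "train_sessions": ",".join(map(str, train_sessions)),
                "test_sessions": ",".join(map(str, test_sessions)),
                "mean_cs": cs,
            }
            if extra:
                row.update(extra)
            rows.append(row)
    return rows


def forward_increase(view: DatasetView, models: dict, n_train_max: int = 21,
                     test_window: int = 22, n_repeats: int = 1,
                     seed: int = 0) -> pd.DataFrame:
    """Grow the training set session by session from the study start.

    For k = 1..n_train_max the models are trained from scratch on sessions
    0..k-1 and evaluated on the following ``test_window`` sessions (truncated
    at the study end; the actual test list is recorded per row).
    """
    sessions = list(view.sessions)
    if len(sessions) < n_train_max + 1:
        raise ValueError("too few sessions for the requested forward increase")
    rows = []
    for k in range(1, n_train_max + 1):
        train_s = sessions[:k]
        test_s = sessions[k:k + test_window]
        rows += _run_rows(view, models, train_s, test_s, "forward_increase",
                          n_repeats, seed, k, extra={"k": k})
    return pd.DataFrame(rows)


def backward_increase(view: DatasetView, models: dict, anchor: int = 21,
                      n_train_max: int | None = None, test_window: int = 22,
                      n_repeats: int = 1, seed: int = 0) -> pd.DataFrame:
    """Grow the training set backwards from the session before ``anchor``.

    For k = 1..anchor the training set is sessions anchor-k..anchor-1; the
    test set is fixed to the last ``test_window`` sessions of the study.
    """
    sessions = list(view.sessions)
    if anchor >= len(sessions):
        raise ValueError("anchor beyond the study")
    test_s = sessions[-test_window:]
    if sessions[anchor - 1] in test_s:
        raise ValueError("anchor overlaps the fixed test tail")
    n_train_max = n_train_max or anchor
    rows = []
    for k in range(1, n_train_max + 1):
        train_s = sessions[anchor - k:anchor]
        rows += _run_rows(view, models, train_s, test_s, "backward_increase",
                          n_repeats, seed, k, extra={"k": k})
    return pd.DataFrame(rows)


def random_increase(view: DatasetView, models: dict, sizes,
                    pool_sessions: int = 22, test_window: int = 22,
                    n_eval_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Train on random epoch subsets of the first ``pool_sessions`` sessions.

    For each target size, epochs are sampled uniformly without replacement
    from the pool and the model is evaluated on the fixed last-``test_window``
    test set; each evaluation is repeated ``n_eval_repeats`` times with
    distinct seeds.
    """
    sessions = list(view.sessions)
    pool = sessions[:pool_sessions]
    test_s = sessions[-test_window:]
    if set(pool) & set(test_s):
        raise ValueError("pool overlaps the test tail")
    mask = np.isin(view.session_index, pool)
    x_pool, y_pool = view.x[mask], view.y[mask]
    x_te, y_te = view.select(test_s)
    rows = []
    for size in sizes:
        if size > len(x_pool):
            raise ValueError(f"requested size {size} exceeds pool {len(x_pool)}")
        for rep in range(n_eval_repeats):
            rng = np.random.default_rng(_derive_seed(seed, size, rep))
            idx = np.sort(rng.choice(len(x_pool), size=size, replace=False))
            for name, factory in models.items():
                model = factory(_derive_seed(seed, size, rep, zlib.crc32(name.encode()) % 997))
                model.fit(x_pool[idx], y_pool[idx])
                rows.append({
                    "experiment": "random_increase",
                    "model_name": name,
                    "repeat": rep,
                    "train_size_minutes": view.minutes(size),
                    "train_sessions": ",".join(map(str, pool)),
                    "test_sessions": ",".join(map(str, test_s)),
                    "mean_cs": evaluate_cs(model, x_te, y_te),
                })
    return pd.DataFrame(rows)


def dataset_translation(view: DatasetView, models: dict, window: int = 6,
                        n_repeats: int = 1, seed: int = 0) -> pd.DataFrame:
    """Slide a fixed-size training window over the study.

    For each start s the models train on sessions s..s+window-1 and are
    evaluated on the following ``window`` sessions; s slides until the test
    window would overflow the study (43 sessions, window 6 -> 32 steps).
    """
    sessions = list(view.sessions)
    if len(sessions) < 2 * window:
        raise ValueError("too few sessions for dataset translation")
    rows = []
    for s in range(len(sessions) - 2 * window + 1):
        train_s = sessions[s:s + window]
        test_s = sessions[s + window:s + 2 * window]
        rows += _run_rows(view, models, train_s, test_s, "dataset_translation",
                          n_repeats, seed, s, extra={"start": s})
    return pd.DataFrame(rows)
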