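"""Recursive exponentially weighted N-way PLS (tensor-input regression).

The decoder maps ``channels x bands x steps`` feature tensors to 3D direction
vectors.  Training is pseudo-online: the model absorbs chunks of data (15 s by
default) and maintains exponentially weighted first and second moments from
which PLS factors are recomputed after every chunk.  The number of latent
factors is chosen by recursive validation: before a chunk is absorbed, each
candidate factor count is scored on that (still unseen) chunk and the
cumulative error decides which count the model uses for prediction.

Moment-domain factor extraction is algebraically identical to batch N-way PLS
on the concatenated data when the forgetting factor is 1, which
:func:`batch_npls_oracle` (an independent data-domain implementation) verifies
in the test suite.

Per factor the input weight vector is constrained to rank one over the input
modes, ``w = w1 (x) w2 (x) w3``, found by alternating least squares on the
cross-covariance tensor; the regression then proceeds as in ordinary PLS with
score-based deflation of both covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _rank_one_factors(z: np.ndarray, tol: float = 1e-12, max_iter: int = 500):
    """Best rank-one mode weights of a cross-covariance tensor.

    ``z`` has shape ``modes + (n_outputs,)``.  Returns unit vectors
    ``(w_1, ..., w_N)`` (one per input mode) and the unit output weight ``q``
    maximizing ``<z ; w_1, ..., w_N, q>``.  Deterministic: initialized from
    the leading singular vector of the matricized tensor, signs fixed so the
    largest-magnitude entry of each vector is positive.
    """
    modes = z.shape[:-1]
    m = z.shape[-1]
    d = int(np.prod(modes))
    zmat = z.reshape(d, m)
    # deterministic init for q from the leading right singular vector
    _, _, vt = np.linalg.svd(zmat, full_matrices=False)
    q = vt[0]
    ws = None
    prev = -np.inf
    for _ in range(max_iter):
        t = (zmat @ q).reshape(modes)  # contract output mode
        ws = _rank_one_tensor(t, tol=tol, max_iter=max_iter)
        w = _outer(ws).ravel()
        q = zmat.T @ w
        nq = np.linalg.norm(q)
        if nq == 0:
            q = np.zeros(m)
            q[0] = 1.0
            break
        q /= nq
        val = float(w @ zmat @ q)
        if abs(val - prev) <= tol * max(1.0, abs(val)):
            break
        prev = val
    ws = [_fix_sign(w) for w in ws]
    q = _fix_sign(q)
    return ws, q


def _rank_one_tensor(t: np.ndarray, tol: float = 1e-12, max_iter: int = 500):
    """Leading rank-one factors of a real tensor by HOSVD-initialized ALS."""
    ws = []
    for ax in range(t.ndim):
        unfold = np.moveaxis(t, ax, 0).reshape(t.shape[ax], -1)
        u, _, _ = np.linalg.svd(unfold, full_matrices=False)
        ws.append(u[:, 0])
    prev = -np.inf
    for _ in range(max_iter):
        for ax in range(t.ndim):
            v = t
            for other in range(t.ndim - 1, -1, -1):
                if other == ax:
                    continue
                v = np.tensordot(v, ws[other], axes=([other], [0]))
            nv = np.linalg.norm(v)
            ws[ax] = v / nv if nv > 0 else _unit(t.shape[ax])
        val = float(np.tensordot(t, _outer(ws), axes=t.ndim))
        if abs(val - prev) <= tol * max(1.0, abs(val)):
            break
        prev = val
    return ws


def _outer(ws):
    out = ws[0]
    for w in ws[1:]:
        out = np.multiply.outer(out, w)
    return out


def _unit(n):
    v = np.zeros(n)
    v[0] = 1.0
    return v


def _fix_sign(v):
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _npls_from_moments(sc_xx: np.ndarray, sc_xy: np.ndarray, input_shape,
                       n_factors: int):
    """PLS factors from centered scatter matrices with rank-one mode weights.

    Returns per-factor direction vectors ``W`` (d, F), loadings ``P`` (d, F)
    and output weights ``B`` (F, m); stops early on degenerate covariance.
    """
    d = sc_xx.shape[0]
    m = sc_xy.shape[1]
    cxx = sc_xx.copy()
    cxy = sc_xy.copy()
    scale = max(float(np.trace(sc_xx)), 1e-300)
    ws_list, ps, bs = [], [], []
    for _ in range(n_factors):
        if np.linalg.norm(cxy) <= 1e-14 * max(1.0, np.linalg.norm(sc_xy)):
            break
        mode_ws, _q = _rank_one_factors(cxy.reshape(*input_shape, m))
        w = _outer(mode_ws).ravel()
        denom = float(w @ cxx @ w)
        if denom <= 1e-14 * scale:
            break
        p = (cxx @ w) / denom
        b = (cxy.T @ w) / denom
        # deflation: X <- X (I - w p'), Y <- Y - X w b'
        cxy = cxy - np.outer(cxx @ w, b)
        cxy -= np.outer(p, w @ cxy)
        cw = cxx @ w
        wc = cxx.T @ w  # cxx symmetric in exact arithmetic; keep both for safety
        cxx = cxx - np.outer(p, wc) - np.outer(cw, p) + np.outer(p, p) * denom
        ws_list.append(w)
        ps.append(p)
        bs.append(b)
    if not ws_list:
        return np.zeros((d, 0)), np.zeros((d, 0)), np.zeros((0, m))
    return np.column_stack(ws_list), np.column_stack(ps), np.vstack(bs)


def _prefix_coefs(W: np.ndarray, P: np.ndarray, B: np.ndarray):
    """Coefficient matrix for every prefix factor count via the rotation
    recursion r_f = w_f - sum_{j<f} r_j (p_j' w_f)."""
    d, F = W.shape
    m = B.shape[1] if F else 0
    coefs = []
    R = np.zeros((d, F))
    acc = np.zeros((d, m)) if F else np.zeros((d, 0))
    for f in range(F):
        r = W[:, f].copy()
        if f:
            r -= R[:, :f] @ (P[:, :f].T @ W[:, f])
        R[:, f] = r
        acc = acc + np.outer(r, B[f])
        coefs.append(acc.copy())
    return coefs


@dataclass
class RewNplsState:
    """Running moments and fitted factors of the recursive decoder."""

    input_shape: tuple
    n_outputs: int = 3
    f_max: int = 20
    forgetting: float = 1.0  # lambda; 1 = no forgetting
    n_eff: float = 0.0       # exponentially weighted sample count
    s_x: np.ndarray | None = None
    s_y: np.ndarray | None = None
    s_xx: np.ndarray | None = None
    s_xy: np.ndarray | None = None
    coefs: list = field(default_factory=list)   # prefix coefficient matrices
    biases: list = field(default_factory=list)
    cum_val_err: np.ndarray | None = None       # per candidate factor count
    f_selected: int = 1


class RewNpls:
    """Chunk-wise recursive exponentially weighted N-way PLS decoder."""

    def __init__(self, input_shape=(64, 15, 10), n_outputs: int = 3,
                 f_max: int = 20, forgetting: float = 1.0):
        if not 0.0 < forgetting <= 1.0:
            raise ValueError("forgetting factor must lie in (0, 1]")
        if f_max < 1:
            raise ValueError("f_max must be at least 1")
        d = int(np.prod(input_shape))
        self.state = RewNplsState(
            input_shape=tuple(input_shape), n_outputs=n_outputs, f_max=f_max,
            forgetting=forgetting,
            s_x=np.zeros(d), s_y=np.zeros(n_outputs),
            s_xx=np.zeros((d, d)), s_xy=np.zeros((d, n_outputs)),
            cum_val_err=np.zeros(f_max),
        )

    # -- contract -----------------------------------------------------------

    def update(self, x_chunk: np.ndarray, y_chunk: np.ndarray) -> "RewNpls":
        """Absorb one chunk; validates candidate factor counts chunk-ahead."""
        st = self.state
        x_chunk = np.asarray(x_chunk, dtype=float)
        y_chunk = np.asarray(y_chunk, dtype=float)
        if x_chunk.size == 0:
            raise ValueError("empty chunk")
        if x_chunk.shape[1:] != st.input_shape:
            raise ValueError(f"chunk input shape {x_chunk.shape[1:]} != "
                             f"model input shape {st.input_shape}")
        if y_chunk.shape != (x_chunk.shape[0], st.n_outputs):
            raise ValueError("output chunk shape mismatch")
        n = x_chunk.shape[0]
        xf = x_chunk.reshape(n, -1)

        # recursive validation on the not-yet-absorbed chunk
        if st.coefs:
            for f in range(st.f_max):
                k = min(f, len(st.coefs) - 1)
                pred = xf @ st.coefs[k] + st.biases[k]
                st.cum_val_err[f] += float(np.sum((pred - y_chunk) ** 2))
            st.f_selected = int(np.argmin(st.cum_val_err)) + 1

        lam = st.forgetting
        st.n_eff = lam * st.n_eff + n
        st.s_x = lam * st.s_x + xf.sum(axis=0)
        st.s_y = lam * st.s_y + y_chunk.sum(axis=0)
        st.s_xx = lam * st.s_xx + xf.T @ xf
        st.s_xy = lam * st.s_xy + xf.T @ y_chunk
        self._refit()
        return self

    def _refit(self):
        st = self.state
        w = st.n_eff
        mx = st.s_x / w
        my = st.s_y / w
        sc_xx = st.s_xx - np.outer(st.s_x, st.s_x) / w
        sc_xy = st.s_xy - np.outer(st.s_x, st.s_y) / w
        if float(np.trace(sc_xx)) <= 1e-12 * max(1.0, float(np.dot(mx, mx)) * w):
            raise ValueError("degenerate covariance: inputs are constant")
        W, P, B = _npls_from_moments(sc_xx, sc_xy, st.input_shape, st.f_max)
        coefs = _prefix_coefs(W, P, B)
        if not coefs:
            d = sc_xx.shape[0]
            coefs = [np.zeros((d, st.n_outputs))]
        st.coefs = coefs
        st.biases = [my - c.T @ mx for c in coefs]
        st.f_selected = min(st.f_selected, len(coefs))

    def predict(self, x: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        """Predict 3D directions; uses the recursively validated factor count."""
        st = self.state
        if not st.coefs or st.n_eff <= 0:
            raise ValueError("model has not been fitted")
        f = st.f_selected if n_factors is None else n_factors
        f = int(np.clip(f, 1, len(st.coefs)))
        x = np.asarray(x, dtype=float)
        xf = x.reshape(x.shape[0], -1)
        return xf @ st.coefs[f - 1] + st.biases[f - 1]

    def fit_pseudo_online(self, x: np.ndarray, y: np.ndarray,
                          chunk_size: int = 150) -> "RewNpls":
        """Train by iterating chunks in chronological order (15 s at 0.1 s hop
        corresponds to ``chunk_size=150``)."""
        n = x.shape[0]
        for start in range(0, n, chunk_size):
            self.update(x[start:start + chunk_size], y[start:start + chunk_size])
        return self

    @property
    def coef_(self) -> np.ndarray:
        st = self.state
        f = int(np.clip(st.f_selected, 1, len(st.coefs)))
        return st.coefs[f - 1].reshape(*st.input_shape, st.n_outputs)

    def count_parameters(self) -> int:
        """Entries of the prediction tensor (bias excluded): 64*15*10*3 = 28,800."""
        st = self.state
        return int(np.prod(st.input_shape)) * st.n_outputs


    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write moments, coefficients and config to an HDF5 file."""
        import h5py

        st = self.state
        with h5py.File(path, "w") as h5:
            h5.attrs["input_shape"] = np.asarray(st.input_shape)
            h5.attrs["n_outputs"] = st.n_outputs
            h5.attrs["f_max"] = st.f_max
            h5.attrs["forgetting"] = st.forgetting
            h5.attrs["n_eff"] = st.n_eff
            h5.attrs["f_selected"] = st.f_selected
            for name in ("s_x", "s_y", "s_xx", "s_xy", "cum_val_err"):
                h5.create_dataset(name, data=getattr(st, name))
            for i, (c, b) in enumerate(zip(st.coefs, st.biases)):
                h5.create_dataset(f"coef_{i:03d}", data=c)
                h5.create_dataset(f"bias_{i:03d}", data=b)

    @classmethod
    def load(cls, path) -> "RewNpls":
        import h5py

        with h5py.File(path, "r") as h5:
            model = cls(input_shape=tuple(int(v) for v in h5.attrs["input_shape"]),
                        n_outputs=int(h5.attrs["n_outputs"]),
                        f_max=int(h5.attrs["f_max"]),
                        forgetting=float(h5.attrs["forgetting"]))
            st = model.state
            st.n_eff = float(h5.attrs["n_eff"])
            st.f_selected = int(h5.attrs["f_selected"])
            for name in ("s_x", "s_y", "s_xx", "s_xy", "cum_val_err"):
                setattr(st, name, h5[name][...])
            i = 0
            while f"coef_{i:03d}" in h5:
                st.coefs.append(h5[f"coef_{i:03d}"][...])
                st.biases.append(h5[f"bias_{i:03d}"][...])
                i += 1
        return model


def count_parameters(input_shape=(64, 15, 10), n_outputs: int = 3) -> int:
    """Prediction-tensor size of the multilinear model for given modes."""
    return int(np.prod(input_shape)) * n_outputs


def batch_npls_oracle(x_all: np.ndarray, y_all: np.ndarray, n_factors: int):
    """Independent batch N-way PLS in the data domain (reference for tests).

    Centers the data, then per factor extracts rank-one mode weights from the
    cross-covariance of the *deflated* data matrices, scores, loadings and
    output weights, deflating X and Y by the score.  Returns the coefficient
    tensor mapping raw (uncentered) inputs to outputs, and the bias.
    """
    x_all = np.asarray(x_all, dtype=float)
    y_all = np.asarray(y_all, dtype=float)
    n = x_all.shape[0]
    input_shape = x_all.shape[1:]
    m = y_all.shape[1]
    if n < n_factors:
        raise ValueError("fewer samples than requested factors")
    xf = x_all.reshape(n, -1)
    mx = xf.mean(axis=0)
    my = y_all.mean(axis=0)
    X = xf - mx
    Y = y_all - my
    total = float(np.sum((xf - mx) ** 2))
    if total <= 1e-12 * max(1.0, float(mx @ mx)) * n:
        raise ValueError("degenerate covariance: inputs are constant")
    ws, ps, bs = [], [], []
    for _ in range(n_factors):
        z = (X.T @ Y)
        if np.linalg.norm(z) <= 1e-14 * max(1.0, np.linalg.norm(xf.T @ y_all)):
            break
        mode_ws, _q = _rank_one_factors(z.reshape(*input_shape, m))
        w = _outer(mode_ws).ravel()
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-14 * total:
            break
        p = (X.T @ t) / tt
        b = (Y.T @ t) / tt
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, b)
        ws.append(w)
        ps.append(p)
        bs.append(b)
    if not ws:
        d = xf.shape[1]
        coef = np.zeros((d, m))
    else:
        coef = _prefix_coefs(np.column_stack(ws), np.column_stack(ps),
                             np.vstack(bs))[-1]
    bias = my - coef.T @ mx
    return coef.reshape(*input_shape, m), bias
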