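"""Data-quality diagnostics: 2D embeddings, per-session state separability,
local and global intrinsic dimensionality, and the ID-performance report.

Local intrinsic dimensionality (ID) uses the expected simplex skewness (ESS)
estimator on 100-point nearest-neighbor neighborhoods: in a neighborhood
centered at its centroid, the norm-weighted mean sine of the angle between
vector pairs has a closed-form expectation under isotropy that is strictly
increasing in the dimension, so inverting it yields a (fractional) dimension
estimate.  Global ID uses the TwoNN estimator: the ratio mu of second- to
first-nearest-neighbor distances follows F(mu) = 1 - mu^(-d) on a uniform
d-dimensional manifold, and d is fit from the empirical log-ratio law with
the conventional 10% upper-tail trim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from ecoglearn.experiments import fit_linear_trend


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingReport:
    coords: np.ndarray          # (points, 2)
    meta: pd.DataFrame          # session, state per point
    scope: str                  # both_hands | left_only | right_only
    n_neighbors: int = 15
    min_dist: float = 0.1


def subsample_for_embedding(epochs, stride: int = 10, state: int | None = None):
    """Every ``stride``-th epoch, flattened; returns (features, meta).

    ``state`` restricts the selection to one hand (for per-hand embedding
    scopes); ``None`` keeps both states.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pool = epochs if state is None else [e for e in epochs if e.state == state]
    sel = pool[::stride]
    feats = np.stack([e.x.ravel() for e in sel]).astype(np.float64)
    meta = pd.DataFrame({
        "session": [e.session_index for e in sel],
        "state": [e.state for e in sel],
    })
    return feats, meta


def fit_embedding(features: np.ndarray, meta: pd.DataFrame | None = None,
                  scope: str = "both_hands", n_neighbors: int = 15,
                  min_dist: float = 0.1, seed: int = 0) -> EmbeddingReport:
    """Seeded 2D UMAP embedding fit jointly on all sessions."""
    import umap

    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] < 50:
        raise ValueError("need at least 50 points for a meaningful embedding")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(features)
    if meta is None:
        meta = pd.DataFrame(index=range(features.shape[0]))
    return EmbeddingReport(coords=np.asarray(coords), meta=meta.reset_index(drop=True),
                           scope=scope, n_neighbors=n_neighbors, min_dist=min_dist)


@dataclass
class SeparabilityReport:
    per_session: pd.DataFrame   # session, accuracy, flagged
    trend: tuple                # (slope, intercept, R, p)


def session_separability(report: EmbeddingReport, C: float = 1.0) -> SeparabilityReport:
    """Linear SVM accuracy per session in the 2D embedding plane.

    The classifier is fit per session on that session's embedding coordinates
    and scored on its own training points (no cross-validation: the accuracy
    is a cluster-separability indicator, not a generalization estimate).
    Sessions with a single state are flagged with undefined accuracy.
    """
    rows = []
    for sess, grp in report.meta.groupby("session"):
        idx = grp.index.to_numpy()
        states = report.meta.loc[idx, "state"].to_numpy()
        if np.unique(states).size < 2:
            rows.append({"session": sess, "accuracy": np.nan, "flagged": True})
            continue
        clf = SVC(kernel="linear", C=C)
        pts = report.coords[idx]
        clf.fit(pts, states)
        acc = float(clf.score(pts, states))
        rows.append({"session": sess, "accuracy": acc, "flagged": False})
    df = pd.DataFrame(rows)
    ok = df[~df["flagged"]]
    trend = fit_linear_trend(ok["session"], ok["accuracy"]) if len(ok) >= 3 else (
        np.nan, np.nan, np.nan, np.nan)
    return SeparabilityReport(per_session=df, trend=trend)


# ---------------------------------------------------------------------------
# Intrinsic dimensionality
# ---------------------------------------------------------------------------

def _ess_expectation(n: float) -> float:
    """Expected norm-weighted sine of the angle between isotropic vector
    pairs in dimension ``n`` (strictly increasing, -> 1 as n -> inf)."""
    if n <= 1:
        return 0.0
    return float(np.exp(2 * gammaln(n / 2) - gammaln((n + 1) / 2)
                        - gammaln((n - 1) / 2)))


def _invert_ess(s: float, n_max: float = 1e6) -> float:
    """Dimension whose isotropic expectation matches statistic ``s``."""
    if s <= 0.0:
        return 1.0
    if s >= _ess_expectation(n_max):
        return float(n_max)
    return float(brentq(lambda n: _ess_expectation(n) - s, 1.0 + 1e-12, n_max))


def ess_local_id(features: np.ndarray, k: int = 100):
    """Expected-simplex-skewness local ID per point and its mean.

    Each point's neighborhood is its ``k`` nearest neighbors; vectors are
    taken from the neighborhood centroid; the statistic is the mean sine of
    pairwise angles weighted by the product of vector norms.  Points whose
    neighborhood is degenerate (duplicates collapsing all norms) are skipped
    and reported as NaN.
    """
    x = np.asarray(features, dtype=np.float64)
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    ids = np.full(n, np.nan)
    for i in range(n):
        nb = x[idx[i, 1:]]            # k neighbors, query point excluded
        v = nb - nb.mean(axis=0)
        g = v @ v.T
        d = np.diag(g).copy()
        wij = np.sqrt(np.outer(d, d))
        cross = np.maximum(wij ** 2 - g ** 2, 0.0)
        iu = np.triu_indices(k, 1)
        denom = wij[iu].sum()
        if denom <= 0:
            continue
        s = np.sqrt(cross[iu]).sum() / denom
        ids[i] = _invert_ess(s)
    valid = ids[np.isfinite(ids)]
    mean_id = float(valid.mean()) if valid.size else np.nan
    return ids, mean_id


def twonn_global_id(features: np.ndarray, discard_fraction: float = 0.1) -> float:
    """TwoNN global ID from first/second nearest-neighbor distance ratios.

    Exact duplicate rows are removed first so every first-neighbor distance
    is positive.  The estimate is the slope (through the origin) of
    -log(1 - F(mu)) against log(mu) after trimming the largest
    ``discard_fraction`` of the ratios.
    """
    x = np.unique(np.asarray(features, dtype=np.float64), axis=0)
    n = x.shape[0]
    if n < 100:
        raise ValueError("need at least 100 distinct points for TwoNN")
    nn = NearestNeighbors(n_neighbors=3).fit(x)
    dist, _ = nn.kneighbors(x)
    r1, r2 = dist[:, 1], dist[:, 2]
    ok = r1 > 0
    mu = np.sort(r2[ok] / r1[ok])
    m = mu.size
    keep = int(np.floor(m * (1.0 - discard_fraction)))
    mu = mu[:keep]
    f_emp = np.arange(1, keep + 1) / m
    lx = np.log(mu)
    ly = -np.log(1.0 - f_emp)
    denom = float(lx @ lx)
    if denom <= 0:
        raise ValueError("degenerate neighbor-distance ratios")
    return float((lx @ ly) / denom)


@dataclass
class IDReport:
    per_session: pd.DataFrame       # session, ess_mean, twonn
    per_window: pd.DataFrame | None = None
    correlation: tuple | None = None  # (r, p) vs decoder CS
    neighborhood: int = 100


def session_id_report(features: np.ndarray, sessions: np.ndarray,
                      k: int = 100) -> IDReport:
    """Per-session mean ESS local ID and TwoNN global ID."""
    rows = []
    sessions = np.asarray(sessions)
    for sess in np.unique(sessions):
        feats = features[sessions == sess]
        k_eff = min(k, feats.shape[0] - 1)
        _, ess_mean = ess_local_id(feats, k=k_eff)
        try:
            twonn = twonn_global_id(feats)
        except ValueError:
            twonn = np.nan
        rows.append({"session": sess, "ess_mean": ess_mean, "twonn": twonn})
    return IDReport(per_session=pd.DataFrame(rows), neighborhood=k)


def window_average_id(report: IDReport, windows: list) -> pd.DataFrame:
    """Average per-session IDs over training windows (lists of sessions)."""
    per = report.per_session.set_index("session")
    rows = []
    for w, sess_list in enumerate(windows):
        sub = per.loc[[s for s in sess_list if s in per.index]]
        rows.append({"window": w, "ess_mean": float(sub["ess_mean"].mean()),
                     "twonn": float(sub["twonn"].mean())})
    return pd.DataFrame(rows)


def correlate_id_performance(id_per_window, cs_per_window):
    """Pearson correlation (r, two-sided p) between window ID and decoder CS."""
    from scipy import stats

    a = np.asarray(id_per_window, dtype=float)
    b = np.asarray(cs_per_window, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired windows")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
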