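"""Weighted graph measures of PLI networks and surrogate normalization.

The network read-out consists of four numbers per recording and band:

* Cw -- mean weighted clustering coefficient. Per node i,
  ``C_i = sum_{k!=l} w_ik w_il w_kl / sum_{k!=l} w_ik w_il`` (sums over
  neighbors distinct from i), i.e. the weighted probability that two
  neighbors of i are themselves connected; Cw is the mean over nodes.
* Lw -- mean weighted shortest path length. Edge lengths are the
  reciprocal weights 1/w (a strong functional connection is a short
  functional distance); pairwise distances follow Dijkstra and Lw is the
  mean over all ordered pairs.
* gamma = Cw / <Cw over surrogates>, lambda = Lw / <Lw over surrogates>,
  where each surrogate randomly shuffles the upper-triangle weights while
  keeping the matrix symmetric. The ratio removes the dependence of the
  raw measures on network size and overall connection strength; values
  near 1 indicate random organization, larger values ordered/small-world
  structure.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator

from .types import ConnectivityMatrix, NetworkMeasures


def _as_weights(net) -> np.ndarray:
    W = net.weights if isinstance(net, ConnectivityMatrix) else np.asarray(net, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weights must be symmetric")
    if not np.isfinite(W).all():
        raise ValueError("weights must be finite")
    if W.min() < 0:
        raise ValueError("weights must be non-negative")
    return np.asarray(W, dtype=float)


def weighted_clustering(net) -> float:
    """Mean weighted clustering coefficient Cw.

    Nodes whose open-triple denominator is zero (isolated or degree-1
    nodes) contribute C_i = 0.
    """
    W = _as_weights(net)
    n = W.shape[0]
    if n < 3:
        raise ValueError("clustering requires at least 3 nodes")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    # For zero diagonal, (W^3)_ii equals the closed-triple sum
    # sum_{k!=l, k,l!=i} w_ik w_kl w_li.
    num = np.einsum("ij,jk,ki->i", W, W, W)
    s = W.sum(axis=1)
    q = (W ** 2).sum(axis=1)
    den = s ** 2 - q  # open triples: (sum_k w_ik)^2 - sum_k w_ik^2
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(den > 0, num / den, 0.0)
    return float(ci.mean())


def weighted_path_length(net) -> float:
    """Mean weighted shortest path length Lw (Dijkstra on lengths 1/w).

    Zero-weight entries are treated as absent edges. If the graph is
    disconnected, unreachable pair distances are set to 1/eps with eps the
    smallest positive weight in the matrix, and a warning is emitted;
    19-channel PLI matrices are in practice fully connected.
    """
    W = _as_weights(net)
    n = W.shape[0]
    if n < 2:
        raise ValueError("path length requires at least 2 nodes")
    if not (W > 0).any():
        raise ValueError("all-zero weight matrix: no network")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    D = dijkstra(lengths, directed=False)
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    if np.isinf(d).any():
        eps = W[W > 0].min()
        warnings.warn(
            "disconnected network: unreachable pair distances set to "
            f"1/{eps:g}", stacklevel=2,
        )
        d = np.where(np.isinf(d), 1.0 / eps, d)
    return float(d.mean())


def shuffle_surrogate(net, rng: np.random.Generator):
    """Random surrogate: permute upper-triangle weights, keep symmetry.

    Preserves the multiset of edge weights (and hence overall connection
    strength) while destroying any topological organization.
    """
    W = _as_weights(net)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = W[iu].copy()
    rng.shuffle(vals)
    S = np.zeros_like(W)
    S[iu] = vals
    S = S + S.T
    if isinstance(net, ConnectivityMatrix):
        return ConnectivityMatrix(weights=S, labels=list(net.labels),
                                  band=net.band, epoch_id=net.epoch_id)
    return S


def normalized_measures(net, n_surrogates: int = 50,
                        seed: int | None = None,
                        band: str | None = None) -> NetworkMeasures:
    """Cw, Lw and their surrogate-normalized ratios gamma and lambda.

    The surrogate ensemble (default 50 networks) uses an RNG stream
    derived deterministically from ``seed``.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    W = _as_weights(net)
    if band is None and isinstance(net, ConnectivityMatrix):
        band = net.band
    cw = weighted_clustering(W)
    lw = weighted_path_length(W)
    rng = np.random.default_rng(seed)
    cw_s = np.empty(n_surrogates)
    lw_s = np.empty(n_surrogates)
    for k in range(n_surrogates):
        S = shuffle_surrogate(W, rng)
        cw_s[k] = weighted_clustering(S)
        lw_s[k] = weighted_path_length(S)
    cbar, lbar = cw_s.mean(), lw_s.mean()
    if cbar == 0 or lbar == 0:
        raise ValueError("surrogate mean is zero: normalization undefined")
    return NetworkMeasures(cw=cw, lw=lw, gamma=cw / cbar, lambda_=lw / lbar,
                           band=band, n_surrogates=n_surrogates, seed=seed)


def measures_per_recording(mats: list[ConnectivityMatrix],
                           n_surrogates: int = 50,
                           seed: int | None = None,
                           average: str = "measures") -> NetworkMeasures:
    """Aggregate the graph read-out over the epochs of one recording.

    average="measures" (default): normalized measures are computed per
    epoch matrix and then averaged arithmetically; the per-epoch values
    are kept on ``per_epoch`` for provenance. average="matrix": the epoch
    PLI matrices are element-wise averaged first and the measures computed
    once on the mean matrix.
    """
    if not mats:
        raise ValueError("no connectivity matrices given")
    bands = {m.band for m in mats}
    if len(bands) > 1:
        raise ValueError(f"mixed bands in one aggregation: {sorted(map(str, bands))}")
    band = mats[0].band
    if average not in ("measures", "matrix"):
        raise ValueError(f"unknown averaging order {average!r}")
    seeds = np.random.SeedSequence(seed).generate_state(len(mats)) % (2 ** 31)
    if average == "matrix":
        Wbar = np.mean([m.weights for m in mats], axis=0)
        out = normalized_measures(Wbar, n_surrogates, int(seeds[0]), band=band)
        out.seed = seed
        return out
    per = [normalized_measures(m, n_surrogates, int(s), band=band)
           for m, s in zip(mats, seeds)]
    return NetworkMeasures(
        cw=float(np.mean([p.cw for p in per])),
        lw=float(np.mean([p.lw for p in per])),
        gamma=float(np.mean([p.gamma for p in per])),
        lambda_=float(np.mean([p.lambda_ for p in per])),
        band=band, n_surrogates=n_surrogates, seed=seed, per_epoch=per,
    )


class SmallWorldMetrics(BaseEstimator):
    """Estimator computing the surrogate-normalized small-world read-out.

    Parameters
    ----------
    n_surrogates : surrogate networks per input network (default 50).
    seed : master seed for the surrogate RNG streams.
    average : "measures" (per-epoch measures averaged) or "matrix"
        (epoch matrices averaged before measuring).

    Attributes (after fit)
    ----------------------
    measures_ : NetworkMeasures with cw_, lw_, gamma_, lambda_ mirrors.
    """

    def __init__(self, n_surrogates: int = 50, seed: int | None = None,
                 average: str = "measures"):
        self.n_surrogates = n_surrogates
        self.seed = seed
        self.average = average

    def fit(self, X, y=None):
        """X: a weight matrix, a ConnectivityMatrix, or a list of epoch
        ConnectivityMatrix objects of a single band."""
        if isinstance(X, list):
            m = measures_per_recording(X, self.n_surrogates, self.seed,
                                       self.average)
        else:
            m = normalized_measures(X, self.n_surrogates, self.seed)
        self.measures_ = m
        self.cw_ = m.cw
        self.lw_ = m.lw
        self.gamma_ = m.gamma
        self.lambda_ = m.lambda_
        return self
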