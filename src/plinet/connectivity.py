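"""Phase Lag Index (PLI) functional connectivity.

The PLI between two narrowband signals is the absolute time-average of
the sign of the sine of their instantaneous phase difference::

    PLI = | < sign(sin(phi_i(t) - phi_j(t))) >_t |,   sign(0) = 0

It is 0 when the phase difference is symmetric around 0 or pi (the
signature of volume conduction: one source seen instantaneously at two
electrodes) and 1 when one signal consistently leads or lags the other.
Discarding zero phase differences (sign(0) = 0) is what makes the index
insensitive to instantaneously mixed common sources.

Instantaneous phase is taken as the argument of the analytic signal
(Hilbert transform) of the band-filtered epoch, with the edges trimmed to
suppress transform end effects.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .types import ConnectivityMatrix, Epoch, PhaseSeries

#: Samples discarded at each end of an epoch before phase statistics.
DEFAULT_EDGE_TRIM = 128


def instantaneous_phase(epoch: Epoch, edge_trim: int = DEFAULT_EDGE_TRIM) -> PhaseSeries:
    """Per-channel instantaneous phase of a band-filtered epoch.

    Parameters
    ----------
    epoch : band-filtered epoch (phases of broadband signals are not
        physically interpretable).
    edge_trim : samples discarded per side to suppress Hilbert edge
        artifacts (default 128).

    Raises
    ------
    ValueError : if the epoch is too short after trimming, or if any
        channel is identically zero (phase undefined).
    """
    if epoch.n_samples < 2 * edge_trim + 2:
        raise ValueError(
            f"epoch of {epoch.n_samples} samples too short for an edge trim "
            f"of {edge_trim} per side"
        )
    if np.any(np.all(epoch.data == 0, axis=1)):
        raise ValueError("constant-zero channel: instantaneous phase undefined")
    analytic = hilbert(epoch.data, axis=1)
    phases = np.angle(analytic)
    if edge_trim:
        phases = phases[:, edge_trim:-edge_trim]
    return PhaseSeries(phases=phases, rate=epoch.rate, band=epoch.band,
                       edge_trim=edge_trim)


def pli_pair(phi_i: np.ndarray, phi_j: np.ndarray) -> float:
    """PLI between two equal-length phase series (radians)."""
    phi_i = np.asarray(phi_i, dtype=float)
    phi_j = np.asarray(phi_j, dtype=float)
    if phi_i.shape != phi_j.shape:
        raise ValueError(
            f"phase series lengths differ: {phi_i.shape} vs {phi_j.shape}"
        )
    return float(np.abs(np.mean(np.sign(np.sin(phi_i - phi_j)))))


def pli_matrix(phases: PhaseSeries, labels: list[str] | None = None,
               epoch_id: int | None = None) -> ConnectivityMatrix:
    """PLI between every unordered channel pair.

    Returns a symmetric matrix with an exactly zero diagonal; entries lie
    in [0, 1].
    """
    P = phases.phases
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels")
    # sign(sin(phi_i - phi_j)) for all pairs at once
    diffs = P[:, None, :] - P[None, :, :]
    W = np.abs(np.sign(np.sin(diffs)).mean(axis=-1))
    W = (W + W.T) / 2  # enforce exact symmetry against float asymmetry
    np.fill_diagonal(W, 0.0)
    if labels is None:
        labels = [f"ch{i}" for i in range(n)]
    return ConnectivityMatrix(weights=W, labels=labels, band=phases.band,
                              epoch_id=epoch_id)


class PhaseLagIndex(TransformerMixin, BaseEstimator):
    """Transformer from band-filtered epochs to PLI connectivity matrices.

    Parameters
    ----------
    edge_trim : samples trimmed per epoch side before phase statistics.
    """

    def __init__(self, edge_trim: int = DEFAULT_EDGE_TRIM):
        self.edge_trim = edge_trim

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[Epoch],
                  labels: list[str] | None = None) -> list[ConnectivityMatrix]:
        out = []
        for k, epoch in enumerate(X):
            ph = instantaneous_phase(epoch, edge_trim=self.edge_trim)
            out.append(pli_matrix(ph, labels=labels, epoch_id=k))
        return out


def connectivity_to_edges(mat: ConnectivityMatrix) -> "pd.DataFrame":
    """Long-format edge list (ch_i, ch_j, band, epoch, pli)."""
    import pandas as pd

    n = mat.n_channels
    iu, ju = np.triu_indices(n, k=1)
    return pd.DataFrame({
        "ch_i": [mat.labels[i] for i in iu],
        "ch_j": [mat.labels[j] for j in ju],
        "band": mat.band,
        "epoch": mat.epoch_id,
        "pli": mat.weights[iu, ju],
    })


def edges_to_connectivity(edges: "pd.DataFrame") -> ConnectivityMatrix:
    """Rebuild a square matrix from a long-format edge list."""
    labels = sorted(set(edges["ch_i"]) | set(edges["ch_j"]))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    for _, row in edges.iterrows():
        i, j = index[row["ch_i"]], index[row["ch_j"]]
        W[i, j] = W[j, i] = row["pli"]
    band = edges["band"].iloc[0] if "band" in edges else None
    epoch = edges["epoch"].iloc[0] if "epoch" in edges else None
    return ConnectivityMatrix(weights=W, labels=labels, band=band,
                              epoch_id=epoch)
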