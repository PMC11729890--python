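"""Batch-trained Kohonen self-organizing map on normalized ΔR1 profiles.

An 8×8 hexagonal lattice of prototype vectors is trained in batch mode:
each epoch assigns every input to its best matching unit (BMU, minimal
Euclidean distance) and replaces each prototype by the neighborhood-kernel
weighted mean of the inputs.  The neighborhood radius decays linearly from
``initial_neighborhood`` (3 lattice units) to 1 over ``cover_steps`` epochs
(the ordering phase) and then stays at 1 for the remaining tuning epochs,
up to ``max_epochs`` (250).  The kernel is a Gaussian in hexagonal lattice
distance, truncated at the current radius, with sigma = radius / 2.

Given model labels from the conventional nested model selection, per-neuron
hit counts K_j(m, n) and the per-neuron model probabilities

    P_j(m, n) = K_j(m, n) / (K_1(m, n) + K_2(m, n) + K_3(m, n))

are computed.  The literal formulation carries an additional constant
prefactor 1/((Σ_1..8 n)·(Σ_1..8 m)) = 1/1296; it cancels in the
model-averaging equations and is available via ``scaling="literal"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .kinetics import ConcentrationProfile

__all__ = [
    "hex_positions",
    "normalize_profile",
    "normalize_profiles",
    "KohonenSOM",
    "HitMaps",
    "NeuronProbabilities",
    "hit_maps",
    "neuron_probabilities",
]

N_MODELS = 3


def hex_positions(rows: int, cols: int, topology: str = "hexagonal") -> np.ndarray:
    """Lattice coordinates of a rows×cols map, row-major neuron order.

    Hexagonal: odd rows are offset by half a unit and rows are √3/2 apart,
    so nearest neighbors sit at distance 1.  Rectangular: integer grid.
    """

    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if topology == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
    elif topology == "rectangular":
        x, y = c.astype(float), r.astype(float)
    else:
        raise ValueError("topology must be 'hexagonal' or 'rectangular'")
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def normalize_profiles(C: np.ndarray, n_baseline: int) -> np.ndarray:
    """Peak-normalized feature vectors from raw profiles (rows of ``C``).

    The baseline mean (over the ``n_baseline`` leading samples) is
    subtracted, the post-baseline segment is kept and scaled by its own
    maximum absolute value, giving features in [−1, 1] with peak 1 (an
    all-zero profile maps to the all-zero vector).
    """

    C = np.atleast_2d(np.asarray(C, dtype=float))
    if not 0 <= n_baseline < C.shape[1]:
        raise ValueError("n_baseline out of range")
    base = C[:, :n_baseline].mean(axis=1, keepdims=True) if n_baseline > 0 else 0.0
    feat = C[:, n_baseline:] - base
    scale = np.max(np.abs(feat), axis=1, keepdims=True)
    return np.divide(feat, scale, out=np.zeros_like(feat), where=scale > 0)


def normalize_profile(profile: ConcentrationProfile) -> np.ndarray:
    """Feature vector of a single profile (see :func:`normalize_profiles`)."""

    return normalize_profiles(profile.c[None, :], profile.grid.n_baseline)[0]


class KohonenSOM(BaseEstimator, TransformerMixin):
    """Batch self-organizing map on a hexagonal lattice.

    Parameters
    ----------
    rows, cols : int
        Lattice size (8×8 by default).
    topology : str
        "hexagonal" (default) or "rectangular".
    initial_neighborhood : float
        Starting neighborhood radius in lattice-distance units.
    cover_steps : int
        Epochs of the ordering phase (linear radius decay to 1).
    max_epochs : int
        Total training epochs (ordering + tuning).
    tol : float
        Early-stop threshold on the maximum absolute weight change,
        applied only after the ordering phase (0 disables).
    random_state : int or None
        Seeds prototype initialization; training is deterministic given it.

    Attributes
    ----------
    weights_ : (rows*cols, n_features) prototype vectors, row-major.
    positions_ : (rows*cols, 2) lattice coordinates.
    quantization_errors_ : per-epoch mean BMU distance (before update).
    n_iter_ : number of epochs run.
    """

    def __init__(
        self,
        rows: int = 8,
        cols: int = 8,
        topology: str = "hexagonal",
        initial_neighborhood: float = 3.0,
        cover_steps: int = 100,
        max_epochs: int = 250,
        tol: float = 1e-9,
        random_state=None,
    ):
        self.rows = rows
        self.cols = cols
        self.topology = topology
        self.initial_neighborhood = initial_neighborhood
        self.cover_steps = cover_steps
        self.max_epochs = max_epochs
        self.tol = tol
        self.random_state = random_state

    # -- internals ----------------------------------------------------
    def _radius(self, epoch: int) -> float:
        r0 = float(self.initial_neighborhood)
        if epoch >= self.cover_steps:
            return 1.0
        return max(1.0, r0 - (r0 - 1.0) * epoch / self.cover_steps)

    def _bmu_sqdist(self, X):
        W = self.weights_
        d2 = (
            np.einsum("ij,ij->i", X, X)[:, None]
            - 2.0 * (X @ W.T)
            + np.einsum("ij,ij->i", W, W)[None, :]
        )
        np.clip(d2, 0.0, None, out=d2)
        return d2

    def fit(self, X, y=None):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("rows and cols must be >= 2")
        X = check_array(X, dtype=float, ensure_2d=True)
        n, n_feat = X.shape
        k = self.rows * self.cols
        if n == 0:
            raise ValueError("empty training set")
        if n < k:
            warnings.warn(
                f"fewer training vectors ({n}) than neurons ({k}); prototypes will repeat",
                stacklevel=2,
            )
        rng = check_random_state(self.random_state)
        order = rng.permutation(n)
        X = X[order]
        init_idx = rng.choice(n, size=k, replace=n < k)
        self.positions_ = hex_positions(self.rows, self.cols, self.topology)
        diff = self.positions_[:, None, :] - self.positions_[None, :, :]
        self.lattice_distances_ = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        W = X[init_idx].copy()
        self.weights_ = W
        qe_trace = []
        D2L = self.lattice_distances_**2
        for epoch in range(self.max_epochs):
            d2 = self._bmu_sqdist(X)
            bmu = np.argmin(d2, axis=1)
            qe_trace.append(float(np.mean(np.sqrt(d2[np.arange(n), bmu]))))
            r = self._radius(epoch)
            sigma2 = (r / 2.0) ** 2
            H = np.exp(-D2L / (2.0 * sigma2))
            H[self.lattice_distances_ > r + 1e-12] = 0.0
            S = np.zeros((k, n_feat))
            np.add.at(S, bmu, X)
            counts = np.bincount(bmu, minlength=k).astype(float)
            num = H @ S
            den = H @ counts
            W_new = W.copy()
            upd = den > 0
            W_new[upd] = num[upd] / den[upd, None]
            delta = float(np.max(np.abs(W_new - W))) if W.size else 0.0
            W = W_new
            self.weights_ = W
            if self.tol > 0 and epoch >= self.cover_steps and delta < self.tol:
                break
        self.n_iter_ = epoch + 1
        self.quantization_errors_ = np.asarray(qe_trace)
        self.n_features_in_ = n_feat
        return self

    # -- inference ----------------------------------------------------
    def _check_features(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(np.atleast_2d(X), dtype=float, ensure_2d=True)
        if X.shape[1] != self.weights_.shape[1]:
            raise ValueError("feature length does not match the trained prototypes")
        return X

    def transform(self, X):
        """Euclidean distances to every prototype, shape (n, rows*cols)."""

        X = self._check_features(X)
        return np.sqrt(self._bmu_sqdist(X))

    def predict(self, X):
        """Flat (row-major) BMU index per input; ties break to the smallest index."""

        X = self._check_features(X)
        return np.argmin(self._bmu_sqdist(X), axis=1)

    def bmu(self, feature) -> tuple[int, int]:
        """(row, col) of the best matching unit for one feature vector."""

        j = int(self.predict(np.atleast_2d(feature))[0])
        return divmod(j, self.cols)


@dataclass
class HitMaps:
    """Label-conditioned BMU hit counts, shape (3, rows, cols)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.shape[0] != N_MODELS:
            raise ValueError("counts must have shape (3, rows, cols)")
        if np.any(counts < 0):
            raise ValueError("hit counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class NeuronProbabilities:
    """Per-neuron model probabilities P_j(m, n), shape (3, rows, cols).

    ``empty_mask`` marks neurons with zero total hits, whose values were
    filled from the nearest non-empty neuron on the lattice.  ``scaling``
    records whether P is the normalized ratio (sums to 1 per neuron) or the
    literal constant-prefactor variant.
    """

    P: np.ndarray
    empty_mask: np.ndarray
    scaling: str = "normalized"


def hit_maps(model: KohonenSOM, features: np.ndarray, labels: np.ndarray) -> HitMaps:
    """Count, per neuron and model label, how often that neuron is the BMU."""

    labels = np.asarray(labels)
    features = np.atleast_2d(features)
    if labels.shape[0] != features.shape[0]:
        raise ValueError("labels and features must have equal length")
    if not np.isin(labels, [1, 2, 3]).all():
        raise ValueError("labels must be in {1, 2, 3}")
    bmu = model.predict(features)
    k = model.rows * model.cols
    counts = np.zeros((N_MODELS, k), dtype=np.int64)
    for j in (1, 2, 3):
        counts[j - 1] = np.bincount(bmu[labels == j], minlength=k)
    return HitMaps(counts.reshape(N_MODELS, model.rows, model.cols))


def neuron_probabilities(
    hits: HitMaps,
    scaling: str = "normalized",
    empty_fill: str = "nearest",
    positions: np.ndarray | None = None,
    topology: str = "hexagonal",
) -> NeuronProbabilities:
    """Per-neuron model probabilities from label-conditioned hit counts.

    ``scaling="normalized"`` (canonical) stores P_j = K_j / ΣK, which sums
    to 1 at every non-empty neuron; ``"literal"`` additionally multiplies by
    the constant 1/((Σ1..rows)·(Σ1..cols)) of the original formulation
    (1/1296 for 8×8), which cancels in all downstream averaging.  Empty
    neurons are filled from the nearest non-empty neuron on the lattice
    (``empty_fill="nearest"``, ties averaged) or set uniform
    (``empty_fill="uniform"``), and flagged in ``empty_mask``.
    """

    counts = hits.counts.astype(float)
    _, rows, cols = counts.shape
    tot = counts.sum(axis=0)
    empty = tot == 0
    if empty.all():
        raise ValueError("all neurons are empty; cannot form probabilities")
    P = np.divide(counts, tot, out=np.zeros_like(counts), where=tot > 0)
    if empty.any():
        if empty_fill == "uniform":
            P[:, empty] = 1.0 / N_MODELS
        elif empty_fill == "nearest":
            if positions is None:
                positions = hex_positions(rows, cols, topology)
            Pf = P.reshape(N_MODELS, -1)
            e = empty.ravel()
            d = np.sqrt(((positions[e][:, None, :] - positions[~e][None, :, :]) ** 2).sum(-1))
            dmin = d.min(axis=1, keepdims=True)
            near = d <= dmin + 1e-9
            w = near / near.sum(axis=1, keepdims=True)
            filled = w @ Pf[:, ~e].T  # (n_empty, 3)
            Pf[:, e] = filled.T
            P = Pf.reshape(N_MODELS, rows, cols)
        else:
            raise ValueError("empty_fill must be 'nearest' or 'uniform'")
    if scaling == "literal":
        pref = 1.0 / (np.arange(1, rows + 1).sum() * np.arange(1, cols + 1).sum())
        P = P * pref
    elif scaling != "normalized":
        raise ValueError("scaling must be 'normalized' or 'literal'")
    return NeuronProbabilities(P=P, empty_mask=empty, scaling=scaling)
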