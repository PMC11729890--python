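"""Probabilistic nested model selection: SOM-derived voxel probabilities and
probability-weighted (model-averaged) permeability maps.

A voxel's normalized ΔR1 profile is mapped to its best matching unit on the
trained SOM; the neuron's label-conditioned probabilities (P1, P2, P3)
become the voxel's model weights.  The averaged parameters are

    vp     = (P1·vp^(M1) + P2·vp^(M2) + P3·vp^(M3)) / (P1 + P2 + P3)
    Ktrans = (P2·Ktrans^(M2) + P3·Ktrans^(M3)) / (P2 + P3)
    ve     = Ktrans / kep^(M3)

using each voxel's three conventional NMS fits.  All three expressions are
invariant to a common rescaling of the P_j, so the constant prefactor of
the literal per-neuron probability formula has no effect here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .kinetics import AIF, ConcentrationProfile, fit_models_matrix
from .nms import _sequential_labels
from .som import (
    KohonenSOM,
    NeuronProbabilities,
    hit_maps,
    neuron_probabilities,
    normalize_profile,
    normalize_profiles,
)

__all__ = [
    "VoxelProbabilities",
    "PNMSModel",
    "voxel_probabilities",
    "averaged_vp",
    "averaged_ktrans",
    "averaged_ve",
    "run_pnms_volume",
]


@dataclass
class VoxelProbabilities:
    """Model probabilities (P1, P2, P3) for a set of voxels, rows sum to 1."""

    P: np.ndarray  # (n_voxels, 3)
    empty_bmu: np.ndarray | None = None  # voxels whose BMU had zero training hits


class PNMSModel(BaseEstimator):
    """SOM-based probabilistic model classifier (fit on NMS-labeled features).

    ``fit(X, y)`` trains the Kohonen map on the normalized profile features
    ``X`` and tabulates label-conditioned hit maps from the conventional-NMS
    labels ``y`` (1, 2 or 3).  ``predict_proba(X)`` returns each feature's
    BMU probabilities (P1, P2, P3); ``predict`` the argmax model.

    SOM hyperparameters mirror :class:`~dcepnms.som.KohonenSOM`.
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
        empty_fill: str = "nearest",
        scaling: str = "normalized",
        random_state=None,
    ):
        self.rows = rows
        self.cols = cols
        self.topology = topology
        self.initial_neighborhood = initial_neighborhood
        self.cover_steps = cover_steps
        self.max_epochs = max_epochs
        self.tol = tol
        self.empty_fill = empty_fill
        self.scaling = scaling
        self.random_state = random_state

    def fit(self, X, y):
        som = KohonenSOM(
            rows=self.rows,
            cols=self.cols,
            topology=self.topology,
            initial_neighborhood=self.initial_neighborhood,
            cover_steps=self.cover_steps,
            max_epochs=self.max_epochs,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(X)
        self.som_ = som
        self.hits_ = hit_maps(som, X, y)
        self.neuron_probabilities_ = neuron_probabilities(
            self.hits_, scaling=self.scaling, empty_fill=self.empty_fill,
            positions=som.positions_, topology=self.topology,
        )
        return self

    def predict_proba(self, X):
        """(n, 3) model probabilities of each feature's BMU (rows sum to 1
        under the canonical scaling)."""

        check_is_fitted(self, "som_")
        bmu = self.som_.predict(X)
        Pf = self.neuron_probabilities_.P.reshape(3, -1)
        return Pf[:, bmu].T

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1) + 1

    def bmu_is_empty(self, X):
        """Quality flag: True where the BMU had zero training hits."""

        check_is_fitted(self, "som_")
        bmu = self.som_.predict(X)
        return self.neuron_probabilities_.empty_mask.ravel()[bmu]


def voxel_probabilities(
    som: KohonenSOM, probs: NeuronProbabilities, profile: ConcentrationProfile
) -> np.ndarray:
    """(P1, P2, P3) of a single voxel: its BMU's neuron probabilities."""

    feat = normalize_profile(profile)
    j = int(som.predict(feat[None, :])[0])
    return probs.P.reshape(3, -1)[:, j].copy()


# ---------------------------------------------------------------------------
# model-averaged parameters
# ---------------------------------------------------------------------------

def averaged_vp(P: np.ndarray, vp1, vp2, vp3):
    """Probability-weighted plasma volume over all three models.

    ``P`` is (..., 3); renormalizes by P1+P2+P3 (so any common rescaling of
    the probabilities cancels).  A zero probability sum yields NaN.
    """

    P = np.asarray(P, dtype=float)
    s = P.sum(axis=-1)
    num = P[..., 0] * vp1 + P[..., 1] * vp2 + P[..., 2] * vp3
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, num / np.where(s > 0, s, 1.0), np.nan)
    return out if np.ndim(out) else float(out)


def averaged_ktrans(P: np.ndarray, kt2, kt3):
    """Probability-weighted Ktrans over the leaky models (2 and 3).

    Renormalizes by P2+P3.  Where P2+P3 = 0 the voxel is treated as
    non-leaky and the value is 0 (callers may flag it).
    """

    P = np.asarray(P, dtype=float)
    s = P[..., 1] + P[..., 2]
    num = P[..., 1] * kt2 + P[..., 2] * kt3
    out = np.where(s > 0, num / np.where(s > 0, s, 1.0), 0.0)
    return out if np.ndim(out) else float(out)


def averaged_ve(ktrans_avg, kep_m3):
    """Interstitial volume fraction: averaged Ktrans over the model-3 kep.

    Undefined (NaN) where kep^(M3) <= 0.
    """

    ktrans_avg = np.asarray(ktrans_avg, dtype=float)
    kep_m3 = np.asarray(kep_m3, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(kep_m3 > 0, ktrans_avg / np.where(kep_m3 > 0, kep_m3, 1.0), np.nan)
    return out if np.ndim(out) else float(out)


@dataclass
class PNMSVolumeResult:
    """Voxel-wise probability maps, averaged parameter maps, masks and flags."""

    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    vp: np.ndarray
    ktrans: np.ndarray
    ve: np.ndarray
    masks: dict[int, np.ndarray]
    rgb: np.ndarray
    nms_label: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)


def run_pnms_volume(
    volume4d: np.ndarray,
    mask: np.ndarray,
    aif: AIF,
    model: PNMSModel,
    alpha: float = 0.05,
    threshold: float = 0.5,
    mask_model1: bool = True,
) -> PNMSVolumeResult:
    """Probabilistic NMS over a 4-D volume.

    Per voxel: normalize the profile, read its BMU probabilities, fit the
    three nested models, and form the averaged vp / Ktrans / ve maps.
    Binary model masks are thresholded at ``threshold`` (default 50%); with
    ``mask_model1`` the model-1 region is removed from the brain before the
    model-2/3 masks are formed (validation parity with the conventional
    pipeline).  The fused RGB map codes (R, G, B) = (P3, P2, P1).
    """

    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) volume")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume4d.shape[:3]:
        raise ValueError("mask shape does not match the volume")
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError("mask selects no voxels")
    X = volume4d.reshape(-1, volume4d.shape[3])[idx]
    grid = aif.grid
    if X.shape[1] != grid.n_t:
        raise ValueError("volume time axis does not match the AIF grid")

    feats = normalize_profiles(X, grid.n_baseline)
    P = model.predict_proba(feats)
    empty_flag = model.bmu_is_empty(feats)
    fits = fit_models_matrix(X, aif)
    labels, *_ = _sequential_labels(
        fits["ssr1"], fits["ssr2"], fits["ssr3"], fits["cc"], fits["n_fit"], alpha
    )

    vp = averaged_vp(P, fits["vp1"], fits["vp2"], fits["vp3"])
    kt = averaged_ktrans(P, fits["kt2"], fits["kt3"])
    ve = averaged_ve(kt, fits["kep3"])
    nonleaky = (P[:, 1] + P[:, 2]) <= 0
    kep_nonpos = fits["kep3"] <= 0
    low_p3 = P[:, 2] < threshold

    s = P.sum(axis=1, keepdims=True)
    Pn = np.divide(P, s, out=np.full_like(P, np.nan), where=s > 0)

    shape3 = volume4d.shape[:3]

    def to_map(v, fill=0.0, dtype=float):
        m = np.full(np.prod(shape3), fill, dtype=dtype)
        m[idx] = v
        return m.reshape(shape3)

    P1m, P2m, P3m = (to_map(Pn[:, j]) for j in range(3))
    m1 = to_map(Pn[:, 0] >= threshold, fill=False, dtype=bool)
    remaining = mask & ~m1
    m2 = to_map(Pn[:, 1] >= threshold, fill=False, dtype=bool)
    m3 = to_map(Pn[:, 2] >= threshold, fill=False, dtype=bool)
    if mask_model1:
        m2 &= remaining
        m3 &= remaining
    rgb = np.zeros(shape3 + (3,), dtype=np.uint8)
    for ch, pm in zip(range(3), (P3m, P2m, P1m)):
        rgb[..., ch] = np.round(np.nan_to_num(pm) * 255).astype(np.uint8)

    return PNMSVolumeResult(
        P1=P1m, P2=P2m, P3=P3m,
        vp=to_map(vp), ktrans=to_map(kt), ve=to_map(np.nan_to_num(ve)),
        masks={1: m1, 2: m2, 3: m3},
        rgb=rgb,
        nms_label=to_map(labels, dtype=np.int8),
        flags={
            "empty_bmu": to_map(empty_flag, fill=False, dtype=bool),
            "nonleaky": to_map(nonleaky, fill=False, dtype=bool),
            "kep_nonpositive": to_map(kep_nonpos, fill=False, dtype=bool),
            "low_p3_ve": to_map(low_p3, fill=False, dtype=bool),
        },
    )
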