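"""Conventional nested model selection (NMS) by sequential F-tests.

For every voxel the three nested models are fitted and compared to their
reduced alternatives: Model 1 vs Model 2 and, only if Model 2 is accepted,
Model 2 vs Model 3.  Each comparison uses the standard nested-regression
F-statistic

    F = ((SSR_reduced − SSR_full) / df_extra) / (SSR_full / df_resid)

thresholded at a confidence level (95% by default, i.e. alpha = 0.05).
Residual degrees of freedom use the post-baseline sample count minus the
number of parameters of the fuller model.  Ties and perfect fits resolve
toward the simpler model (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .kinetics import (
    AIF,
    ConcentrationProfile,
    ModelFit,
    PKParams,
    fit_model,
    fit_models_matrix,
)
from .kinetics import _PERFECT_FIT_RTOL

__all__ = ["NMSResult", "f_statistic", "f_pvalue", "select_model", "NestedModelSelector", "run_nms_volume"]


def f_statistic(ssr_reduced, ssr_full, df_extra: int, df_resid: int):
    """Nested-regression F-statistic; accepts scalars or arrays.

    Negative numerators (impossible for exact nesting, possible from
    roundoff) are clipped to 0.  ``ssr_full == 0`` with a strictly larger
    ``ssr_reduced`` returns the infinite-F sentinel (perfect fit of the
    fuller model); two perfect fits give F = 0.
    """

    ssr_reduced = np.asarray(ssr_reduced, dtype=float)
    ssr_full = np.asarray(ssr_full, dtype=float)
    if df_extra < 1 or df_resid < 1:
        raise ValueError("df_extra and df_resid must be >= 1")
    if np.any(ssr_full < 0):
        raise ValueError("ssr_full must be >= 0")
    num = np.clip(ssr_reduced - ssr_full, 0.0, None) / df_extra
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssr_full > 0, num / (ssr_full / df_resid), np.where(num > 0, np.inf, 0.0))
    return f if f.ndim else float(f)


def f_pvalue(f, df_extra: int, df_resid: int):
    """Upper-tail probability of the F(df_extra, df_resid) distribution."""

    return stats.f.sf(f, df_extra, df_resid)


@dataclass
class NMSResult:
    """Per-voxel outcome of the sequential nested model selection."""

    label: int
    f12: float
    p12: float
    f23: float
    p23: float
    fits: dict[int, ModelFit]


def _sequential_labels(ssr1, ssr2, ssr3, cc, n_fit: int, alpha: float):
    """Vectorized sequential 1→2→3 selection with a perfect-fit guard.

    A reduced model whose SSR is at numerical roundoff relative to the
    signal energy (``cc``) is already a perfect description, so the fuller
    model is never accepted from it.
    """

    floor = _PERFECT_FIT_RTOL * np.maximum(cc, 1e-300)
    f12 = np.asarray(f_statistic(ssr1, ssr2, 1, n_fit - 2), dtype=float)
    f23 = np.asarray(f_statistic(ssr2, ssr3, 1, n_fit - 3), dtype=float)
    f12 = np.where(ssr1 <= floor, 0.0, f12)
    f23 = np.where(ssr2 <= floor, 0.0, f23)
    p12 = f_pvalue(f12, 1, n_fit - 2)
    p23 = f_pvalue(f23, 1, n_fit - 3)
    labels = np.ones(f12.shape, dtype=np.int8)
    promote2 = p12 < alpha
    labels[promote2] = 2
    labels[promote2 & (p23 < alpha)] = 3
    return labels, f12, p12, f23, p23


class NestedModelSelector(BaseEstimator):
    """Voxel-wise nested model selection as a scikit-learn style estimator.

    Parameters
    ----------
    aif : AIF
        Arterial input function sharing the acquisition time grid (its
        ``n_baseline`` leading samples are excluded from the residuals).
    alpha : float
        F-test tail probability; 0.05 reproduces the 95% confidence level.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (n_voxels,) int array of selected models (1, 2 or 3)
    fits_ : dict of per-voxel parameter/SSR arrays for all three models
    f12_, p12_, f23_, p23_ : per-voxel test statistics and p-values
    """

    def __init__(self, aif: AIF = None, alpha: float = 0.05):
        self.aif = aif
        self.alpha = alpha

    def _check(self, X):
        if self.aif is None:
            raise ValueError("an AIF is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        X = check_array(X, dtype=float, ensure_2d=True)
        if X.shape[1] != self.aif.grid.n_t:
            raise ValueError("profiles do not match the AIF time grid length")
        return X

    def fit(self, X, y=None):
        X = self._check(X)
        fits = fit_models_matrix(X, self.aif)
        labels, f12, p12, f23, p23 = _sequential_labels(
            fits["ssr1"], fits["ssr2"], fits["ssr3"], fits["cc"], fits["n_fit"], self.alpha
        )
        self.n_features_in_ = X.shape[1]
        self.fits_ = fits
        self.labels_ = labels
        self.f12_, self.p12_, self.f23_, self.p23_ = f12, p12, f23, p23
        return self

    def predict(self, X):
        """Model labels for new profiles (selection is per-voxel, so this
        simply runs the same sequential procedure on ``X``)."""

        check_is_fitted(self, "labels_")
        X = self._check(X)
        fits = fit_models_matrix(X, self.aif)
        labels, *_ = _sequential_labels(
            fits["ssr1"], fits["ssr2"], fits["ssr3"], fits["cc"], fits["n_fit"], self.alpha
        )
        return labels

    # -- selected-model parameter views -------------------------------
    def selected_params(self) -> pd.DataFrame:
        """Per-voxel table of the selected model's estimates.

        ``vp`` follows the selected model; ``ktrans`` is 0 for label 1;
        ``ve`` is defined (Ktrans3/kep3) only for label 3.
        """

        check_is_fitted(self, "labels_")
        f, lab = self.fits_, self.labels_
        vp = np.select([lab == 1, lab == 2, lab == 3], [f["vp1"], f["vp2"], f["vp3"]])
        kt = np.select([lab == 2, lab == 3], [f["kt2"], f["kt3"]], default=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ve3 = np.where(f["kep3"] > 0, f["kt3"] / f["kep3"], 0.0)
        ve = np.where(lab == 3, ve3, 0.0)
        return pd.DataFrame(
            {
                "label": lab, "vp": vp, "ktrans": kt, "ve": ve,
                "f12": self.f12_, "p12": self.p12_, "f23": self.f23_, "p23": self.p23_,
                "vp1": f["vp1"], "vp2": f["vp2"], "kt2": f["kt2"],
                "vp3": f["vp3"], "kt3": f["kt3"], "kep3": f["kep3"],
                "ssr1": f["ssr1"], "ssr2": f["ssr2"], "ssr3": f["ssr3"],
            }
        )


def select_model(profile: ConcentrationProfile, aif: AIF, alpha: float = 0.05) -> NMSResult:
    """Sequential nested model selection for a single voxel."""

    sel = NestedModelSelector(aif=aif, alpha=alpha).fit(profile.c[None, :])
    f = sel.fits_
    n_fit = f["n_fit"]
    fits = {
        1: ModelFit(1, PKParams(vp=float(f["vp1"][0])), float(f["ssr1"][0]), n_fit),
        2: ModelFit(2, PKParams(vp=float(f["vp2"][0]), ktrans=float(f["kt2"][0])), float(f["ssr2"][0]), n_fit),
        3: ModelFit(
            3,
            PKParams(vp=float(f["vp3"][0]), ktrans=float(f["kt3"][0]), kep=float(f["kep3"][0])),
            float(f["ssr3"][0]),
            n_fit,
        ),
    }
    return NMSResult(
        label=int(sel.labels_[0]),
        f12=float(sel.f12_[0]), p12=float(sel.p12_[0]),
        f23=float(sel.f23_[0]), p23=float(sel.p23_[0]),
        fits=fits,
    )


def run_nms_volume(volume4d: np.ndarray, mask: np.ndarray, aif: AIF, alpha: float = 0.05) -> dict:
    """NMS over a 4-D volume: label map plus vp / Ktrans / ve parameter maps.

    Returns a dict with 3-D maps (0 outside the mask; ``ve`` only where
    label = 3), the fitted :class:`NestedModelSelector` and the per-voxel
    table (with flat voxel indices of the masked voxels).
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
    sel = NestedModelSelector(aif=aif, alpha=alpha).fit(X)
    table = sel.selected_params()
    table.insert(0, "voxel", idx)

    shape3 = volume4d.shape[:3]
    out = {}
    label_map = np.zeros(shape3, dtype=np.int8).ravel()
    label_map[idx] = sel.labels_
    out["label"] = label_map.reshape(shape3)
    for name in ("vp", "ktrans", "ve"):
        m = np.zeros(shape3, dtype=float).ravel()
        m[idx] = table[name].to_numpy()
        out[name] = m.reshape(shape3)
    out["selector"] = sel
    out["table"] = table
    return out
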