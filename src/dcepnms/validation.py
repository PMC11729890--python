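"""Quantitative comparison of probabilistic vs. conventional model selection.

Provides the Dice similarity coefficient, the mean percent difference
(MPD = 100·(PNMS − NMS)/NMS), and a subject-level k-fold nested
cross-validation: the outer loop holds out a test fold of subjects; the
inner loop trains the SOM-based probability model on training subjects
only; test-fold profiles are scored by that model.  Parameter summaries
follow the conventional-region fusion convention: vp over the fused model
1+2+3 regions, Ktrans over 2+3, ve over region 3 — with the conventional
and probabilistic estimates both averaged over the same (NMS-defined)
regions so they are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import AIF
from .nms import NestedModelSelector
from .pnms import PNMSModel, averaged_ktrans, averaged_ve, averaged_vp
from .som import normalize_profiles

__all__ = ["dice", "mpd", "CVPlan", "CVResult", "label_profiles", "pnms_masks_flat", "nested_cv"]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Two empty masks are defined to agree perfectly (1.0).
    """

    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)


def mpd(nms_value: float, pnms_value: float) -> float:
    """Mean percent difference 100·(PNMS − NMS)/NMS of two estimates."""

    if nms_value == 0:
        raise ZeroDivisionError("MPD undefined for a zero baseline value")
    return 100.0 * (pnms_value - nms_value) / nms_value


@dataclass(frozen=True)
class CVPlan:
    """Subject-level k-fold plan: disjoint test folds (every subject tested
    exactly once) with the training cohort subsampled to ``train_fraction``
    of the subjects from the remaining pool."""

    k: int = 10
    train_fraction: float = 0.66
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def label_profiles(profiles: np.ndarray, aif: AIF, alpha: float = 0.05):
    """Conventional NMS labels + per-profile fit table for a flat profile set."""

    sel = NestedModelSelector(aif=aif, alpha=alpha).fit(profiles)
    return sel.labels_, sel.selected_params()


def pnms_masks_flat(P: np.ndarray, threshold: float = 0.5, mask_model1: bool = True) -> dict[int, np.ndarray]:
    """Thresholded model masks over a flat voxel set (model-1 mask-out first)."""

    s = P.sum(axis=1, keepdims=True)
    Pn = np.divide(P, s, out=np.zeros_like(P), where=s > 0)
    m1 = Pn[:, 0] >= threshold
    m2 = Pn[:, 1] >= threshold
    m3 = Pn[:, 2] >= threshold
    if mask_model1:
        m2 &= ~m1
        m3 &= ~m1
    return {1: m1, 2: m2, 3: m3}


def _percentile_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int = 2000, level: float = 0.95):
    """Percentile bootstrap CI of the mean over folds."""

    values = np.asarray(values, dtype=float)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


@dataclass
class CVResult:
    """Per-fold metrics and across-fold summaries of the nested CV."""

    folds: pd.DataFrame
    summary: dict


def _region_means(labels, fit_table, P):
    """NMS and PNMS parameter means over the NMS-region fusions."""

    vp_sel = fit_table["vp"].to_numpy()
    kt_sel = fit_table["ktrans"].to_numpy()
    ve_sel = fit_table["ve"].to_numpy()
    kep3 = fit_table["kep3"].to_numpy()
    leaky = np.isin(labels, (2, 3))
    m3 = labels == 3

    vp_avg = averaged_vp(P, fit_table["vp1"].to_numpy(), fit_table["vp2"].to_numpy(), fit_table["vp3"].to_numpy())
    kt_avg = averaged_ktrans(P, fit_table["kt2"].to_numpy(), fit_table["kt3"].to_numpy())
    ve_avg = averaged_ve(kt_avg, kep3)

    out = {
        "vp_nms": float(vp_sel.mean()),
        "vp_pnms": float(np.nanmean(vp_avg)),
        "ktrans_nms": float(kt_sel[leaky].mean()) if leaky.any() else np.nan,
        "ktrans_pnms": float(np.nanmean(kt_avg[leaky])) if leaky.any() else np.nan,
        "ve_nms": float(ve_sel[m3].mean()) if m3.any() else np.nan,
        "ve_pnms": float(np.nanmean(ve_avg[m3 & (kep3 > 0)])) if m3.any() else np.nan,
    }
    return out


def nested_cv(
    profiles: np.ndarray,
    subjects: np.ndarray,
    aif: AIF,
    plan: CVPlan = CVPlan(),
    som_params: dict | None = None,
    alpha: float = 0.05,
    threshold: float = 0.5,
    n_boot: int = 2000,
) -> CVResult:
    """Subject-level nested cross-validation of the PNMS pipeline.

    Profiles are first labeled by the conventional NMS (the source of truth
    for SOM supervision).  For each outer fold, a fresh probability model is
    trained on the training subjects only and scored on the held-out
    subjects: per-fold Dice coefficients for the model-2 and model-3
    regions (after model-1 mask-out at ``threshold``) and per-fold
    parameter means for both techniques.  Summaries include across-fold
    means, percentile-bootstrap CIs, and MPDs computed both as the mean of
    per-fold MPDs and as the MPD of the fold-averaged parameters.
    """

    profiles = np.asarray(profiles, dtype=float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < plan.k:
        raise ValueError(f"need at least k={plan.k} subjects, got {uniq.size}")
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(uniq)  # random permutation sampling
    folds_subj = np.array_split(order, plan.k)

    labels, fit_table = label_profiles(profiles, aif, alpha)
    feats = normalize_profiles(profiles, aif.grid.n_baseline)
    n_train_subj = max(1, int(round(plan.train_fraction * uniq.size)))

    rows = []
    for i, test_subj in enumerate(folds_subj):
        pool = np.array([s for s in order if s not in set(test_subj)])
        take = min(n_train_subj, pool.size)
        train_subj = rng.choice(pool, size=take, replace=False)
        tr = np.isin(subjects, train_subj)
        te = np.isin(subjects, test_subj)
        assert not np.any(tr & te)
        model = PNMSModel(
            **(som_params or {}), random_state=int(rng.integers(2**31 - 1))
        ).fit(feats[tr], labels[tr])
        P = model.predict_proba(feats[te])
        masks = pnms_masks_flat(P, threshold=threshold)
        lab_te = labels[te]
        not_m1 = ~masks[1]
        row = {
            "fold": i,
            "n_test": int(te.sum()),
            "n_train": int(tr.sum()),
            "dsc2": dice((lab_te == 2) & not_m1, masks[2]),
            "dsc3": dice((lab_te == 3) & not_m1, masks[3]),
        }
        row.update(_region_means(lab_te, fit_table[te].reset_index(drop=True), P))
        rows.append(row)
    folds = pd.DataFrame(rows)

    boot_rng = np.random.default_rng(plan.seed + 1)
    summary: dict = {}
    for col in ("dsc2", "dsc3", "vp_nms", "vp_pnms", "ktrans_nms", "ktrans_pnms", "ve_nms", "ve_pnms"):
        vals = folds[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        lo, hi = _percentile_ci(vals, boot_rng, n_boot=n_boot)
        summary[col] = {"mean": float(vals.mean()), "ci": (lo, hi), "ci_width": hi - lo}
    for p in ("vp", "ktrans", "ve"):
        nms_v = folds[f"{p}_nms"].to_numpy(dtype=float)
        pnms_v = folds[f"{p}_pnms"].to_numpy(dtype=float)
        ok = np.isfinite(nms_v) & np.isfinite(pnms_v) & (nms_v != 0)
        summary[f"mpd_{p}"] = {
            "mean_of_fold_mpds": float(np.mean(100.0 * (pnms_v[ok] - nms_v[ok]) / nms_v[ok])),
            "mpd_of_fold_means": mpd(float(nms_v[ok].mean()), float(pnms_v[ok].mean())),
        }
    return CVResult(folds=folds, summary=summary)
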