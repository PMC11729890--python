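"""End-to-end evaluation experiments on fully synthetic data.

Each function regenerates its inputs from a seed, runs the pipeline and
returns measured quantities: F-test calibration, forward-model
discretization error against a fine-grid oracle, noiseless and noisy
parameter recovery, nesting and BMU invariants, SOM determinism,
model-averaging identities, PNMS-vs-NMS region agreement (Dice), and
cohort-level nested cross-validation spread.  Problem sizes default to
what a single CPU handles in minutes; they are arguments, not constants.
"""

from __future__ import annotations

import numpy as np

from .aif import AIFSpec, aif_curve, synth_aif
from .kinetics import TimeGrid, AIF, exp_conv, fit_models_matrix, model2_forward, model3_forward
from .nms import NestedModelSelector, run_nms_volume
from .phantom import (
    PhantomSpec,
    default_grid,
    generate_cohort,
    generate_phantom,
    generate_profile_set,
    paper_like_counts,
)
from .pnms import PNMSModel, averaged_ktrans, averaged_ve, averaged_vp
from .som import KohonenSOM, normalize_profiles
from .validation import CVPlan, dice, label_profiles, nested_cv, pnms_masks_flat

__all__ = [
    "ftest_type1_rate",
    "forward_discretization_error",
    "noiseless_identifiability",
    "model3_recovery",
    "nesting_violations",
    "som_determinism",
    "bmu_oracle_mismatches",
    "averaging_identities",
    "end_to_end_dsc",
    "cohort_cv_spread",
]


def ftest_type1_rate(n_voxels: int = 2000, noise_sigma: float = 0.02,
                     alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of true model-1 voxels promoted to model >= 2 at ``alpha``."""

    ps = generate_profile_set(n_voxels, 0, 0, noise_sigma=noise_sigma, seed=seed)
    sel = NestedModelSelector(aif=ps.aif, alpha=alpha).fit(ps.profiles)
    rate = float(np.mean(sel.labels_ >= 2))
    return {"rate": rate, "n": n_voxels}


def _fine_grid_conv(spec: AIFSpec, t_coarse: np.ndarray, kep: float, refine: int) -> np.ndarray:
    """Oracle: trapezoid convolution of the analytic AIF on a refine×-finer grid."""

    t_fine = np.linspace(t_coarse[0], t_coarse[-1], (t_coarse.size - 1) * refine + 1)
    c_fine = aif_curve(spec, t_fine)
    out = np.empty(t_coarse.size)
    for i, ti in enumerate(t_coarse):
        m = t_fine <= ti + 1e-12
        tt = t_fine[m]
        out[i] = np.trapezoid(c_fine[m] * np.exp(-kep * (ti - tt)), tt) if tt.size > 1 else 0.0
    return out


def forward_discretization_error(refine: int = 100, grid: TimeGrid | None = None) -> dict:
    """Max relative L2 error of the acquisition-grid forward curves versus a
    fine-grid numerical oracle, over a 3×3×3 kinetic parameter grid."""

    grid = grid or default_grid()
    spec = AIFSpec(t_inj=15 * float(grid.t[1] - grid.t[0]))
    aif = synth_aif(spec, grid)
    t = grid.t
    q_oracle = _fine_grid_conv(spec, t, 0.0, refine)
    vps = np.array([0.005, 0.02, 0.04])
    kts = np.array([0.01, 0.1, 0.3])
    keps = np.array([0.1, 0.5, 3.0])
    worst = 0.0
    for kep in keps:
        conv_oracle = _fine_grid_conv(spec, t, float(kep), refine)
        conv_ours = exp_conv(aif.c, t, float(kep))
        for vp in vps:
            for kt in kts:
                ours3 = model3_forward(vp, kt, float(kep), aif).c
                oracle3 = vp * aif.c + kt * conv_oracle
                worst = max(worst, _rel_l2(ours3, oracle3))
                ours2 = model2_forward(vp, kt, aif).c
                oracle2 = vp * aif.c + kt * q_oracle
                worst = max(worst, _rel_l2(ours2, oracle2))
        del conv_ours
    return {"max_rel_l2": worst, "n": 27}


def _rel_l2(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def noiseless_identifiability(seed: int = 0, shape=(32, 32, 1)) -> dict:
    """On a σ=0 phantom: NMS label accuracy and worst selected-parameter error."""

    ph = generate_phantom(PhantomSpec(shape=shape, noise_sigma=0.0, seed=seed))
    res = run_nms_volume(ph.volume, ph.mask, ph.aif)
    m = ph.mask
    acc = float(np.mean(res["label"][m] == ph.labels[m]))
    errs = [np.abs(res["vp"][m] - ph.vp[m]) / ph.vp[m]]
    leaky = m & (ph.labels >= 2)
    errs.append(np.abs(res["ktrans"][leaky] - ph.ktrans[leaky]) / ph.ktrans[leaky])
    m3 = m & (ph.labels == 3)
    errs.append(np.abs(res["ve"][m3] - ph.ve[m3]) / ph.ve[m3])
    max_err = float(max(np.max(e) for e in errs))
    return {"label_accuracy": acc, "max_param_rel_err": max_err, "n": int(m.sum())}


def model3_recovery(n: int = 500, noise_sigma: float = 0.02, seed: int = 0) -> dict:
    """Median relative recovery error of vp, Ktrans, ve on noisy model-3 voxels."""

    ps = generate_profile_set(0, 0, n, noise_sigma=noise_sigma, seed=seed)
    fits = fit_models_matrix(ps.profiles, ps.aif)
    truth = ps.params
    rel = lambda est, tr: np.median(np.abs(est - tr) / tr)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve_est = np.where(fits["kep3"] > 0, fits["kt3"] / fits["kep3"], np.nan)
    return {
        "vp_median_rel_err": float(rel(fits["vp3"], truth["vp"].to_numpy())),
        "ktrans_median_rel_err": float(rel(fits["kt3"], truth["ktrans"].to_numpy())),
        "ve_median_rel_err": float(np.nanmedian(np.abs(ve_est - truth["ve"].to_numpy()) / truth["ve"].to_numpy())),
        "n": n,
    }


def nesting_violations(n: int = 2000, noise_sigma: float = 0.03, seed: int = 0,
                       rtol: float = 1e-9) -> dict:
    """Count of fits violating SSR1 >= SSR2 >= SSR3 beyond ``rtol``."""

    n1, n2, n3 = paper_like_counts(n)
    ps = generate_profile_set(n1, n2, n3, noise_sigma=noise_sigma, seed=seed)
    f = fit_models_matrix(ps.profiles, ps.aif)
    v = int(np.sum(f["ssr2"] > f["ssr1"] * (1 + rtol) + 1e-300))
    v += int(np.sum(f["ssr3"] > f["ssr2"] * (1 + rtol) + 1e-300))
    return {"violations": v, "n": n}


def _training_set(n: int, noise_sigma: float, seed: int):
    n1, n2, n3 = paper_like_counts(n)
    ps = generate_profile_set(n1, n2, n3, noise_sigma=noise_sigma, seed=seed)
    labels, _ = label_profiles(ps.profiles, ps.aif)
    feats = normalize_profiles(ps.profiles, ps.grid.n_baseline)
    return ps, feats, labels


def som_determinism(n: int = 3000, noise_sigma: float = 0.02, seed: int = 0) -> dict:
    """Bitwise repeatability of SOM training and per-neuron probability sums."""

    _, feats, labels = _training_set(n, noise_sigma, seed)
    m1 = PNMSModel(random_state=seed).fit(feats, labels)
    m2 = PNMSModel(random_state=seed).fit(feats, labels)
    wdiff = float(np.max(np.abs(m1.som_.weights_ - m2.som_.weights_)))
    nonempty = ~m1.neuron_probabilities_.empty_mask
    sums = m1.neuron_probabilities_.P.sum(axis=0)[nonempty]
    return {"weight_max_abs_diff": wdiff,
            "prob_sum_max_dev": float(np.max(np.abs(sums - 1.0))),
            "n": n}


def bmu_oracle_mismatches(n_features: int = 100, seed: int = 0) -> dict:
    """Exhaustive distance scan versus the BMU routine on random features."""

    rng = np.random.default_rng(seed)
    X_train = rng.standard_normal((500, 40))
    som = KohonenSOM(max_epochs=60, cover_steps=30, random_state=seed).fit(X_train)
    X = rng.standard_normal((n_features, 40))
    pred = som.predict(X)
    brute = np.array([
        int(np.argmin([np.linalg.norm(x - w) for w in som.weights_])) for x in X
    ])
    return {"mismatches": int(np.sum(pred != brute)), "n": n_features}


def averaging_identities(seed: int = 0, n: int = 1500, noise_sigma: float = 0.02) -> dict:
    """One-hot reduction to NMS and invariance under global P rescaling."""

    n1, n2, n3 = paper_like_counts(n)
    ps = generate_profile_set(n1, n2, n3, noise_sigma=noise_sigma, seed=seed)
    labels, table = label_profiles(ps.profiles, ps.aif)
    onehot = np.eye(3)[labels - 1]
    vp1, vp2, vp3 = (table[c].to_numpy() for c in ("vp1", "vp2", "vp3"))
    kt2, kt3, kep3 = (table[c].to_numpy() for c in ("kt2", "kt3", "kep3"))
    vp_a = averaged_vp(onehot, vp1, vp2, vp3)
    kt_a = averaged_ktrans(onehot, kt2, kt3)
    ve_a = averaged_ve(kt_a, kep3)
    m3 = (labels == 3) & (kep3 > 0)
    reduction = max(
        float(np.max(np.abs(vp_a - table["vp"].to_numpy()))),
        float(np.max(np.abs(kt_a - table["ktrans"].to_numpy()))),
        float(np.max(np.abs(ve_a[m3] - table["ve"].to_numpy()[m3]))) if m3.any() else 0.0,
    )
    rng = np.random.default_rng(seed + 1)
    P = rng.dirichlet(np.ones(3), size=n)
    scale = 7.3
    diffs = []
    for fn, args in (
        (averaged_vp, (vp1, vp2, vp3)),
        (averaged_ktrans, (kt2, kt3)),
    ):
        a = np.asarray(fn(P, *args))
        b = np.asarray(fn(P * scale, *args))
        denom = np.maximum(np.abs(a), 1e-30)
        diffs.append(np.max(np.abs(a - b) / denom))
    ve_ref = averaged_ve(averaged_ktrans(P, kt2, kt3), kep3)
    ve_scaled = averaged_ve(averaged_ktrans(P * scale, kt2, kt3), kep3)
    ok = np.isfinite(ve_ref)
    diffs.append(np.max(np.abs(ve_ref[ok] - ve_scaled[ok]) / np.maximum(np.abs(ve_ref[ok]), 1e-30)))
    return {"onehot_max_abs_diff": reduction,
            "rescale_max_rel_diff": float(max(diffs)),
            "n": n}


def end_to_end_dsc(noise_sigma: float, n_profiles: int = 20000, seed: int = 0,
                   threshold: float = 0.5) -> dict:
    """Train the probability model on NMS-labeled noisy profiles and measure
    the Dice agreement of PNMS-thresholded regions with the NMS labels."""

    _, feats, labels = _training_set(n_profiles, noise_sigma, seed)
    model = PNMSModel(random_state=seed).fit(feats, labels)
    P = model.predict_proba(feats)
    masks = pnms_masks_flat(P, threshold=threshold)
    not_m1 = ~masks[1]
    return {
        "dsc_model2": dice((labels == 2) & not_m1, masks[2]),
        "dsc_model3": dice((labels == 3) & not_m1, masks[3]),
        "n": n_profiles,
    }


def cohort_cv_spread(seed: int = 0, n_subjects: int = 10,
                     profiles_per_subject: int = 400, k: int = 10) -> dict:
    """Nested CV on a synthetic cohort: fold-to-fold CI widths and MPDs."""

    cohort = generate_cohort(n_subjects=n_subjects,
                             profiles_per_subject=profiles_per_subject, seed=seed)
    res = nested_cv(cohort.profiles, cohort.subjects, cohort.aif,
                    CVPlan(k=k, seed=seed))
    s = res.summary
    narrower = sum(
        s[f"{p}_pnms"]["ci_width"] <= s[f"{p}_nms"]["ci_width"]
        for p in ("vp", "ktrans", "ve")
    )
    return {
        "n_params_pnms_ci_narrower": int(narrower),
        "dsc2_mean": s["dsc2"]["mean"],
        "dsc3_mean": s["dsc3"]["mean"],
        "mpd_vp": s["mpd_vp"]["mpd_of_fold_means"],
        "mpd_ktrans": s["mpd_ktrans"]["mpd_of_fold_means"],
        "mpd_ve": s["mpd_ve"]["mpd_of_fold_means"],
        "vp_nms_mean": s["vp_nms"]["mean"],
        "vp_pnms_mean": s["vp_pnms"]["mean"],
        "ktrans_nms_mean": s["ktrans_nms"]["mean"],
        "ktrans_pnms_mean": s["ktrans_pnms"]["mean"],
        "ve_nms_mean": s["ve_nms"]["mean"],
        "ve_pnms_mean": s["ve_pnms"]["mean"],
        "n": n_subjects * profiles_per_subject,
    }
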