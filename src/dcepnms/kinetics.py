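"""Nested tracer-kinetic forward models and voxel-wise least-squares fitting.

Three physiologically nested compartmental models describe a tissue
contrast-concentration curve C(t) (ΔR1-proportional units) driven by an
arterial input function (AIF):

* Model 1 (normal, non-leaky vasculature)::

      C(t) = vp · C_aif(t)

* Model 2 (leakage without measurable back-flux; Patlak)::

      C(t) = vp · C_aif(t) + Ktrans · ∫0..t C_aif(λ) dλ

* Model 3 (leakage with back-flux; extended Tofts/Patlak)::

      C(t) = vp · C_aif(t) + Ktrans · ∫0..t C_aif(λ) e^{−kep (t−λ)} dλ

with ``vp`` the fractional plasma volume (dimensionless), ``Ktrans`` the
forward volumetric transfer constant (1/min), ``kep`` the reverse transfer
constant (1/min) and ``ve = Ktrans / kep`` the interstitial volume fraction.
Time is in minutes throughout; no hematocrit correction is applied.

Models 1 and 2 are linear in their parameters and solved by linear least
squares.  Model 3 is solved by separable least squares: an outer search over
``kep`` (log-spaced coarse grid, a zoom round, then parabolic refinement)
with an inner linear solve for ``(vp, Ktrans)``.  The leading pre-injection
baseline samples are excluded from all residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "TimeGrid",
    "AIF",
    "ConcentrationProfile",
    "PKParams",
    "ModelFit",
    "SingularFitError",
    "exp_conv",
    "model1_forward",
    "model2_forward",
    "model3_forward",
    "fit_model",
    "fit_models_matrix",
]

KEP_MIN = 1e-3
KEP_MAX = 20.0
KEP_GRID_POINTS = 64
_PERFECT_FIT_RTOL = 1e-12  # SSR below this fraction of signal energy counts as perfect


class SingularFitError(ValueError):
    """Raised when the least-squares design is degenerate (e.g. all-zero AIF)."""


@dataclass(frozen=True)
class TimeGrid:
    """Shared sampling times (minutes) for AIF and tissue curves.

    ``n_baseline`` leading samples are treated as the pre-injection/
    equilibration window and excluded from fitting (the integrals in the
    forward models still run from t[0]).
    """

    t: np.ndarray
    n_baseline: int = 20

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid must be a 1-D array with >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not (0 <= self.n_baseline < t.size):
            raise ValueError("n_baseline must satisfy 0 <= n_baseline < len(t)")
        object.__setattr__(self, "t", t)

    @property
    def n_t(self) -> int:
        return self.t.size

    @property
    def n_fit(self) -> int:
        return self.t.size - self.n_baseline

    @property
    def fit_slice(self) -> slice:
        return slice(self.n_baseline, None)

    def matches(self, other: "TimeGrid") -> bool:
        return (
            self.n_baseline == other.n_baseline
            and self.t.size == other.t.size
            and np.allclose(self.t, other.t)
        )


def _check_series(grid: TimeGrid, c: np.ndarray, name: str) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.shape != grid.t.shape:
        raise ValueError(f"{name} length {c.shape} does not match grid {grid.t.shape}")
    if not np.all(np.isfinite(c)):
        raise ValueError(f"{name} contains non-finite values")
    return c


@dataclass(frozen=True)
class AIF:
    """Arterial input function: plasma contrast concentration on a time grid."""

    grid: TimeGrid
    c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", _check_series(self.grid, self.c, "AIF"))

    @property
    def peak(self) -> float:
        return float(np.max(self.c))

    def scaled(self, s: float) -> "AIF":
        return AIF(self.grid, self.c * float(s))


@dataclass(frozen=True)
class ConcentrationProfile:
    """One voxel's tissue ΔR1(t) trace on a time grid."""

    grid: TimeGrid
    c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", _check_series(self.grid, self.c, "profile"))


@dataclass
class PKParams:
    """Pharmacokinetic parameters of a fitted nested model.

    Fields not estimated by the model are ``None``.  Estimates outside their
    physical range (fractions in [0, 1], rates >= 0) are retained — altering
    them would distort the F-test null — and reported via ``flags``.
    """

    vp: Optional[float] = None
    ktrans: Optional[float] = None
    kep: Optional[float] = None
    ve: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ve is None and self.ktrans is not None and self.kep is not None:
            if self.kep > 0:
                self.ve = self.ktrans / self.kep
        for name, lo, hi in (("vp", 0.0, 1.0), ("ve", 0.0, 1.0)):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                self.flags.append(f"{name}_out_of_range")
        for name in ("ktrans", "kep"):
            v = getattr(self, name)
            if v is not None and v < 0:
                self.flags.append(f"{name}_negative")


@dataclass
class ModelFit:
    """Result of fitting one nested model to one voxel."""

    model_id: int
    params: PKParams
    ssr: float
    n_fit: int

    @property
    def n_params(self) -> int:
        return self.model_id

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if self.ssr < 0:
            raise ValueError("ssr must be non-negative")


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def exp_conv(c: np.ndarray, t: np.ndarray, kep: float) -> np.ndarray:
    """Causal exponential convolution ``I(t_i) = ∫0..t_i c(λ) e^{−kep (t_i−λ)} dλ``.

    Exact for a piecewise-linear ``c`` between samples (stable for large
    ``kep·dt``); reduces to the cumulative trapezoid for ``kep -> 0``.
    """

    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    if kep < 0:
        raise ValueError("kep must be >= 0")
    dt = np.diff(t)
    if kep * dt.max() < 1e-8:
        return cumulative_trapezoid(c, t, initial=0.0)
    if np.allclose(dt, dt[0], rtol=1e-8, atol=0.0):
        h = dt[0]
        E = np.exp(-kep * h)
        g = (1.0 - E) / kep
        beta = (h - g) / (kep * h)
        alpha = g - beta
        y = lfilter([beta, alpha], [1.0, -E], c)
        # enforce I(t0) = 0 (lfilter starts from y0 = beta*c0)
        y -= (beta * c[0]) * E ** np.arange(c.size)
        y[0] = 0.0
        return y
    out = np.zeros_like(c)
    for i in range(1, c.size):
        h = dt[i - 1]
        E = np.exp(-kep * h)
        g = (1.0 - E) / kep
        beta = (h - g) / (kep * h)
        alpha = g - beta
        out[i] = E * out[i - 1] + alpha * c[i - 1] + beta * c[i]
    return out


def _exp_conv_many(c: np.ndarray, t: np.ndarray, keps: np.ndarray) -> np.ndarray:
    """Exponential convolution of one signal for many kep values, shape (n_kep, n_t)."""

    keps = np.asarray(keps, dtype=float)
    dt = np.diff(t)
    h = dt[0]
    if not np.allclose(dt, h, rtol=1e-8, atol=0.0):
        return np.stack([exp_conv(c, t, k) for k in keps])
    k = np.where(keps > 0, keps, 1.0)
    E = np.exp(-keps * h)
    g = np.where(keps * h < 1e-8, h - keps * h * h / 2.0, (1.0 - E) / k)
    beta = np.where(keps * h < 1e-8, h / 2.0, (h - g) / (k * h))
    alpha = g - beta
    out = np.zeros((keps.size, c.size))
    for i in range(1, c.size):
        out[:, i] = E * out[:, i - 1] + alpha * c[i - 1] + beta * c[i]
    return out


def model1_forward(vp: float, aif: AIF) -> ConcentrationProfile:
    """Non-leaky vasculature: ``C(t) = vp · C_aif(t)``."""

    return ConcentrationProfile(aif.grid, vp * aif.c)


def model2_forward(vp: float, ktrans: float, aif: AIF) -> ConcentrationProfile:
    """Patlak model: plasma term plus unidirectional leakage integral."""

    integral = cumulative_trapezoid(aif.c, aif.grid.t, initial=0.0)
    return ConcentrationProfile(aif.grid, vp * aif.c + ktrans * integral)


def model3_forward(vp: float, ktrans: float, kep: float, aif: AIF) -> ConcentrationProfile:
    """Extended model with back-flux: exponentially weighted leakage integral."""

    conv = exp_conv(aif.c, aif.grid.t, kep)
    return ConcentrationProfile(aif.grid, vp * aif.c + ktrans * conv)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _solve_2col(aa, ab, bb, ca, cb):
    """Least-squares solve for design [a, b] against rows of C.

    All arguments broadcast; returns (theta_a, theta_b, valid).
    """

    det = aa * bb - ab * ab
    scale = np.maximum(aa * bb, 1e-300)
    valid = det > 1e-14 * scale
    det_safe = np.where(valid, det, 1.0)
    th_a = (bb * ca - ab * cb) / det_safe
    th_b = (aa * cb - ab * ca) / det_safe
    return th_a, th_b, valid


def fit_models_matrix(C: np.ndarray, aif: AIF, n_golden: int = 24) -> dict:
    """Fit all three nested models to every row of ``C`` (n_voxels, n_t).

    Returns a dict of per-voxel arrays: ``vp1, ssr1, vp2, kt2, ssr2, vp3,
    kt3, kep3, ssr3, cc, n_fit``.  ``cc`` is the signal energy over the fit
    window (used downstream for perfect-fit detection).
    """

    C = np.atleast_2d(np.asarray(C, dtype=float))
    grid = aif.grid
    if C.shape[1] != grid.n_t:
        raise ValueError("profile length does not match the AIF time grid")
    fs = grid.fit_slice
    t = grid.t
    a_full = aif.c
    a = a_full[fs]
    aa = float(a @ a)
    if aa <= 1e-300:
        raise SingularFitError("AIF is (numerically) zero over the fit window")

    Cf = C[:, fs]
    cc = np.einsum("ij,ij->i", Cf, Cf)
    ca = Cf @ a

    # Model 1: single column
    vp1 = ca / aa
    ssr1 = np.maximum(cc - vp1 * ca, 0.0)

    # Model 2: columns [a, cumulative trapezoid of the AIF]
    q = cumulative_trapezoid(a_full, t, initial=0.0)[fs]
    qq = float(q @ q)
    aq = float(a @ q)
    cq = Cf @ q
    vp2, kt2, ok2 = _solve_2col(aa, aq, qq, ca, cq)
    ssr2 = np.maximum(cc - (vp2 * ca + kt2 * cq), 0.0)
    if not np.all(ok2):
        # degenerate second column (e.g. constant-zero tail): fall back to model 1
        vp2 = np.where(ok2, vp2, vp1)
        kt2 = np.where(ok2, kt2, 0.0)
        ssr2 = np.where(ok2, ssr2, ssr1)
    ssr2 = np.minimum(ssr2, ssr1)

    # Model 3: separable LS over kep.  kep = 0 (model-2 design) is always a
    # candidate so that SSR3 <= SSR2 by construction.
    ratio = (KEP_MAX / KEP_MIN) ** (1.0 / (KEP_GRID_POINTS - 1))
    cands = np.concatenate([[0.0], np.logspace(np.log10(KEP_MIN), np.log10(KEP_MAX), KEP_GRID_POINTS)])

    def eval_keps(keps: np.ndarray, rows: np.ndarray | None = None):
        """SSR and params for each kep in ``keps`` on the selected voxel rows."""
        cols = _exp_conv_many(a_full, t, keps)[:, fs]
        Cf_r = Cf if rows is None else Cf[rows]
        ca_r = ca if rows is None else ca[rows]
        cc_r = cc if rows is None else cc[rows]
        bb = np.einsum("kj,kj->k", cols, cols)
        ab = cols @ a
        cb = Cf_r @ cols.T  # (n_rows, n_kep)
        th_a, th_b, ok = _solve_2col(aa, ab[None, :], bb[None, :], ca_r[:, None], cb)
        ssr = cc_r[:, None] - (th_a * ca_r[:, None] + th_b * cb)
        ssr = np.where(ok, np.maximum(ssr, 0.0), np.inf)
        return ssr, th_a, th_b

    ssr_c, th_a_c, th_b_c = eval_keps(cands)
    best = np.argmin(ssr_c, axis=1)
    n_vox = C.shape[0]
    rows_all = np.arange(n_vox)
    kep3 = cands[best]
    ssr3 = ssr_c[rows_all, best]
    vp3 = th_a_c[rows_all, best]
    kt3 = th_b_c[rows_all, best]

    log_step = np.log(ratio)
    for kc in np.unique(kep3):
        if kc <= 0:
            continue
        rows = np.where(kep3 == kc)[0]
        ladder = kc * np.exp(np.linspace(-log_step, log_step, 17))
        np.clip(ladder, 0.0, KEP_MAX, out=ladder)
        ssr_l, th_a_l, th_b_l = eval_keps(ladder, rows)
        j = np.argmin(ssr_l, axis=1)
        r = np.arange(rows.size)
        improve = ssr_l[r, j] < ssr3[rows]
        upd = rows[improve]
        kep3[upd] = ladder[j[improve]]
        ssr3[upd] = ssr_l[r, j][improve]
        vp3[upd] = th_a_l[r, j][improve]
        kt3[upd] = th_b_l[r, j][improve]

    # golden-section polish in log-kep, vectorized across voxels
    refine = np.where(kep3 > 0)[0]
    if refine.size:
        step = 2.0 * log_step / 16.0  # ladder spacing above
        xl = np.log(kep3[refine]) - step
        xh = np.log(kep3[refine]) + step
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        x1 = xh - gr * (xh - xl)
        x2 = xl + gr * (xh - xl)

        def f(x):
            s, _, _ = _eval_per_voxel(Cf, ca, cc, a, a_full, t, fs, aa, np.exp(x), refine)
            return s

        f1, f2 = f(x1), f(x2)
        for _ in range(n_golden):
            left = f1 < f2
            xh = np.where(left, x2, xh)
            xl = np.where(left, xl, x1)
            x2n = np.where(left, x1, xl + gr * (xh - xl))
            x1n = np.where(left, xh - gr * (xh - xl), x2)
            fx = f(np.where(left, x1n, x2n))
            f2, f1 = np.where(left, f1, fx), np.where(left, fx, f2)
            x1, x2 = x1n, x2n
        xb = np.where(f1 < f2, x1, x2)
        kep_v = np.clip(np.exp(xb), 0.0, KEP_MAX)
        ssr_v, th_a_v, th_b_v = _eval_per_voxel(Cf, ca, cc, a, a_full, t, fs, aa, kep_v, refine)
        better = ssr_v < ssr3[refine]
        upd = refine[better]
        kep3[upd] = kep_v[better]
        ssr3[upd] = ssr_v[better]
        vp3[upd] = th_a_v[better]
        kt3[upd] = th_b_v[better]

    ssr3 = np.minimum(ssr3, ssr2)
    return {
        "vp1": vp1, "ssr1": ssr1,
        "vp2": vp2, "kt2": kt2, "ssr2": ssr2,
        "vp3": vp3, "kt3": kt3, "kep3": kep3, "ssr3": ssr3,
        "cc": cc, "n_fit": grid.n_fit,
    }


def _eval_per_voxel(Cf, ca, cc, a, a_full, t, fs, aa, keps, rows):
    """Linear solve at one distinct kep per voxel (vectorized over voxels)."""

    cols = _exp_conv_many(a_full, t, keps)[:, fs]  # (n_rows, n_fit)
    Cr = Cf[rows]
    bb = np.einsum("ij,ij->i", cols, cols)
    ab = cols @ a
    cb = np.einsum("ij,ij->i", Cr, cols)
    th_a, th_b, ok = _solve_2col(aa, ab, bb, ca[rows], cb)
    ssr = cc[rows] - (th_a * ca[rows] + th_b * cb)
    ssr = np.where(ok, np.maximum(ssr, 0.0), np.inf)
    return ssr, th_a, th_b


def fit_model(profile: ConcentrationProfile, aif: AIF, model_id: int) -> ModelFit:
    """Fit a single nested model to one voxel's profile.

    Models 1 and 2 are linear least squares; model 3 uses the separable
    solver (coarse log-grid over kep, zoom, parabolic refinement).
    """

    if not profile.grid.matches(aif.grid):
        raise ValueError("profile and AIF must share the same time grid")
    r = fit_models_matrix(profile.c[None, :], aif)
    n_fit = r["n_fit"]
    if model_id == 1:
        return ModelFit(1, PKParams(vp=float(r["vp1"][0])), float(r["ssr1"][0]), n_fit)
    if model_id == 2:
        return ModelFit(
            2, PKParams(vp=float(r["vp2"][0]), ktrans=float(r["kt2"][0])), float(r["ssr2"][0]), n_fit
        )
    if model_id == 3:
        return ModelFit(
            3,
            PKParams(vp=float(r["vp3"][0]), ktrans=float(r["kt3"][0]), kep=float(r["kep3"][0])),
            float(r["ssr3"][0]),
            n_fit,
        )
    raise ValueError("model_id must be 1, 2 or 3")
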