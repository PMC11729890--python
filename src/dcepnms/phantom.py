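"""Synthetic DCE-MRI phantoms and labeled profile collections.

The phantom emulates the statistical structure the analysis assumes: a
brain-slice geometry with a non-leaky normal-tissue background (model 1), a
leaky tumor rim (model 2) and a tumor core with measurable back-flux
(model 3); a bolus-shaped AIF with a pre-injection baseline (injection at
sample 15 of a 400-sample acquisition, ~1.53 s per frame); additive iid
Gaussian noise expressed as a fraction of the AIF peak.  Ground-truth
labels and parameter maps are always emitted alongside the data.

Default parameter ranges (sampled uniformly per voxel) are physiological
conventions for rat brain tumor tissue: vp in [0.005, 0.04], Ktrans in
[0.01, 0.3] 1/min, kep in [0.1, 3] 1/min.  Flat profile collections use a
65 / 26 / 9 % class imbalance mirroring a realistic labeled corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aif import AIFSpec, synth_aif
from .kinetics import AIF, TimeGrid, exp_conv
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DEFAULT_RANGES",
    "PhantomSpec",
    "Phantom",
    "ProfileSet",
    "Cohort",
    "paper_like_counts",
    "default_grid",
    "generate_phantom",
    "generate_profile_set",
    "generate_cohort",
]

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "vp": (0.005, 0.04),
    "ktrans": (0.01, 0.3),
    "kep": (0.1, 3.0),
}

#: class fractions of a labeled corpus dominated by normal tissue
CLASS_FRACTIONS = (0.6526, 0.2628, 0.0846)

FRAME_MINUTES = 1.533 / 60.0  # ~23 s to injection frame 15


def default_grid(n_t: int = 400, dt: float = FRAME_MINUTES, n_baseline: int = 20) -> TimeGrid:
    """The default 400-frame acquisition grid (minutes)."""

    return TimeGrid(np.arange(n_t) * dt, n_baseline=n_baseline)


def paper_like_counts(n_total: int) -> tuple[int, int, int]:
    """Split ``n_total`` into the default 65/26/9% model-class imbalance."""

    n1 = int(round(n_total * CLASS_FRACTIONS[0]))
    n2 = int(round(n_total * CLASS_FRACTIONS[1]))
    return n1, n2, n_total - n1 - n2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetic ranges and noise of the digital brain-slice phantom."""

    shape: tuple[int, int, int] = (32, 32, 1)
    n_t: int = 400
    dt: float = FRAME_MINUTES
    n_baseline: int = 20
    injection_index: int = 15
    noise_sigma: float = 0.02  # fraction of the AIF peak
    noise_ar1: float = 0.0  # optional temporal correlation of the noise
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    aif_spec: AIFSpec | None = None
    seed: int = 0

    def grid(self) -> TimeGrid:
        return TimeGrid(np.arange(self.n_t) * self.dt, n_baseline=self.n_baseline)

    def resolved_aif_spec(self) -> AIFSpec:
        if self.aif_spec is not None:
            return self.aif_spec
        return AIFSpec(t_inj=self.injection_index * self.dt)


@dataclass
class Phantom:
    """Synthetic 4-D volume with ground truth."""

    volume: np.ndarray  # (x, y, z, t)
    labels: np.ndarray  # 0 background, 1..3 model regions
    mask: np.ndarray  # brain mask (labels > 0)
    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    aif: AIF
    grid: TimeGrid
    spec: PhantomSpec


def _region_labels(shape: tuple[int, int, int]) -> np.ndarray:
    """Brain ellipse (1) with an off-center tumor rim (2) around a core (3)."""

    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    brain = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.45 * ny)) ** 2 <= 1.0
    tx, ty = cx + 0.18 * nx, cy - 0.12 * ny
    r = np.sqrt((x - tx) ** 2 + (y - ty) ** 2)
    scale = min(nx, ny)
    core = r <= 0.11 * scale
    rim = (r <= 0.20 * scale) & ~core
    lab2d = np.zeros((nx, ny), dtype=np.int8)
    lab2d[brain] = 1
    lab2d[rim & brain] = 2
    lab2d[core & brain] = 3
    return np.repeat(lab2d[:, :, None], nz, axis=2)


def _synth_curves(params: pd.DataFrame, aif: AIF) -> np.ndarray:
    """Noiseless forward curves for a table of (label, vp, ktrans, kep)."""

    t = aif.grid.t
    a = aif.c
    q = cumulative_trapezoid(a, t, initial=0.0)
    C = params["vp"].to_numpy()[:, None] * a[None, :]
    lab = params["label"].to_numpy()
    kt = params["ktrans"].to_numpy()
    kep = params["kep"].to_numpy()
    is2 = lab == 2
    if is2.any():
        C[is2] += kt[is2, None] * q[None, :]
    is3 = lab == 3
    if is3.any():
        # group voxels by kep for vectorized convolution
        for k in np.unique(kep[is3]):
            rows = is3 & (kep == k)
            C[rows] += kt[rows, None] * exp_conv(a, t, float(k))[None, :]
    return C


def _sample_params(rng: np.random.Generator, labels: np.ndarray, ranges: dict) -> pd.DataFrame:
    n = labels.size
    vp = rng.uniform(*ranges["vp"], size=n)
    kt = np.where(labels >= 2, rng.uniform(*ranges["ktrans"], size=n), 0.0)
    kep = np.where(labels == 3, rng.uniform(*ranges["kep"], size=n), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(kep > 0, kt / kep, 0.0)
    return pd.DataFrame({"label": labels, "vp": vp, "ktrans": kt, "kep": kep, "ve": ve})


def _add_noise(C: np.ndarray, sigma_abs: float, rng: np.random.Generator, ar1: float = 0.0) -> np.ndarray:
    if sigma_abs <= 0:
        return C
    eps = rng.normal(0.0, sigma_abs, size=C.shape)
    if ar1 > 0:
        for i in range(1, C.shape[1]):
            eps[:, i] = ar1 * eps[:, i - 1] + np.sqrt(1 - ar1**2) * eps[:, i]
    return C + eps


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic (seeded) digital phantom with ground-truth maps."""

    grid = spec.grid()
    aif = synth_aif(spec.resolved_aif_spec(), grid)
    labels3d = _region_labels(spec.shape)
    mask = labels3d > 0
    rng = np.random.default_rng(spec.seed)
    idx = np.flatnonzero(mask.ravel())
    lab = labels3d.ravel()[idx]
    params = _sample_params(rng, lab, spec.ranges)
    C = _synth_curves(params, aif)
    C = _add_noise(C, spec.noise_sigma * aif.peak, rng, spec.noise_ar1)
    volume = np.zeros(spec.shape + (spec.n_t,), dtype=float)
    volume.reshape(-1, spec.n_t)[idx] = C

    def to_map(v):
        m = np.zeros(np.prod(spec.shape))
        m[idx] = v
        return m.reshape(spec.shape)

    return Phantom(
        volume=volume,
        labels=labels3d,
        mask=mask,
        vp=to_map(params["vp"]),
        ktrans=to_map(params["ktrans"]),
        kep=to_map(params["kep"]),
        ve=to_map(params["ve"]),
        aif=aif,
        grid=grid,
        spec=spec,
    )


@dataclass
class ProfileSet:
    """Flat labeled profile collection for SOM training and validation."""

    profiles: np.ndarray  # (n, n_t) raw ΔR1 curves
    labels: np.ndarray  # ground-truth model class
    params: pd.DataFrame
    aif: AIF
    grid: TimeGrid


def generate_profile_set(
    n1: int,
    n2: int,
    n3: int,
    noise_sigma: float = 0.02,
    seed: int = 0,
    grid: TimeGrid | None = None,
    aif_spec: AIFSpec | None = None,
    ranges: dict | None = None,
    noise_ar1: float = 0.0,
) -> ProfileSet:
    """Labeled flat table of synthetic profiles (n1 + n2 + n3 rows)."""

    if min(n1, n2, n3) < 0:
        raise ValueError("counts must be >= 0")
    if n1 + n2 + n3 == 0:
        raise ValueError("at least one profile is required")
    grid = grid or default_grid()
    spec = aif_spec or AIFSpec(t_inj=15 * float(np.diff(grid.t[:2])[0]))
    aif = synth_aif(spec, grid)
    labels = np.concatenate([np.full(n, j, dtype=np.int8) for j, n in ((1, n1), (2, n2), (3, n3))])
    rng = np.random.default_rng(seed)
    params = _sample_params(rng, labels, ranges or DEFAULT_RANGES)
    C = _synth_curves(params, aif)
    C = _add_noise(C, noise_sigma * aif.peak, rng, noise_ar1)
    return ProfileSet(profiles=C, labels=labels, params=params, aif=aif, grid=grid)


@dataclass
class Cohort:
    """Multi-subject profile collection with subject ids for CV splitting."""

    profiles: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    params: pd.DataFrame
    aif: AIF
    grid: TimeGrid


def generate_cohort(
    n_subjects: int = 10,
    profiles_per_subject: int = 800,
    noise_sigma: float = 0.02,
    seed: int = 0,
    subject_sd: float = 0.15,
    grid: TimeGrid | None = None,
    class_fractions: tuple[float, float, float] = CLASS_FRACTIONS,
) -> Cohort:
    """Synthetic cohort: subjects share the study AIF but differ by a
    lognormal random effect on their kinetic-range centers (``subject_sd``)."""

    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(n_subjects):
        eff = np.exp(rng.normal(0.0, subject_sd, size=2))  # vp, ktrans multipliers
        ranges = {
            "vp": tuple(np.clip(np.array(DEFAULT_RANGES["vp"]) * eff[0], 1e-4, 0.2)),
            "ktrans": tuple(np.clip(np.array(DEFAULT_RANGES["ktrans"]) * eff[1], 1e-3, 1.0)),
            "kep": DEFAULT_RANGES["kep"],
        }
        n1 = int(round(profiles_per_subject * class_fractions[0]))
        n2 = int(round(profiles_per_subject * class_fractions[1]))
        n3 = profiles_per_subject - n1 - n2
        ps = generate_profile_set(
            n1, n2, n3,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31 - 1)),
            grid=grid,
            ranges=ranges,
        )
        sets.append(ps)
    profiles = np.vstack([p.profiles for p in sets])
    labels = np.concatenate([p.labels for p in sets])
    subjects = np.concatenate([np.full(p.labels.size, s) for s, p in enumerate(sets)])
    params = pd.concat([p.params for p in sets], ignore_index=True)
    params["subject"] = subjects
    return Cohort(
        profiles=profiles, labels=labels, subjects=subjects,
        params=params, aif=sets[0].aif, grid=grid,
    )
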