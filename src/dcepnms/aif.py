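"""Parametric arterial input functions and reference-tissue normalization.

The simulation AIF is a gamma-variate first-pass bolus plus a slowly
decaying recirculation/washout term — a smooth Parker-like family that
stands in for a measured group-averaged radiological trace.  It is used for
synthetic data only; measured AIFs enter through the same :class:`~dcepnms.kinetics.AIF`
container.

``normalize_aif`` rescales a raw AIF so that a non-leaky reference tissue
(conventionally the caudate putamen) fits to a prescribed plasma volume
fraction, 1% by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import AIF, ConcentrationProfile, SingularFitError, TimeGrid, fit_models_matrix

__all__ = ["AIFSpec", "synth_aif", "normalize_aif"]


@dataclass(frozen=True)
class AIFSpec:
    """Shape parameters of the simulated bolus AIF.

    t_inj : float
        Injection time (min); the AIF is exactly zero before it.
    amplitude : float
        Scale of the first-pass peak (ΔR1-proportional units).
    peak_delay : float
        Time to the gamma-variate peak after injection (min).
    bolus_shape : float
        Gamma-variate shape exponent (sharpness of the first pass).
    washout_fraction : float
        Plateau amplitude of the recirculation term relative to the peak.
    washout_rate : float
        Slow washout rate of the recirculation term (1/min).
    rise_rate : float
        Rise rate of the recirculation term (1/min).
    """

    t_inj: float = 23.0 / 60.0
    amplitude: float = 1.0
    peak_delay: float = 0.25
    bolus_shape: float = 3.0
    washout_fraction: float = 0.35
    washout_rate: float = 0.12
    rise_rate: float = 8.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.peak_delay <= 0 or self.bolus_shape <= 0:
            raise ValueError("peak_delay and bolus_shape must be positive")


def synth_aif(spec: AIFSpec, grid: TimeGrid) -> AIF:
    """Evaluate the parametric bolus AIF on a time grid (zero before ``t_inj``)."""

    t = grid.t
    if not (t[0] <= spec.t_inj <= t[-1]):
        raise ValueError("injection time lies outside the time grid")
    c = aif_curve(spec, t)
    return AIF(grid, c)


def aif_curve(spec: AIFSpec, t: np.ndarray) -> np.ndarray:
    """The AIF as a smooth function of time (used for fine-grid oracles too)."""

    tau = np.asarray(t, dtype=float) - spec.t_inj
    c = np.zeros_like(tau)
    pos = tau > 0
    tp, al = spec.peak_delay, spec.bolus_shape
    x = tau[pos] / tp
    bolus = x**al * np.exp(al * (1.0 - x))
    recirc = spec.washout_fraction * (1.0 - np.exp(-spec.rise_rate * tau[pos])) * np.exp(
        -spec.washout_rate * tau[pos]
    )
    c[pos] = spec.amplitude * (bolus + recirc)
    return c


def normalize_aif(
    aif_raw: AIF, ref_profile: ConcentrationProfile, vp_ref: float = 0.01
) -> tuple[AIF, float]:
    """Scale an AIF so the non-leaky reference tissue fits to ``vp_ref``.

    The model-1 least-squares plasma volume of ``ref_profile`` against the
    raw AIF is ``vp_raw``; the returned AIF is scaled by ``s = vp_raw /
    vp_ref`` so that refitting yields exactly ``vp_ref``.  Returns
    ``(aif_normalized, s)``.
    """

    if vp_ref <= 0:
        raise ValueError("vp_ref must be positive")
    if not ref_profile.grid.matches(aif_raw.grid):
        raise ValueError("reference profile and AIF must share a time grid")
    fit = fit_models_matrix(ref_profile.c[None, :], aif_raw)
    vp_raw = float(fit["vp1"][0])
    ref_energy = float(fit["cc"][0])
    if ref_energy <= 1e-300 or abs(vp_raw) <= 1e-12:
        raise SingularFitError("reference signal too small to normalize the AIF")
    s = vp_raw / vp_ref
    return aif_raw.scaled(s), s
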