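"""Spectrophotometric pKa estimation from pH-dependent intensities.

A single-wavelength two-state model: the observed intensity is the
population-weighted mixture of the neutral and ionized end-member
intensities, with the ionized fraction following Henderson-Hasselbalch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simulate import PhSeries

__all__ = ["IonizationFit", "ionized_fraction", "fit_pka"]


@dataclass(frozen=True)
class IonizationFit:
    """Two-state fit of an intensity-vs-pH series."""

    pka: float
    se_pka: float
    i_neutral: float
    i_ionized: float
    residual_sd: float
    success: bool = True
    message: str = ""


def ionized_fraction(ph: float, pka: float) -> float:
    """Henderson-Hasselbalch ionized fraction f = 1/(1 + 10^(pKa - pH))."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def fit_pka(series: PhSeries) -> IonizationFit:
    """Nonlinear least squares of I(pH) = f*I_ion + (1-f)*I_neutral.

    Free parameters are (pKa, I_neutral, I_ionized).  The pKa is initialized
    at the pH of the steepest observed intensity change and the end-members
    at the intensities at the pH extremes.  A series whose total intensity
    range does not exceed three times a second-difference noise estimate is
    reported as having no titratable transition in the window.
    """
    ph = np.asarray(series.ph_values, dtype=float)
    intens = np.asarray(series.intensities, dtype=float)
    if len(ph) < 4:
        raise ValueError("at least 4 pH points are required")
    if ph[-1] - ph[0] < 2.0:
        raise ValueError("pH window must span at least 2 units")

    span = float(np.ptp(intens))
    noise = _noise_estimate(intens)
    if span == 0.0 or span < 3.0 * noise:
        return IonizationFit(
            pka=math.nan, se_pka=math.nan,
            i_neutral=math.nan, i_ionized=math.nan,
            residual_sd=noise, success=False,
            message="no titratable transition in window",
        )

    grad = np.abs(np.diff(intens) / np.diff(ph))
    pka0 = float(0.5 * (ph[np.argmax(grad)] + ph[np.argmax(grad) + 1]))
    x0 = np.array([pka0, intens[0], intens[-1]])

    def resid(params: np.ndarray) -> np.ndarray:
        pka, i_n, i_i = params
        f = 1.0 / (1.0 + 10.0 ** (pka - ph))
        return f * i_i + (1.0 - f) * i_n - intens

    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    dof = max(len(ph) - 3, 1)
    sigma2 = float(np.sum(sol.fun**2)) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        se_pka = float(math.sqrt(max(sigma2 * np.linalg.inv(jtj)[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_pka = math.nan

    return IonizationFit(
        pka=float(sol.x[0]),
        se_pka=se_pka,
        i_neutral=float(sol.x[1]),
        i_ionized=float(sol.x[2]),
        residual_sd=math.sqrt(sigma2),
        success=bool(sol.success),
        message="" if sol.success else "optimizer did not converge",
    )


def _noise_estimate(intens: np.ndarray) -> float:
    """Noise SD from second differences (kills smooth trend, keeps noise)."""
    if len(intens) < 3:
        return 0.0
    d2 = np.diff(intens, n=2)
    return float(np.sqrt(np.mean(d2**2) / 6.0))
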