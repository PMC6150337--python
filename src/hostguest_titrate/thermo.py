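"""Complexation thermodynamics bookkeeping.

Harmonic-oscillator vibrational entropy from normal-mode wavenumbers,
Gibbs free energy from enthalpy/entropy pairs, van't Hoff conversion of
free energy to a decimal log equilibrium constant, and a consistency
checker for tabulated (dH, dS, dG) records.

Units follow the tabulation conventions of the field: dH and dG in kJ/mol,
dS in J/(K*mol); the kJ/J bridge lives in exactly one place
(:func:`gibbs_free_energy`).  The default temperature is 298.16 K, matching
the reference tabulation this module is checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.constants import R, c, h, k

__all__ = [
    "T_DEFAULT",
    "ThermoRecord",
    "VibrationalSpectrum",
    "vibrational_entropy",
    "gibbs_free_energy",
    "vant_hoff_log_k",
    "ConsistencyReport",
    "check_table_consistency",
]

T_DEFAULT = 298.16  # K

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ThermoRecord:
    """Thermodynamic parameters of one host-guest pair under one solvation hypothesis."""

    host: str
    guest: str
    dh: float  # kJ/mol
    ds: float  # J/(K*mol)
    dg: float | None = None  # kJ/mol, as tabulated
    temperature: float = T_DEFAULT  # K
    solvation_hypothesis: str = ""  # "dehydrated-guest" | "hydrated-guest"

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class VibrationalSpectrum:
    """Harmonic normal-mode wavenumbers (cm^-1) at a temperature (K)."""

    frequencies: tuple[float, ...]
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("all vibrational frequencies must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


def vibrational_entropy(spec: VibrationalSpectrum) -> float:
    """Harmonic vibrational entropy, J/(K*mol).

    S_vib = R * sum_i [ x_i/(exp(x_i) - 1) - ln(1 - exp(-x_i)) ]

    with x_i = h*nu_i/(k*T); wavenumbers are converted to Hz via the speed
    of light.  Each mode contributes nonnegatively, the sum is additive over
    modes, and every term vanishes in the high-frequency limit.  An empty
    mode list gives exactly zero.
    """
    if not spec.frequencies:
        return 0.0
    nu = np.asarray(spec.frequencies, dtype=float) * 100.0 * c  # cm^-1 -> Hz
    x = h * nu / (k * spec.temperature)
    terms = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(R * np.sum(terms))


def gibbs_free_energy(dh: float, ds: float, temperature: float = T_DEFAULT) -> float:
    """dG = dH - T*dS with dH, dG in kJ/mol and dS in J/(K*mol)."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return dh - temperature * ds / 1000.0


def vant_hoff_log_k(dh: float, ds: float, temperature: float = T_DEFAULT) -> float:
    """Decimal log equilibrium constant implied by dH and dS at T.

    log10 K = -dG / (ln10 * R * T), dG from :func:`gibbs_free_energy`.
    For an exothermic association (dH < 0) the result decreases with T.
    """
    dg = gibbs_free_energy(dh, ds, temperature)
    return -dg * 1000.0 / (_LN10 * R * temperature)


@dataclass(frozen=True)
class ConsistencyRow:
    host: str
    guest: str
    solvation_hypothesis: str
    dg_tabulated: float
    dg_computed: float
    residual: float
    flagged: bool


@dataclass(frozen=True)
class ConsistencyReport:
    rows: tuple[ConsistencyRow, ...]
    skipped: tuple[str, ...]
    tolerance: float

    @property
    def n_flagged(self) -> int:
        return sum(r.flagged for r in self.rows)

    @property
    def max_abs_residual(self) -> float:
        return max((abs(r.residual) for r in self.rows), default=0.0)

    def to_dict(self) -> dict:
        return {
            "tolerance_kJ_mol": self.tolerance,
            "n_rows": len(self.rows),
            "n_flagged": self.n_flagged,
            "max_abs_residual_kJ_mol": self.max_abs_residual,
            "skipped": list(self.skipped),
            "rows": [
                {
                    "host": r.host,
                    "guest": r.guest,
                    "solvation_hypothesis": r.solvation_hypothesis,
                    "dg_tabulated_kJ_mol": r.dg_tabulated,
                    "dg_computed_kJ_mol": r.dg_computed,
                    "residual_kJ_mol": r.residual,
                    "flagged": r.flagged,
                }
                for r in self.rows
            ],
        }


def check_table_consistency(
    records: Sequence[ThermoRecord], tolerance: float = 0.15
) -> ConsistencyReport:
    """Recompute dG = dH - T*dS per record and compare with the tabulated dG.

    Residual = tabulated - computed (kJ/mol); rows whose absolute residual
    exceeds ``tolerance`` are flagged.  Records without a tabulated dG are
    skipped with a note.
    """
    rows: list[ConsistencyRow] = []
    skipped: list[str] = []
    for rec in records:
        if rec.dg is None:
            skipped.append(f"{rec.guest}-{rec.host}: no tabulated dG")
            continue
        dg_comp = gibbs_free_energy(rec.dh, rec.ds, rec.temperature)
        residual = rec.dg - dg_comp
        rows.append(
            ConsistencyRow(
                host=rec.host,
                guest=rec.guest,
                solvation_hypothesis=rec.solvation_hypothesis,
                dg_tabulated=rec.dg,
                dg_computed=dg_comp,
                residual=residual,
                flagged=abs(residual) > tolerance,
            )
        )
    return ConsistencyReport(rows=tuple(rows), skipped=tuple(skipped), tolerance=tolerance)
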