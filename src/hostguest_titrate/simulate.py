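"""Synthetic titration and pH-series generators.

The generators produce data with exactly the statistical structure the
fitting routines assume: saturation-type fluorescence enhancement on the
standard 11-point cyclodextrin grid (0-2.0 mM host, 2 uM guest), intensity
as a linear combination of species concentrations from the exact mass-action
solver, and two-state ionization curves.  Noise is additive Gaussian with a
relative standard deviation, reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import BindingModel, TitrationSeries, solve_speciation

__all__ = [
    "TitrationSimSpec",
    "PhSeries",
    "default_host_grid",
    "generate_titration_bh",
    "generate_titration_speciation",
    "generate_ph_series",
]

#: Host concentration grid used throughout, mol/dm^3 (0, 0.02 ... 2.0 mM),
#: written as exact literals so 0.07 mM is 7e-5 and not 7.000000000000001e-5.
_DEFAULT_GRID = (0.0, 2e-5, 5e-5, 7e-5, 1e-4, 2e-4, 5e-4, 7e-4, 1e-3, 1.5e-3, 2e-3)


def default_host_grid() -> tuple[float, ...]:
    """The standard 11-point cyclodextrin titration grid in mol/dm^3.

    First point is zero host and defines the baseline intensity I0.
    """
    return _DEFAULT_GRID


@dataclass(frozen=True)
class TitrationSimSpec:
    """Parameters of one simulated fluorescence titration.

    ``log_k`` drives the single-constant saturation shortcut
    (:func:`generate_titration_bh`); ``model`` drives the full speciation
    generator.  ``amplitude_a`` is the relative enhancement amplitude A:
    the noise-free intensity saturates at i0 * (1 + A).
    """

    i0: float = 100.0
    amplitude_a: float = 7.0
    log_k: float | None = None
    model: BindingModel | None = None
    guest_total: float = 2.0e-6
    host_grid: tuple[float, ...] = field(default_factory=default_host_grid)
    noise_sd_rel: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValueError("baseline intensity i0 must be positive")
        if not self.amplitude_a > 0:
            raise ValueError("enhancement amplitude must be positive")
        if self.noise_sd_rel < 0:
            raise ValueError("relative noise SD must be nonnegative")
        if len(self.host_grid) == 0:
            raise ValueError("host grid must be non-empty")


def _add_noise(intensities: np.ndarray, noise_sd_rel: float, seed: int | None) -> np.ndarray:
    if noise_sd_rel == 0:
        return intensities
    rng = np.random.default_rng(seed)
    return intensities + rng.normal(0.0, noise_sd_rel * intensities)


def generate_titration_bh(spec: TitrationSimSpec, n: int = 1) -> TitrationSeries:
    """Titration following the saturation enhancement law exactly.

    Noise-free intensities satisfy

        I = I0 * (1 + A * K [CD]^n / (1 + K [CD]^n)),

    the form whose double reciprocal is the Benesi-Hildebrand line
    I0/(I - I0) = 1/A + 1/(A K [CD]^n).
    """
    if spec.log_k is None:
        raise ValueError("spec.log_k is required for the saturation generator")
    grid = np.asarray(spec.host_grid, dtype=float)
    k = 10.0 ** spec.log_k
    occ = np.zeros_like(grid)
    nz = grid > 0
    kcn = k * grid[nz] ** n
    occ[nz] = kcn / (1.0 + kcn)
    intensities = spec.i0 * (1.0 + spec.amplitude_a * occ)
    intensities = _add_noise(intensities, spec.noise_sd_rel, spec.seed)
    return TitrationSeries(
        guest_total=spec.guest_total,
        host_totals=tuple(grid),
        intensities=tuple(intensities),
        metadata={"generator": "saturation", "log_k": repr(spec.log_k)},
    )


def generate_titration_speciation(
    spec: TitrationSimSpec,
    emissivities: Mapping[str | tuple[int, int], float],
) -> TitrationSeries:
    """Titration whose intensities come from the exact speciation solver.

    The observation model is linear in species concentrations,

        I_j = eps_free * [G]_free,j + sum_pq eps_pq * q * [CD_p G_q]_j,

    the same model the global fit assumes; ``emissivities`` maps ``"free"``
    and each (p, q) pair to an emissivity in a.u. per mol/dm^3 of guest.
    """
    if spec.model is None or not spec.model.species:
        raise ValueError("spec.model with at least one species is required")
    if "free" not in emissivities:
        raise ValueError("an emissivity for the free guest ('free') is required")
    for pq in spec.model.stoichiometries:
        if pq not in emissivities:
            raise ValueError(f"missing emissivity for complex {pq}")

    intensities = []
    for host in spec.host_grid:
        sp = solve_speciation(host, spec.guest_total, spec.model)
        i = emissivities["free"] * sp.free_guest
        for pq, c in sp.complex_conc.items():
            i += emissivities[pq] * pq[1] * c
        intensities.append(i)
    intensities = _add_noise(np.asarray(intensities), spec.noise_sd_rel, spec.seed)
    return TitrationSeries(
        guest_total=spec.guest_total,
        host_totals=tuple(spec.host_grid),
        intensities=tuple(intensities),
        metadata={"generator": "speciation", "model": spec.model.label},
    )


@dataclass(frozen=True)
class PhSeries:
    """Intensity as a function of pH at a fixed wavelength."""

    ph_values: tuple[float, ...]
    intensities: tuple[float, ...]
    wavelength_nm: float | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ph_values) != len(self.intensities):
            raise ValueError("ph_values and intensities must have equal length")
        ph = np.asarray(self.ph_values, dtype=float)
        if len(ph) > 1 and not np.all(np.diff(ph) > 0):
            raise ValueError("ph_values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ph_values)


def default_ph_grid() -> tuple[float, ...]:
    """pH 4.0 to 10.0 in steps of 0.5 — brackets both mycotoxin pKa values."""
    return tuple(np.arange(4.0, 10.01, 0.5))


def generate_ph_series(
    pka: float,
    i_neutral: float,
    i_ionized: float,
    ph_grid: Sequence[float] | None = None,
    noise_sd_rel: float = 0.0,
    seed: int | None = None,
    wavelength_nm: float | None = None,
) -> PhSeries:
    """Two-state ionization curve I(pH) = f*I_ion + (1-f)*I_neutral.

    f is the Henderson-Hasselbalch ionized fraction 1/(1 + 10^(pKa - pH)).
    """
    grid = np.asarray(ph_grid if ph_grid is not None else default_ph_grid(), dtype=float)
    if grid.size == 0:
        raise ValueError("ph grid must be non-empty")
    f = 1.0 / (1.0 + 10.0 ** (pka - grid))
    intensities = f * i_ionized + (1.0 - f) * i_neutral
    intensities = _add_noise(intensities, noise_sd_rel, seed)
    return PhSeries(
        ph_values=tuple(grid),
        intensities=tuple(intensities),
        wavelength_nm=wavelength_nm,
        metadata={"generator": "two-state", "pka": repr(pka)},
    )
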