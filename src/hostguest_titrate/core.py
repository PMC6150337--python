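"""Domain types and the mass-action equilibrium speciation solver.

Concentrations are mol/dm^3 throughout; association constants carry
dm^3/mol (or the corresponding power for higher stoichiometries) and are
handled as decimal logarithms wherever they parametrise a model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ComplexSpecies",
    "BindingModel",
    "SpeciationResult",
    "TitrationSeries",
    "StepwiseConstants",
    "solve_speciation",
    "complex_1to1_closed_form",
    "overall_from_stepwise",
    "apparent_pka_shift",
]


@dataclass(frozen=True)
class ComplexSpecies:
    """One host-guest complex CD_p G_q with overall formation constant beta_pq.

    ``log_beta`` is log10 of beta_pq = [CD_p G_q] / ([CD]^p [G]^q), so beta
    carries dimension (dm^3/mol)^(p+q-1).
    """

    p: int
    q: int
    log_beta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.p, (int, np.integer)) and self.p >= 1):
            raise ValueError(f"host coefficient p must be a positive integer, got {self.p!r}")
        if not (isinstance(self.q, (int, np.integer)) and self.q >= 1):
            raise ValueError(f"guest coefficient q must be a positive integer, got {self.q!r}")
        if not math.isfinite(self.log_beta):
            raise ValueError(f"log_beta must be finite, got {self.log_beta!r}")

    @property
    def beta(self) -> float:
        return 10.0 ** self.log_beta


@dataclass(frozen=True)
class BindingModel:
    """A candidate set of complex stoichiometries with their overall constants.

    An empty species tuple is the explicit null (no-binding) model.
    """

    species: tuple[ComplexSpecies, ...]
    label: str = ""

    def __post_init__(self) -> None:
        pairs = [(s.p, s.q) for s in self.species]
        if len(set(pairs)) != len(pairs):
            raise ValueError(f"duplicate stoichiometries in model: {pairs}")

    @classmethod
    def one_to_one(cls, log_k: float, label: str = "1:1") -> "BindingModel":
        return cls(species=(ComplexSpecies(1, 1, log_k),), label=label)

    @classmethod
    def null(cls) -> "BindingModel":
        return cls(species=(), label="null")

    def with_log_betas(self, log_betas: Sequence[float]) -> "BindingModel":
        """Same stoichiometries, new constants (used by fitting)."""
        if len(log_betas) != len(self.species):
            raise ValueError("log_betas length must match number of species")
        return BindingModel(
            species=tuple(
                ComplexSpecies(s.p, s.q, float(lb))
                for s, lb in zip(self.species, log_betas)
            ),
            label=self.label,
        )

    @property
    def stoichiometries(self) -> tuple[tuple[int, int], ...]:
        return tuple((s.p, s.q) for s in self.species)


@dataclass(frozen=True)
class SpeciationResult:
    """Free and complexed equilibrium concentrations at one titration point."""

    free_host: float
    free_guest: float
    complex_conc: Mapping[tuple[int, int], float]
    converged: bool
    residual_mass_balance: float

    @property
    def bound_guest(self) -> float:
        return sum(q * c for (_, q), c in self.complex_conc.items())

    @property
    def bound_host(self) -> float:
        return sum(p * c for (p, _), c in self.complex_conc.items())


@dataclass(frozen=True)
class TitrationSeries:
    """One fluorescence titration: fixed guest, ascending host grid, intensities."""

    guest_total: float
    host_totals: tuple[float, ...]
    intensities: tuple[float, ...]
    ph: float | None = None
    excitation_nm: float | None = None
    emission_nm: float | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.host_totals) != len(self.intensities):
            raise ValueError("host_totals and intensities must have equal length")
        h = np.asarray(self.host_totals, dtype=float)
        if len(h) > 1 and not np.all(np.diff(h) > 0):
            raise ValueError("host_totals must be strictly increasing")
        if not self.guest_total > 0:
            raise ValueError("guest_total must be positive")
        if np.any(np.asarray(self.intensities, dtype=float) < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def i0(self) -> float:
        """Intensity at the zero-host point."""
        if self.host_totals[0] != 0.0:
            raise ValueError("series has no zero-host point defining I0")
        return self.intensities[0]

    def __len__(self) -> int:
        return len(self.host_totals)


@dataclass(frozen=True)
class StepwiseConstants:
    """Stepwise association constants K1..Kq (dm^3/mol)."""

    ks: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ks) == 0:
            raise ValueError("at least one stepwise constant is required")
        if any(k <= 0 for k in self.ks):
            raise ValueError("stepwise constants must be positive")


def overall_from_stepwise(stepwise: StepwiseConstants) -> np.ndarray:
    """Overall constants beta_q = K1 * K2 * ... * Kq (cumulative product)."""
    return np.cumprod(np.asarray(stepwise.ks, dtype=float))


def complex_1to1_closed_form(host_total: float, guest_total: float, k: float) -> float:
    """Exact 1:1 complex concentration from the binding quadratic.

    Solves c^2 - (H + G + 1/K) c + H*G = 0 for the physical (smaller) root,
    evaluated in the numerically stable form 2HG / (b + sqrt(b^2 - 4HG)).
    Symmetric in the two totals and bounded by min(H, G).
    """
    if host_total < 0 or guest_total < 0:
        raise ValueError("totals must be nonnegative")
    if not k > 0:
        raise ValueError("association constant must be positive")
    if host_total == 0.0 or guest_total == 0.0:
        return 0.0
    b = host_total + guest_total + 1.0 / k
    disc = b * b - 4.0 * host_total * guest_total
    # disc >= (H - G)^2 > 0 analytically; clip guards rounding at H == G, huge K
    root = math.sqrt(max(disc, 0.0))
    return 2.0 * host_total * guest_total / (b + root)


def _mass_balance_residuals(
    h: float, g: float, host_total: float, guest_total: float,
    ps: np.ndarray, qs: np.ndarray, betas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw residuals of both balances and the complex concentrations."""
    c = betas * h ** ps * g ** qs
    f = np.array([
        h + float(np.dot(ps, c)) - host_total,
        g + float(np.dot(qs, c)) - guest_total,
    ])
    return f, c


def solve_speciation(
    host_total: float,
    guest_total: float,
    model: BindingModel,
    *,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciationResult:
    """Equilibrium speciation for one (host_total, guest_total) point.

    Solves the pair of mass balances

        H_tot = [CD] + sum_pq p * beta_pq [CD]^p [G]^q
        G_tot = [G]  + sum_pq q * beta_pq [CD]^p [G]^q

    by damped Newton iteration on the logarithms of the free concentrations
    (which keeps them positive), started from free = totals.  Convergence
    requires both relative mass-balance residuals below ``tol``.  Degenerate
    inputs (a zero total, or the null model) are handled analytically.
    """
    if host_total < 0 or guest_total < 0:
        raise ValueError("totals must be nonnegative")

    stoich = model.stoichiometries
    if not model.species or host_total == 0.0 or guest_total == 0.0:
        return SpeciationResult(
            free_host=host_total,
            free_guest=guest_total,
            complex_conc={pq: 0.0 for pq in stoich},
            converged=True,
            residual_mass_balance=0.0,
        )

    ps = np.array([s.p for s in model.species], dtype=float)
    qs = np.array([s.q for s in model.species], dtype=float)
    betas = np.array([s.beta for s in model.species], dtype=float)

    scale = np.array([host_total, guest_total])

    def rel_residual(h: float, g: float) -> tuple[float, np.ndarray]:
        f, c = _mass_balance_residuals(h, g, host_total, guest_total, ps, qs, betas)
        return float(np.max(np.abs(f) / scale)), c

    h, g = host_total, guest_total
    res, c = rel_residual(h, g)
    converged = res <= tol

    for _ in range(max_iter):
        if converged:
            break
        # Jacobian of the balances w.r.t. (ln h, ln g)
        j11 = h + float(np.dot(ps * ps, c))
        j12 = float(np.dot(ps * qs, c))
        j22 = g + float(np.dot(qs * qs, c))
        jac = np.array([[j11, j12], [j12, j22]])
        f, _ = _mass_balance_residuals(h, g, host_total, guest_total, ps, qs, betas)
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5.0, 5.0)  # guard wild early steps in log space
        lam = 1.0
        for _ in range(60):
            h_new = h * math.exp(lam * step[0])
            g_new = g * math.exp(lam * step[1])
            res_new, c_new = rel_residual(h_new, g_new)
            if res_new < res:
                h, g, res, c = h_new, g_new, res_new, c_new
                break
            lam *= 0.5
        else:
            break
        converged = res <= tol

    return SpeciationResult(
        free_host=h,
        free_guest=g,
        complex_conc={pq: float(ci) for pq, ci in zip(stoich, c)},
        converged=bool(converged),
        residual_mass_balance=float(res),
    )


def apparent_pka_shift(pka: float, k: float, free_host: float) -> float:
    """Apparent pKa of a guest whose neutral form alone binds the host.

    Complexation sequesters the neutral acid, so the observed dissociation
    midpoint moves alkaline by log10(1 + K*[CD]_free):

        pKa' = pKa + log10(1 + K [CD]_free)

    Monotone nondecreasing in both K and the free host concentration.
    """
    if k < 0:
        raise ValueError("association constant must be nonnegative")
    if free_host < 0:
        raise ValueError("free host concentration must be nonnegative")
    return pka + math.log1p(k * free_host) / math.log(10.0)
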