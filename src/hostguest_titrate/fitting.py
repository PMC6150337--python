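"""Association-constant estimation from fluorescence titrations.

Two estimators are provided.  The Benesi-Hildebrand (BH) route linearizes a
1:1 (or n-site) saturation isotherm in double-reciprocal coordinates and
reads K off the intercept/slope ratio; it assumes the free host equals the
total host.  The global route fits overall formation constants through the
exact mass-action speciation model with emissivities profiled out linearly
at every step (separable least squares), and therefore remains unbiased
when guest depletion makes the BH approximation fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .core import BindingModel, TitrationSeries, solve_speciation

__all__ = [
    "BindingFitResult",
    "BHTransform",
    "bh_transform",
    "bh_fit",
    "global_fit",
    "select_model",
    "enhancement_ratio",
]

LOG_BETA_BOUNDS = (-2.0, 12.0)
_MULTISTART_LOG_BETA = (2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class BindingFitResult:
    """Outcome of one binding-constant fit (either method)."""

    method: str  # "benesi-hildebrand" | "global"
    success: bool
    log_k_or_beta: Mapping[tuple[int, int], float] = field(default_factory=dict)
    se_log: Mapping[tuple[int, int], float] = field(default_factory=dict)
    amplitude_a: float | None = None
    emissivities: Mapping[str | tuple[int, int], float] = field(default_factory=dict)
    residual_sd: float | None = None
    r_squared: float | None = None
    n_sites: int | None = None
    n_dropped: int = 0
    n_free_parameters: int = 0
    at_bound: bool = False
    message: str = ""

    @property
    def log_k(self) -> float:
        """Shortcut to the single-constant estimate of a 1:1 fit."""
        if len(self.log_k_or_beta) != 1:
            raise ValueError("log_k is defined only for single-species fits")
        return next(iter(self.log_k_or_beta.values()))


@dataclass(frozen=True)
class BHTransform:
    """Double-reciprocal coordinates x = 1/[CD]^n, y = I0/(I - I0)."""

    x: np.ndarray
    y: np.ndarray
    n_dropped: int
    i0: float


def bh_transform(t: TitrationSeries, n: int = 1, i0: float | None = None) -> BHTransform:
    """Benesi-Hildebrand double-reciprocal transform of a titration.

    Points with zero host are excluded (they define I0); points with
    I <= I0 have no defined transform and are dropped with a count.
    """
    if n < 1:
        raise ValueError("number of binding sites n must be >= 1")
    if i0 is None:
        i0 = t.i0  # raises if no zero-host point
    host = np.asarray(t.host_totals, dtype=float)
    intens = np.asarray(t.intensities, dtype=float)
    nz = host > 0
    host, intens = host[nz], intens[nz]
    usable = intens > i0
    n_dropped = int(np.sum(~usable))
    if n_dropped == len(host):
        raise RuntimeError("all titration points dropped: no intensity exceeds I0")
    x = 1.0 / host[usable] ** n
    y = i0 / (intens[usable] - i0)
    return BHTransform(x=x, y=y, n_dropped=n_dropped, i0=i0)


def bh_fit(
    t: TitrationSeries,
    n: int = 1,
    i0: float | None = None,
    weights: Sequence[float] | None = None,
) -> BindingFitResult:
    """Estimate log10 K by (weighted) least squares on the BH line.

    The regression of y = I0/(I - I0) on x = 1/[CD]^n has intercept 1/A and
    slope 1/(A K), hence K = intercept/slope and A = 1/intercept.  The
    standard error of log10 K follows by first-order propagation from the
    regression covariance.  The default is unweighted OLS (the graphical
    convention); ``weights`` accepts inverse-variance weights aligned with
    the usable transformed points.  A non-positive intercept or slope means
    the data do not saturate and is reported as a flagged failure, not an
    exception.
    """
    try:
        tr = bh_transform(t, n=n, i0=i0)
    except RuntimeError as exc:  # every point dropped: nothing rises above I0
        return BindingFitResult(
            method="benesi-hildebrand",
            success=False,
            n_sites=n,
            n_dropped=len(t) - 1,
            message=f"no saturable binding: {exc}",
        )
    if len(tr.x) < 3:
        raise ValueError("at least 3 usable transformed points are required")

    X = sm.add_constant(tr.x)
    if weights is None:
        ols = sm.OLS(tr.y, X).fit()
    else:
        if len(weights) != len(tr.x):
            raise ValueError("weights must align with the usable transformed points")
        ols = sm.WLS(tr.y, X, weights=np.asarray(weights, dtype=float)).fit()
    intercept, slope = ols.params
    if intercept <= 0 or slope <= 0:
        return BindingFitResult(
            method="benesi-hildebrand",
            success=False,
            n_sites=n,
            n_dropped=tr.n_dropped,
            message="no saturable binding: non-positive BH intercept or slope",
        )

    k = intercept / slope
    amplitude = 1.0 / intercept
    # Var(log10 K) with log10 K = log10(b0) - log10(b1)
    cov = ols.cov_params()
    ln10 = math.log(10.0)
    var_log_k = (
        cov[0, 0] / intercept**2
        + cov[1, 1] / slope**2
        - 2.0 * cov[0, 1] / (intercept * slope)
    ) / ln10**2
    se_log_k = math.sqrt(max(var_log_k, 0.0))

    # residual SD on the intensity scale, from the back-transformed curve
    host = np.asarray(t.host_totals, dtype=float)
    intens = np.asarray(t.intensities, dtype=float)
    kcn = np.where(host > 0, k * host**n, 0.0)
    fitted = tr.i0 * (1.0 + amplitude * kcn / (1.0 + kcn))
    resid = intens - fitted
    dof = max(len(resid) - 3, 1)  # K, A, I0
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))

    return BindingFitResult(
        method="benesi-hildebrand",
        success=True,
        log_k_or_beta={(1, n): math.log10(k)},
        se_log={(1, n): se_log_k},
        amplitude_a=amplitude,
        residual_sd=residual_sd,
        r_squared=float(ols.rsquared),
        n_sites=n,
        n_dropped=tr.n_dropped,
        n_free_parameters=2,
    )


def _design_matrix(
    host: np.ndarray, guest_total: float, model: BindingModel, log_betas: np.ndarray
) -> np.ndarray:
    """Columns: free guest, then q*[CD_p G_q] per species, per titration point."""
    m = model.with_log_betas(log_betas)
    cols = np.empty((len(host), 1 + len(m.species)))
    for j, h in enumerate(host):
        sp = solve_speciation(h, guest_total, m)
        cols[j, 0] = sp.free_guest
        for i, pq in enumerate(m.stoichiometries):
            cols[j, 1 + i] = pq[1] * sp.complex_conc[pq]
    return cols


def global_fit(
    t: TitrationSeries,
    model: BindingModel,
    *,
    starts: Sequence[float] = _MULTISTART_LOG_BETA,
    weights: Sequence[float] | None = None,
) -> BindingFitResult:
    """Global nonlinear fit of overall log beta values through speciation.

    Minimizes sum_j (I_obs,j - I_calc,j)^2 where I_calc is the linear
    emissivity observation model evaluated on the exact speciation solution.
    Emissivities are profiled out by linear least squares at each beta step
    (variable projection), so the nonlinear search runs over log betas only;
    it is restarted from several initial values to dodge local minima.
    Unweighted by default; ``weights`` accepts per-point inverse-variance
    weights.
    Standard errors come from the Jacobian of the profiled residual at the
    optimum.  The null model (no species) reduces to a one-parameter linear
    fit of a constant intensity.
    """
    intens = np.asarray(t.intensities, dtype=float)
    host = np.asarray(t.host_totals, dtype=float)
    n_beta = len(model.species)
    n_eps = 1 + n_beta
    n_par = n_beta + n_eps
    if len(t) < n_par + 1:
        raise ValueError(
            f"need at least {n_par + 1} titration points for {n_par} free parameters"
        )
    scale = float(np.max(np.abs(intens)))
    if scale == 0 or np.ptp(intens) <= 1e-12 * scale:
        return BindingFitResult(
            method="global",
            success=False,
            message="degenerate data: no concentration-dependent signal to fit",
        )

    if weights is None:
        sqrt_w = np.ones_like(intens)
    else:
        if len(weights) != len(intens):
            raise ValueError("weights must align with the titration points")
        sqrt_w = np.sqrt(np.asarray(weights, dtype=float))

    def profiled(log_betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = _design_matrix(host, t.guest_total, model, log_betas)
        eps, *_ = np.linalg.lstsq(sqrt_w[:, None] * X, sqrt_w * intens, rcond=None)
        return sqrt_w * (intens - X @ eps), eps

    if n_beta == 0:
        resid, eps = profiled(np.empty(0))
        residual_sd = float(np.sqrt(np.sum(resid**2) / max(len(resid) - 1, 1)))
        return BindingFitResult(
            method="global",
            success=True,
            emissivities={"free": float(eps[0])},
            residual_sd=residual_sd,
            n_free_parameters=1,
            message="null model: constant-emissivity linear fit",
        )

    best = None
    lo, hi = LOG_BETA_BOUNDS
    for start in starts:
        x0 = np.clip(_stagger(start, n_beta), lo + 1e-6, hi - 1e-6)
        try:
            sol = least_squares(
                lambda lb: profiled(lb)[0], x0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # singular design at a pathological start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return BindingFitResult(
            method="global",
            success=False,
            message="optimizer failed to converge from every start",
        )

    resid, eps = profiled(best.x)
    ssr = float(np.sum(resid**2))
    dof = max(len(resid) - n_par, 1)
    sigma2 = ssr / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_beta, np.nan)

    at_bound = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    stoich = model.stoichiometries
    emiss: dict[str | tuple[int, int], float] = {"free": float(eps[0])}
    emiss.update({pq: float(e) for pq, e in zip(stoich, eps[1:])})
    return BindingFitResult(
        method="global",
        success=True,
        log_k_or_beta={pq: float(b) for pq, b in zip(stoich, best.x)},
        se_log={pq: float(s) for pq, s in zip(stoich, se)},
        emissivities=emiss,
        residual_sd=float(np.sqrt(sigma2)),
        n_free_parameters=n_par,
        at_bound=at_bound,
        message="parameter at bound" if at_bound else "",
    )


def _stagger(start: float, n: int) -> np.ndarray:
    """Initial log betas: overall constants grow with complex order."""
    return start + np.arange(n, dtype=float) * start


def _physically_admissible(res: BindingFitResult, tol: float = 0.01) -> bool:
    """Emissivities are photon yields and cannot be negative.

    A fit that needs a materially negative emissivity (beyond ``tol`` of the
    largest one, allowing for noise around a true zero) is describing the
    data with an unphysical species and is excluded from model comparison.
    """
    if not res.emissivities:
        return True
    vals = list(res.emissivities.values())
    top = max(vals)
    return top > 0 and all(v >= -tol * top for v in vals)


def select_model(
    t: TitrationSeries,
    candidates: Sequence[BindingModel],
) -> tuple[BindingModel, list[BindingFitResult]]:
    """Fit every candidate stoichiometry; keep the lowest residual SD.

    Only converged, physically admissible fits (nonnegative emissivities)
    compete.  Residual-SD ties (within 1e-12) break toward the candidate
    with fewer free parameters.
    """
    if len(candidates) == 0:
        raise ValueError("at least one candidate model is required")
    results = []
    for cand in candidates:
        try:
            results.append(global_fit(t, cand))
        except ValueError as exc:
            results.append(BindingFitResult(method="global", success=False, message=str(exc)))
    converged = [
        (cand, res) for cand, res in zip(candidates, results) if res.success
    ]
    if not converged:
        raise RuntimeError("no candidate model converged")
    admissible = [cr for cr in converged if _physically_admissible(cr[1])]
    pool = admissible or converged
    best_cand, best_res = min(
        pool,
        key=lambda cr: (round_tie(cr[1].residual_sd), cr[1].n_free_parameters),
    )
    return best_cand, results


def round_tie(sd: float, tol: float = 1e-12) -> float:
    """Quantize residual SDs so near-equal values compare as ties."""
    return round(sd / tol) * tol if sd else 0.0


def enhancement_ratio(t: TitrationSeries) -> float:
    """Fluorescence enhancement I/I0 at the highest host concentration."""
    i0 = t.i0
    if i0 == 0:
        raise ValueError("I0 is zero: enhancement ratio undefined")
    return t.intensities[-1] / i0
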