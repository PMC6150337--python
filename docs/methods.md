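# Methods

## The equilibrium model

Complex formation between a cyclodextrin host (CD) and a zearalenol guest
(G) is described by mass action. Every candidate species
CD<sub>p</sub>G<sub>q</sub> (p, q ≥ 1) carries an overall formation
constant β<sub>pq</sub> = [CD<sub>p</sub>G<sub>q</sub>] /
([CD]<sup>p</sup>[G]<sup>q</sup>), with dimension (dm³/mol)^(p+q−1);
stepwise constants multiply cumulatively into overall ones
(β₁ = K₁, β₂ = K₁K₂, …). All concentrations are mol/dm³ internally; the
CSV layer converts from mM (host) and µM (guest). Constants are handled as
decimal logarithms.

Activity corrections, ionic-strength effects and any temperature dependence
of β inside the solver are deliberately out of scope; temperature enters
only through the van't Hoff relation in the thermodynamics module.

### Speciation solver

Given totals (CD_tot, G_tot) and a model, the two mass balances

    CD_tot = [CD] + Σ p·β_pq [CD]^p [G]^q
    G_tot  = [G]  + Σ q·β_pq [CD]^p [G]^q

are solved by damped Newton iteration on (ln[CD], ln[G]) — the log
parametrization keeps concentrations positive without constraints — started
from free = totals, with step halving whenever a step fails to reduce the
residual, steps clipped to ±5 log-units, an iteration cap of 200, and
convergence declared when both relative residuals fall below 1e−12.
Zero totals and the null (no-binding) model are handled analytically.
Non-convergence is reported through an explicit flag, never as silently
wrong numbers. The 1:1 special case has a closed-form solution (the smaller
root of c² − (CD_tot + G_tot + 1/K)c + CD_tot·G_tot = 0, evaluated in the
cancellation-free form 2·CD_tot·G_tot/(b + √(b²−4·CD_tot·G_tot))), which the
test suite uses as an independent oracle for the general solver.

## Estimating binding constants

### Benesi–Hildebrand (BH)

The saturation enhancement law I = I₀(1 + A·K[CD]ⁿ/(1 + K[CD]ⁿ))
linearizes to I₀/(I−I₀) = 1/A + 1/(A·K·[CD]ⁿ). The zero-host point defines
I₀ and is excluded from the regression (its transform is undefined); points
with I ≤ I₀ are dropped and counted. The regression is unweighted
y-on-x OLS — the convention of the graphical method — with K =
intercept/slope, A = 1/intercept, and Var(log₁₀K) by the delta method from
the OLS covariance. A non-positive intercept or slope is reported as a
flagged "no saturable binding" failure: this occurs legitimately for weak
binders under noise, because the transform amplifies noise at small
(I − I₀) and the small intercept (1/A) can be pushed negative (the weakest
bundled reference complex, β-zearalenol–QABCD at log K 2.64, does this at
0.5% noise).

### Global speciation fit

The observation model is linear in species concentrations:
I_j = ε_free[G]_free,j + Σ ε_pq·q·[CD_pG_q]_j. For fixed log β the optimal
emissivities solve a linear least-squares problem, so they are profiled out
(variable projection) and the nonlinear search runs over log β only,
bounded to [−2, 12], restarted from log β ∈ {2, 3, 4, 5} (staggered upward
for multi-species models, since overall constants grow with complex order).
Standard errors come from σ²(JᵀJ)⁻¹ with J the Jacobian of the profiled
residual at the optimum and σ² = SSR/(n − m), m counting both β's and
emissivities. Estimates within 1e−6 of a bound are flagged.

The residual SD reported and used for model comparison is the
degrees-of-freedom-corrected √(SSR/(n−m)); an uncorrected sample SD would
always favor the richer model. Ties within 1e−12 break toward fewer free
parameters. Model selection additionally requires physical admissibility:
fitted emissivities are photon yields and may not be materially negative
(tolerance 1% of the largest, allowing noise around a true zero). Without
this constraint a 1:2 or 2:1 candidate absorbs noise via a negative-ε
pseudo-species often enough to corrupt selection on single titrations.
Even with it, stoichiometry selection from one 11-point titration at 0.5%
noise misidentifies occasionally (~10–25% of random replicates); reliable
selection needs lower noise, replicate titrations, or joint fits — a known
limitation of lowest-residual selection, not of the implementation.

### Why both estimators

BH assumes free host ≈ total host. With 2 µM guest against a 20 µM lowest
host point, up to ~10% of the host is sequestered for strong binders, and
the BH constant biases low; the exact-speciation fit does not. The bias
sweep (analysis/05) quantifies this: at guest/min-host ratios 0.01, 0.1,
0.5, 1.0 and true log K = 4.89, BH recovers 4.887, 4.863, 4.752, 4.613
while the global fit recovers 4.890 at every ratio. The two estimators
agree to < 0.02 log-units only where depletion is jointly negligible in K
and the guest/host ratio (ratio 0.1 suffices for log K ≤ 4.5; the
strongest complexes need ratio ≲ 0.02). This also explains why globally
fitted constants sit systematically a little above BH constants for the
same system.

## Synthetic data

No instrument data are available numerically, so generators reproduce the
study conditions: guest total 2 µM on the 11-point host grid 0, 0.02, 0.05,
0.07, 0.10, 0.20, 0.50, 0.70, 1.0, 1.5, 2.0 mM. Two generators exist — the
saturation law (exactly the BH model, used to validate the BH fitter
against its own assumptions) and the speciation generator (exact mass
action plus the linear emissivity model, the ground truth for the global
fitter and for BH-bias studies). Noise is additive Gaussian with SD
relative to the noise-free intensity, seeded via `numpy` Generator for
reproducibility. The default relative SD of 0.005 makes recovered log K
standard errors the order of the ±0.01–0.09 dispersions quoted with the
reference constants; whether those published ± values are fit SEs or
replicate SDs is unknown, so no replicate structure is emulated. The
emissivities of the reference experiments (5e7 free, 3.5e8 complexed
a.u. per mol/dm³) give a baseline of 100 a.u. and an enhancement plateau
of 7, typical of the measured enhancement bars.

Not simulated: full emission spectra (the wavelength axis), inner-filter
effects, photobleaching, buffer-specific quenching. Passing recovery tests
therefore demonstrates correctness of the estimation chain under its own
assumptions, not robustness to those instrument artifacts.

pH series use the two-state Henderson–Hasselbalch model on the grid
pH 4.0–10.0 in 0.5 steps, which brackets both reference acidity constants
(6.2 and 7.8). The original pKa procedure (molar coefficients from
excitation spectra near the estimated pKa) is not reconstructible from the
published text, so the standard single-wavelength two-state fit is
implemented instead; on two-state data this recovers the generating pKa
exactly. The apparent-pKa shift under complexation,
pKa′ = pKa + log₁₀(1 + K[CD]_free), is an interpretive model assuming only
the neutral guest binds — the direction matches the observed
CD-induced shift toward the non-ionized form at alkaline pH, but the
coupled equilibrium was never fit in the source system.

## Thermodynamics

Vibrational entropy uses the harmonic-oscillator partition function,
S_vib = R·Σ[x/(eˣ−1) − ln(1−e⁻ˣ)], x = hν/kT, with CODATA constants from
`scipy.constants` and wavenumber→Hz conversion via c. Each term is
nonnegative, decreases monotonically with frequency and vanishes in the
high-frequency limit; zero or negative frequencies are rejected (divergent
term). The module default temperature is 298.16 K — the value the bundled
tables were computed at (nonstandard relative to 298.15 K; the 0.01 K
difference is far below the consistency tolerance). ΔG = ΔH − TΔS performs
the single kJ/J unit bridge; van't Hoff gives log₁₀K = −ΔG/(ln10·R·T).

The consistency checker recomputes ΔG for every bundled record and flags
residuals beyond a tolerance (default 0.15 kJ/mol, absorbing the one-decimal
rounding of the tabulated ΔH and ΔS). All 12 bundled rows pass; the largest
residual is 0.087 kJ/mol (α-zearalenol–DIMEB, hydrated-guest hypothesis).
The enthalpy–entropy compensation bookkeeping checks that the two solvation
hypotheses — guest dehydrated before inclusion (entropy-driven) versus
entering hydrated (enthalpy-driven) — yield the same ΔG within 2.2 kJ/mol
per host–guest pair; the worst bundled pair differs by 1.80 kJ/mol.
Activation-energy records are carried verbatim for reporting; no kinetic
model is fit to them, and their negative values are stored uninterpreted.

## Problem sizes

All experiments are desk-scale: titrations are 11 points, pH series 13
points, replicate studies use 200 seeded replicates, and the full test
suite plus the acceptance recomputation run in well under a minute.

## Known limitations

- The speciation observation model ties each complex's contribution to
  q·[complex]; per-wavelength or multi-response fitting is not supported.
- Stoichiometry selection from a single titration is noise-fragile (above).
- The BH and global estimators share the synthetic generators' assumptions.
  Both default to unweighted regression (the convention of the original
  analyses); per-point inverse-variance weights are accepted but no
  automatic variance model is estimated from the data.
- Uncertainties are asymptotic (OLS covariance, profiled-Jacobian); no
  bootstrap or Bayesian intervals.
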