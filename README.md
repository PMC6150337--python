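# hostguest-titrate

Analysis toolkit for fluorescence titrations of cyclodextrin host–guest
inclusion complexes, built around the zearalenol–β-cyclodextrin system.
Zearalenone (ZEN) and its reduced metabolites α- and β-zearalenol (ZOL) are
estrogenic *Fusarium* mycotoxins whose fluorescence is strongly enhanced
when the guest enters the hydrophobic cyclodextrin cavity and sheds part of
its hydration shell. That enhancement, recorded against increasing host
concentration, carries the association constant of the complex — and this
package implements the full quantitative chain that extracts it.

For whom: spectroscopists and cheminformaticians estimating binding
constants from saturation-type titrations, and anyone who needs a tested
mass-action speciation solver with fitting machinery around it.

## What it computes

**Equilibrium speciation.** For complexes CD<sub>p</sub>G<sub>q</sub> with
overall constants β<sub>pq</sub> = [CD<sub>p</sub>G<sub>q</sub>] /
([CD]<sup>p</sup>[G]<sup>q</sup>), the solver finds free concentrations
satisfying both mass balances to a relative residual ≤ 1e−12 (damped Newton
in log space; the 1:1 case is cross-checked against the closed-form binding
quadratic).

**Benesi–Hildebrand estimation.** The double-reciprocal linearization

  I₀/(I − I₀) = 1/A + 1/(A·K·[CD]ⁿ)

is fit by OLS; K = intercept/slope, enhancement amplitude A = 1/intercept,
with the SE of log₁₀K by error propagation.

**Global speciation fitting.** Nonlinear least squares of log β through the
exact speciation model, with per-species emissivities profiled out linearly
at every step (variable projection) and multi-start initialization.
Stoichiometry is selected among candidate models (1:1, 1:2, 2:1, …) by the
lowest degrees-of-freedom-corrected residual SD, restricted to physically
admissible fits (nonnegative emissivities).

**Ionization.** Two-state spectrophotometric pKa fits,
I(pH) = f·I_ion + (1−f)·I_neutral with Henderson–Hasselbalch f, plus the
apparent-pKa shift pKa′ = pKa + log₁₀(1 + K[CD]) induced by a host that
binds only the neutral guest.

**Thermodynamics.** Harmonic vibrational entropy from normal-mode
wavenumbers, ΔG = ΔH − TΔS at 298.16 K, van't Hoff conversion of ΔG to
log₁₀K, and a consistency checker for tabulated (ΔH, ΔS, ΔG) records.

Because the original instrument data exist only as figures, the package
ships seeded synthetic-data generators with exactly the statistical
structure the estimators assume, and the bundled reference constants are
reproduced as parameter-recovery experiments: generate with the published
value as truth, refit, recover.

## Worked example

```python
from hostguest_titrate import (
    BindingModel, TitrationSimSpec, bh_fit,
    generate_titration_speciation, global_fit,
)

# a noisy 1:1 titration at the study conditions: 2 uM guest,
# 0-2.0 mM host grid, true log K = 4.02, 0.5% relative noise
series = generate_titration_speciation(
    TitrationSimSpec(model=BindingModel.one_to_one(4.02),
                     noise_sd_rel=0.005, seed=1),
    {"free": 5e7, (1, 1): 3.5e8},   # a.u. per mol/dm^3 of guest
)
res = global_fit(series, BindingModel.one_to_one(3.0))
print(f"log K = {res.log_k:.3f} +/- {res.se_log[(1, 1)]:.3f}")
print(f"residual SD = {res.residual_sd:.2f} a.u.")
```

prints

```
log K = 4.019 +/- 0.004
residual SD = 1.45 a.u.
```

i.e. the generating constant (4.02) is recovered well inside one standard
error, and the residual SD matches the injected noise level (~0.5% of a
~300 a.u. signal). The same workflow is available from the shell:

```sh
hostguest-titrate simulate --log-k 4.89 --amplitude 7 --i0 100 --seed 1 --out t.csv
hostguest-titrate fit-bh t.csv
hostguest-titrate thermo-check --tol 0.15
hostguest-titrate reproduce --seed 1 --out reproduction.json
```

The numbered drivers under `analysis/` run the full study: simulate the
titration library (01), refit it by both estimators (02), recover the pKa
values (03), check the thermodynamic tables and the enthalpy–entropy
compensation (04), and sweep the Benesi–Hildebrand depletion bias (05).
Each writes its table under `results/`.

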