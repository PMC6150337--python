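"""Bundled literature reference values for zearalenol-cyclodextrin complexes.

Four small tables ship with the package: decimal log binding constants from
Benesi-Hildebrand analysis and from global nonlinear fitting, complexation
thermodynamics (dH, dS, dG at 298.16 K) under the two solvation hypotheses
(guest dehydrated before inclusion vs. entering hydrated), and
transition-state activation energies.  They serve as generating truths for
the parameter-recovery experiments and as fixtures for the dG consistency
checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .thermo import T_DEFAULT, ThermoRecord

__all__ = [
    "load_bh_log_k",
    "load_global_log_k",
    "load_thermo_records",
    "load_activation_energies",
    "reference_log_k",
]

_HYPOTHESIS_FILES = {
    "dehydrated-guest": "thermo_dehydrated_guest.csv",
    "hydrated-guest": "thermo_hydrated_guest.csv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("hostguest_titrate.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_bh_log_k() -> pd.DataFrame:
    """log10 K of ZOL/ZEN-CD complexes from Benesi-Hildebrand analysis."""
    return _read("bh_log_k.csv")


def load_global_log_k() -> pd.DataFrame:
    """log10 beta of ZOL-CD complexes from global nonlinear fitting."""
    return _read("global_log_k.csv")


def reference_log_k(guest: str, host: str, method: str = "bh") -> float:
    """Look up one reference constant, e.g. ``reference_log_k("alpha-ZOL", "DIMEB")``."""
    df = load_bh_log_k() if method == "bh" else load_global_log_k()
    col = "log_k" if method == "bh" else "log_beta"
    row = df[(df.guest == guest) & (df.host == host)]
    if row.empty:
        raise KeyError(f"no reference value for {guest}-{host} ({method})")
    return float(row[col].iloc[0])


def load_thermo_records(hypothesis: str) -> list[ThermoRecord]:
    """Thermodynamic records under one solvation hypothesis.

    ``hypothesis`` is ``"dehydrated-guest"`` (guest sheds its hydration
    shell before inclusion) or ``"hydrated-guest"`` (it does not).
    """
    if hypothesis not in _HYPOTHESIS_FILES:
        raise KeyError(f"unknown solvation hypothesis {hypothesis!r}")
    df = _read(_HYPOTHESIS_FILES[hypothesis])
    return [
        ThermoRecord(
            host=r.host,
            guest=r.guest,
            dh=r.dh_kJ_mol,
            ds=r.ds_J_Kmol,
            dg=r.dg_kJ_mol,
            temperature=T_DEFAULT,
            solvation_hypothesis=hypothesis,
        )
        for r in df.itertuples()
    ]


def load_activation_energies() -> pd.DataFrame:
    """Pass-through activation-energy records (kJ/mol); no kinetic model is fit."""
    return _read("activation_energies.csv")
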