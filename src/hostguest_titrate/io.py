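"""File formats: titration and pH-series CSV dialects, thermo tables, results.

Titration CSV: ``#``-prefixed ``key: value`` header comments carry series
metadata (guest total in uM, buffer pH, wavelengths), followed by a header
row and the two mandatory columns ``host_total_mM`` and ``intensity``.
Concentrations are converted to mol/dm^3 on read.  Numeric locale is fixed
to the decimal point and U+2212 minus signs are normalized to ASCII.

Result documents are versioned JSON ("schema": "hostguest-titrate/1") that
round-trip losslessly apart from the timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .core import TitrationSeries
from .simulate import PhSeries
from .thermo import T_DEFAULT, ThermoRecord

__all__ = [
    "SchemaError",
    "read_titration_csv",
    "write_titration_csv",
    "read_ph_csv",
    "write_ph_csv",
    "read_thermo_csv",
    "ResultDocument",
]

SCHEMA = "hostguest-titrate/1"

_KNOWN_HEADER_KEYS = {"guest_total_uM", "ph", "excitation_nm", "emission_nm"}


class SchemaError(ValueError):
    """Input file does not match the expected CSV schema."""


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-")


def _read_commented_csv(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    path = Path(path)
    header: dict[str, str] = {}
    body_lines: list[str] = []
    for line in _normalize_minus(path.read_text()).splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                header[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise SchemaError(f"{path}: no data rows")
    from io import StringIO

    return header, pd.read_csv(StringIO("\n".join(body_lines)))


def read_titration_csv(path: str | Path, *, sort: bool = False) -> TitrationSeries:
    """Read one titration series; raises :class:`SchemaError` on bad files."""
    header, df = _read_commented_csv(path)
    for col in ("host_total_mM", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column '{col}'")
    if sort:
        df = df.sort_values("host_total_mM")
    host = df["host_total_mM"].to_numpy(dtype=float)
    if len(host) > 1 and not all(b > a for a, b in zip(host, host[1:])):
        raise SchemaError(
            f"{path}: host grid is not strictly increasing; pass sort=True "
            "(CLI: --sort) if row order is the problem"
        )
    guest_um = float(header.get("guest_total_uM", "nan"))
    if math.isnan(guest_um):
        raise SchemaError(f"{path}: header comment '# guest_total_uM: <value>' is required")
    series = TitrationSeries(
        guest_total=guest_um * 1e-6,
        host_totals=tuple(c * 1e-3 for c in host),
        intensities=tuple(df["intensity"].to_numpy(dtype=float)),
        ph=float(header["ph"]) if "ph" in header else None,
        excitation_nm=float(header["excitation_nm"]) if "excitation_nm" in header else None,
        emission_nm=float(header["emission_nm"]) if "emission_nm" in header else None,
        metadata={k: v for k, v in header.items() if k not in _KNOWN_HEADER_KEYS},
    )
    return series


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# guest_total_uM: {series.guest_total * 1e6:.10g}"]
    if series.ph is not None:
        lines.append(f"# ph: {series.ph:.10g}")
    if series.excitation_nm is not None:
        lines.append(f"# excitation_nm: {series.excitation_nm:.10g}")
    if series.emission_nm is not None:
        lines.append(f"# emission_nm: {series.emission_nm:.10g}")
    for key, value in series.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("host_total_mM,intensity")
    for host, intens in zip(series.host_totals, series.intensities):
        lines.append(f"{float(host) * 1e3:.10g},{float(intens)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_ph_csv(path: str | Path) -> PhSeries:
    header, df = _read_commented_csv(path)
    for col in ("ph", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column '{col}'")
    return PhSeries(
        ph_values=tuple(df["ph"].to_numpy(dtype=float)),
        intensities=tuple(df["intensity"].to_numpy(dtype=float)),
        wavelength_nm=float(header["wavelength_nm"]) if "wavelength_nm" in header else None,
        metadata={k: v for k, v in header.items() if k != "wavelength_nm"},
    )


def write_ph_csv(series: PhSeries, path: str | Path) -> None:
    path = Path(path)
    lines = []
    if series.wavelength_nm is not None:
        lines.append(f"# wavelength_nm: {series.wavelength_nm:.10g}")
    for key, value in series.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("ph,intensity")
    for ph, intens in zip(series.ph_values, series.intensities):
        lines.append(f"{float(ph)!r},{float(intens)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_thermo_csv(path: str | Path, solvation_hypothesis: str = "") -> list[ThermoRecord]:
    """Thermo table CSV: guest, host, dh_kJ_mol, ds_J_Kmol and optional dg_kJ_mol."""
    _, df = _read_commented_csv(path)
    for col in ("guest", "host", "dh_kJ_mol", "ds_J_Kmol"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column '{col}'")
    records = []
    for r in df.itertuples():
        dg = getattr(r, "dg_kJ_mol", None)
        records.append(
            ThermoRecord(
                host=str(r.host),
                guest=str(r.guest),
                dh=float(r.dh_kJ_mol),
                ds=float(r.ds_J_Kmol),
                dg=None if dg is None or (isinstance(dg, float) and math.isnan(dg)) else float(dg),
                temperature=float(getattr(r, "temperature_K", T_DEFAULT)),
                solvation_hypothesis=solvation_hypothesis,
            )
        )
    return records


def _jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, tuple keys) to JSON-safe form."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {
            (",".join(map(str, k)) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


@dataclasses.dataclass
class ResultDocument:
    """Versioned JSON container for fit results, configuration and provenance."""

    results: dict[str, Any]
    seed: int | None = None
    config: dict[str, Any] = dataclasses.field(default_factory=dict)
    inputs: list[str] = dataclasses.field(default_factory=list)
    tool_version: str = ""
    timestamp: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema": SCHEMA,
            "tool_version": self.tool_version,
            "seed": self.seed,
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
            "config": _jsonable(self.config),
            "inputs": list(self.inputs),
            "results": _jsonable(self.results),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ResultDocument":
        data = json.loads(Path(path).read_text())
        if data.get("schema") != SCHEMA:
            raise SchemaError(f"{path}: unexpected schema {data.get('schema')!r}")
        return cls(
            results=data["results"],
            seed=data["seed"],
            config=data["config"],
            inputs=data["inputs"],
            tool_version=data["tool_version"],
            timestamp=data["timestamp"],
        )
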