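"""Readers/writers for the delimited curve formats and the registries.

All curve files are plain tab/whitespace-delimited text with a ``#``
metadata header.  Every file declares its ``kind`` and its units; readers
convert to internal SI on load and writers emit the customary units
(Angstrom^2, mN/m, mV, mol/kg), so a write-read round trip is exact to
float formatting.

Example isotherm file::

    # kind: isotherm
    # surfactant: OA
    # C_m: 1.0 mol/kg
    # T: 293.15 K
    # columns: S[A^2] pi[mN/m]
    46.0    1.23
    ...

The ion, electrolyte and surfactant registries are YAML files; a small
default registry ships with the package (crystallographic radii and
headgroup volumes are data, not code, and are meant to be edited).
"""

from __future__ import annotations

import importlib.resources
import warnings
from decimal import Decimal
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .bulk import ElectrolyteSpec, IonSpec, PropertyTable
from .constants import ANGSTROM, T_DEFAULT
from .isotherm import IsothermCurve, SpreadingSeries
from .planes import SurfactantSpec
from .volta import VoltaCurve

__all__ = [
    "read_curve_file",
    "write_curve_file",
    "read_property_table",
    "load_ion_registry",
    "load_surfactant_registry",
    "load_electrolyte",
]

#: Electrolytes that hydrolyze on an acidified subphase; their analysis on
#: acid would charge the monolayer, which is outside this package's scope.
HYDROLYZING_ON_ACID = {"KSCN", "Na2SO4", "MgSO4"}

_KINDS = ("isotherm", "volta", "spreading")


class CurveFormatError(ValueError):
    pass


def _parse_header(lines: list[str], path: str) -> dict:
    meta: dict[str, str] = {}
    for i, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip().lower()] = val.strip()
    if "kind" not in meta:
        raise CurveFormatError(f"{path}: missing '# kind:' header")
    if "columns" not in meta:
        raise CurveFormatError(f"{path}: missing '# columns:' header "
                               "(units must be declared)")
    return meta


def _read_rows(lines: list[str], path: str, ncols: int) -> list[list[str]]:
    """Validated data tokens (floats), kept as strings so unit conversion
    can be done in one correctly-rounded decimal step."""
    rows = []
    for i, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        if len(parts) != ncols:
            raise CurveFormatError(
                f"{path}, line {i}: expected {ncols} columns, got "
                f"{len(parts)}: {s!r}")
        try:
            for p_ in parts:
                float(p_)
        except ValueError as exc:
            raise CurveFormatError(f"{path}, line {i}: {exc}") from None
        rows.append(parts)
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    return rows


def _col(rows: list[list[str]], i: int, shift: int = 0) -> np.ndarray:
    """Column ``i`` converted to SI by a power-of-ten shift.

    The shift is applied to the exact decimal token, so the only rounding
    is the final (correctly rounded) decimal-to-binary conversion; written
    files therefore round-trip bit-exactly.
    """
    return np.array([float(Decimal(r[i]).scaleb(-shift)) for r in rows])


def _maybe_warn_hydrolyzing(meta: dict) -> None:
    el = meta.get("electrolyte", "")
    subphase = meta.get("subphase", "")
    if el in HYDROLYZING_ON_ACID and "hcl" in subphase.lower():
        warnings.warn(
            f"{el} hydrolyzes on an acidified subphase; at high "
            "concentration it raises the pH, dissociates the acid "
            "monolayer and charges it — excluded from this analysis",
            stacklevel=3)


def read_curve_file(path: Union[str, Path], kind: Optional[str] = None):
    """Read an isotherm, Volta or spreading-pressure file.

    Returns :class:`IsothermCurve`, :class:`VoltaCurve` or
    :class:`SpreadingSeries` according to the file's declared kind
    (``kind`` argument, if given, must match).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _parse_header(lines, str(path))
    file_kind = meta["kind"]
    if file_kind not in _KINDS:
        raise CurveFormatError(f"{path}: unknown kind {file_kind!r}")
    if kind is not None and kind != file_kind:
        raise CurveFormatError(
            f"{path}: declared kind {file_kind!r} != requested {kind!r}")
    _maybe_warn_hydrolyzing(meta)
    cols = meta["columns"].split()
    rows = _read_rows(lines, str(path), len(cols))
    T = float(meta.get("t", str(T_DEFAULT)).split()[0])
    surfactant = meta.get("surfactant", "unknown")
    if file_kind == "isotherm":
        _expect_columns(cols, ["S[A^2]", "pi[mN/m]"], path)
        C_m = float(meta["c_m"].split()[0])
        return IsothermCurve(surfactant=surfactant, C_m=C_m,
                             S=_col(rows, 0, 20),
                             pi=_col(rows, 1, 3), T=T)
    if file_kind == "volta":
        _expect_columns(cols, ["S[A^2]", "dV[mV]"], path)
        C_m = float(meta["c_m"].split()[0])
        repro = float(meta.get("reproducibility", "10 mV").split()[0]) * 1e-3
        return VoltaCurve(surfactant=surfactant, C_m=C_m,
                          S=_col(rows, 0, 20), dV=_col(rows, 1, 3),
                          reproducibility=repro)
    _expect_columns(cols, ["C_m[mol/kg]", "pi_sp[mN/m]"], path)
    return SpreadingSeries(surfactant=surfactant, C_m=_col(rows, 0),
                           pi_sp=_col(rows, 1, 3))


def _expect_columns(cols: list[str], expected: list[str], path) -> None:
    if cols != expected:
        raise CurveFormatError(
            f"{path}: columns must be {' '.join(expected)!r} "
            f"(units are mandatory), got {' '.join(cols)!r}")


def _fmt(v_SI: float, shift: int = 0) -> str:
    """Display-unit decimal of an SI value, exact under read-back.

    The power-of-ten unit shift is performed on the shortest decimal
    representation (exactly, via :class:`decimal.Decimal`), so the reader's
    single decimal-to-binary conversion recovers the stored double bit for
    bit.
    """
    return format(Decimal(repr(float(v_SI))).scaleb(shift), "f")


def write_curve_file(obj, path: Union[str, Path], *,
                     extra_meta: Optional[dict] = None) -> None:
    """Write a curve object in the same format :func:`read_curve_file`
    consumes (bit-exact round trip)."""
    path = Path(path)
    lines = []
    meta = dict(extra_meta or {})
    if isinstance(obj, IsothermCurve):
        meta.update(kind="isotherm", surfactant=obj.surfactant,
                    C_m=f"{obj.C_m!r} mol/kg", T=f"{obj.T!r} K",
                    columns="S[A^2] pi[mN/m]")
        body = [f"{_fmt(s, 20)}\t{_fmt(p, 3)}"
                for s, p in zip(obj.S, obj.pi)]
    elif isinstance(obj, VoltaCurve):
        meta.update(kind="volta", surfactant=obj.surfactant,
                    C_m=f"{obj.C_m!r} mol/kg",
                    reproducibility=f"{obj.reproducibility * 1e3!r} mV",
                    columns="S[A^2] dV[mV]")
        body = [f"{_fmt(s, 20)}\t{_fmt(v, 3)}"
                for s, v in zip(obj.S, obj.dV)]
    elif isinstance(obj, SpreadingSeries):
        meta.update(kind="spreading", surfactant=obj.surfactant,
                    columns="C_m[mol/kg] pi_sp[mN/m]")
        body = [f"{_fmt(c)}\t{_fmt(p, 3)}"
                for c, p in zip(obj.C_m, obj.pi_sp)]
    else:
        raise TypeError(f"cannot write {type(obj).__name__}")
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    lines.extend(body)
    path.write_text("\n".join(lines) + "\n")


def read_property_table(path: Union[str, Path], *, name: str = "",
                        extrapolate: bool = False) -> PropertyTable:
    """Two-column (C_m, value) delimited table with '#' comments."""
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = _read_rows(lines, str(path), 2)
    return PropertyTable(_col(rows, 0), _col(rows, 1),
                         name=name or path.stem, extrapolate=extrapolate)


# ---------------------------------------------------------------------------
# registries

def _default_registry_path(fname: str) -> Path:
    return Path(importlib.resources.files("monoion") / "data" / fname)


def load_ion_registry(path: Optional[Union[str, Path]] = None
                      ) -> dict[str, IonSpec]:
    """Ion registry: name -> IonSpec.  Radii are stored in Angstrom."""
    path = Path(path) if path else _default_registry_path("ions.yaml")
    raw = yaml.safe_load(path.read_text())
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sticky-ion warnings at load time
        for name, d in raw.items():
            out[name] = IonSpec(name=name, z=int(d["z"]),
                                R0=float(d["R0_A"]) * ANGSTROM,
                                role=d["role"])
    return out


def load_surfactant_registry(path: Optional[Union[str, Path]] = None
                             ) -> dict[str, SurfactantSpec]:
    path = Path(path) if path else _default_registry_path("surfactants.yaml")
    raw = yaml.safe_load(path.read_text())
    out = {}
    for name, d in raw.items():
        bounds = tuple(float(v) * 1e-6 for v in d["V_s_mL_per_mol"])
        out[name] = SurfactantSpec(
            name=name, headgroup=d["headgroup"], V_s_bounds=bounds,
            collapse_area=float(d["collapse_area_A2"]) * ANGSTROM**2)
    return out


def load_electrolyte(name: str,
                     registry_path: Optional[Union[str, Path]] = None,
                     ions: Optional[dict[str, IonSpec]] = None
                     ) -> ElectrolyteSpec:
    """Build an :class:`ElectrolyteSpec` from the electrolyte registry.

    Property tables referenced by relative path are resolved against the
    registry file's directory (or the packaged data directory).
    """
    reg_path = (Path(registry_path) if registry_path
                else _default_registry_path("electrolytes.yaml"))
    raw = yaml.safe_load(reg_path.read_text())
    if name not in raw:
        raise KeyError(f"electrolyte {name!r} not in registry "
                       f"({sorted(raw)})")
    d = raw[name]
    ions = ions or load_ion_registry()
    base = reg_path.parent

    def table(key: str) -> Optional[PropertyTable]:
        if key not in d:
            return None
        return read_property_table(base / d[key], name=f"{name}:{key}")

    rho0 = float(d.get("density_intercept", 998.2))
    rho_slope = float(d.get("density_slope", 0.0))
    return ElectrolyteSpec(
        name=name,
        cation=ions[d["cation"]], anion=ions[d["anion"]],
        nu_plus=int(d["nu_plus"]), nu_minus=int(d["nu_minus"]),
        V_el=float(d.get("V_el_mL_per_mol", 0.0)) * 1e-6,
        molar_mass=float(d.get("molar_mass_g_per_mol", 0.0)) * 1e-3,
        activity_table=table("activity_table"),
        density_model=(lambda C_m, a=rho0, b=rho_slope: a + b * C_m),
        eps_table=table("eps_table"),
        chi_table=table("chi_table"),
    )
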