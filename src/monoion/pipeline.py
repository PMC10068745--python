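"""Configured end-to-end analysis runs with an auditable log.

The quantities this package extracts are small slopes estimated from
sparse historical data, so every numerical decision taken during a run —
plateau points projected, tail points used for the spreading-area
extrapolation, clipped chemical-potential ranges, route discrepancies —
is written to a plain-text run log next to the delimited result tables.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as mio
from .bulk import solution_state
from .constants import AVOGADRO, LQ_RATIO_DEFAULT, CHI0_DEFAULT
from .isotherm import (
    build_field,
    induced_adsorption_isobaric,
    induced_adsorption_isochemical,
    induced_adsorption_spread,
    route_consistency,
)
from .planes import eps_plane_band
from .volta import phi_dl_assuming_fixed_Ps, ps_assuming_ms_phi

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Loaded from YAML via :meth:`from_yaml`; every referenced file must
    exist at load time.  Options mirror the library defaults.
    """

    outdir: Path
    electrolyte: str
    isotherm_files: Sequence[Path] = ()
    spreading_file: Optional[Path] = None
    volta_files: Sequence[Path] = ()
    surfactant: Optional[str] = None
    route: str = "both"             # "A" | "B" | "both"
    k_points: int = 3
    plateau_correction: bool = True
    C_target: Optional[float] = None
    Lq_ratio: float = LQ_RATIO_DEFAULT
    chi0: float = CHI0_DEFAULT
    volta_mode: str = "fixed-ps"    # "fixed-ps" | "fixed-phidl"
    seed: int = 0
    registry_path: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return (base / p).resolve()

        cfg = cls(
            outdir=resolve(raw["outdir"]),
            electrolyte=raw["electrolyte"],
            isotherm_files=[resolve(p) for p in raw.get("isotherms", [])],
            spreading_file=(resolve(raw["spreading"])
                            if "spreading" in raw else None),
            volta_files=[resolve(p) for p in raw.get("volta", [])],
            surfactant=raw.get("surfactant"),
            **raw.get("options", {}),
        )
        for f in [*cfg.isotherm_files, *cfg.volta_files,
                  *( [cfg.spreading_file] if cfg.spreading_file else [])]:
            if not Path(f).exists():
                raise FileNotFoundError(f"configured input missing: {f}")
        return cfg

    def digest(self) -> str:
        blob = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(path: Path, header: str, columns: dict) -> None:
    keys = list(columns)
    arr = np.column_stack([np.asarray(columns[k], float) for k in keys])
    lines = [f"# {header}", "# " + "\t".join(keys)]
    lines += ["\t".join(repr(float(v)) for v in row) for row in arr]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the result bundle.

    Stages: bulk (always) -> isotherm inversion (if isotherm files given)
    -> dividing-plane conversion -> Volta decomposition (if Volta files
    given).  Outputs are deterministic for a fixed config and seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    logger = logging.getLogger("monoion.run")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("monoion")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        logger.info("config digest %s, seed %d", config.digest(), config.seed)
        try:
            spec = mio.load_electrolyte(config.electrolyte,
                                        registry_path=config.registry_path)
        except KeyError:
            raise ValueError(f"stage bulk: unknown electrolyte "
                             f"{config.electrolyte!r}") from None
        results["electrolyte"] = spec

        if config.isotherm_files:
            if config.spreading_file is None:
                raise ValueError("stage isotherm: spreading-pressure file "
                                 "required alongside isotherms")
            curves = [mio.read_curve_file(f, "isotherm")
                      for f in config.isotherm_files]
            series = mio.read_curve_file(config.spreading_file, "spreading")
            field = build_field(
                curves, series, spec, k_points=config.k_points,
                apply_plateau_correction=config.plateau_correction)
            results["field"] = field
            star = induced_adsorption_spread(series, spec)
            results["spread_state"] = star
            logger.info("spread-state slope d(pi_sp)/d(p_osm) = %.4g m",
                        star.slope)
            profiles = {}
            if config.route in ("A", "both"):
                profiles["A"] = induced_adsorption_isochemical(
                    field, C_target=config.C_target)
            if config.route in ("B", "both"):
                profiles["B"] = induced_adsorption_isobaric(
                    field, C_target=config.C_target)
            results["profiles"] = profiles
            if len(profiles) == 2:
                disc = route_consistency(profiles["A"], profiles["B"])
                results["discrepancy"] = disc
                logger.info("route discrepancy: max %.2f%%, mean %.2f%%%s",
                            100 * disc.max_rel, 100 * disc.mean_rel,
                            " (FLAGGED >10%)" if disc.flagged else "")
            for key, prof in profiles.items():
                _write_table(
                    out / f"adsorption_route{key}.tsv",
                    f"route {prof.route}, C_m={prof.C_m} mol/kg; "
                    "Gamma_s and DGamma_el in nm^-2",
                    {"Gamma_s[nm^-2]": prof.Gamma_s_nm2,
                     "dGamma_el[nm^-2]": prof.dGamma_el_nm2})
            _write_table(
                out / "spread_state.tsv",
                f"spread-monolayer DGamma_el, slope={star.slope!r} m",
                {"C_m[mol/kg]": star.C_m,
                 "dGamma_el[nm^-2]": star.dGamma_el_nm2})
            if config.surfactant is not None and profiles:
                surf = mio.load_surfactant_registry()[config.surfactant]
                prof = profiles.get("A") or profiles.get("B")
                state = solution_state(spec, prof.C_m)
                band = eps_plane_band(prof, surf, spec, state)
                results["eps_band"] = band
                _write_table(
                    out / "adsorption_eps_plane.tsv",
                    f"DGamma_el^eps band, V_s bounds "
                    f"{surf.V_s_bounds} m^3/mol",
                    {"Gamma_s[nm^-2]": band.Gamma_s * AVOGADRO / 1e18,
                     "low[nm^-2]": band.low * AVOGADRO / 1e18,
                     "central[nm^-2]": band.central * AVOGADRO / 1e18,
                     "high[nm^-2]": band.high * AVOGADRO / 1e18})

        if config.volta_files:
            if spec.chi_table is None:
                raise ValueError(
                    f"stage volta: electrolyte {spec.name!r} has no "
                    "Dchi(C) table; the decomposition is impossible")
            vcurves = [mio.read_curve_file(f, "volta")
                       for f in config.volta_files]
            water = [c for c in vcurves if c.C_m == 0.0]
            if not water:
                raise ValueError("stage volta: need the C_m = 0 curve")
            curve0 = water[0]
            volta_out = []
            for c in vcurves:
                if c.C_m == 0.0:
                    continue
                state = solution_state(spec, c.C_m)
                if config.volta_mode == "fixed-ps":
                    res = phi_dl_assuming_fixed_Ps(
                        c, curve0, spec, state, config.Lq_ratio,
                        chi0=config.chi0)
                    col, unit = "phi_DL[mV]", 1e3
                else:
                    res = ps_assuming_ms_phi(
                        c, curve0, spec, state, config.Lq_ratio,
                        chi0=config.chi0)
                    col, unit = "Ps_per_molecule[D]", 1.0
                volta_out.append((c.C_m, res))
                _write_table(
                    out / f"volta_{config.volta_mode}_C{c.C_m:g}.tsv",
                    f"{res.assumption}; Lq_ratio={config.Lq_ratio}, "
                    f"chi0={config.chi0 * 1e3:g} mV",
                    {"S[A^2]": res.S / 1e-20,
                     col: res.values * unit,
                     "uncertainty": res.uncertainty * unit})
            results["volta"] = volta_out
        logger.info("run complete")
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
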