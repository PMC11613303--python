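"""Run configuration: TOML schema, validation, and community assembly.

A :class:`RunConfig` fully specifies a study: grid, forcing scenario preset
(with optional overrides), species parameters with calibration targets,
simulation horizon and seed, and the analysis options of the TPC pipeline.
``load_config`` parses and validates a TOML file (collecting all problems in
one error), ``dump_config`` writes an equivalent file back, and
``assemble_community`` turns the configuration into the concrete objects a
run needs: the grid, the generated climatology, and the calibrated species
list with resolved satiety thresholds.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .bioenergetics import SpeciesParams, calibrate_thermal_params
from .forcing import (
    ForcingClimatology,
    Grid,
    PRESET_NAMES,
    generate_forcing,
    make_grid,
    make_scenario,
)
from .simulation import _ltl_access_coeffs, resolve_satiety_biomass

__all__ = [
    "ConfigError",
    "RunConfig",
    "SpeciesConfig",
    "assemble_community",
    "demo_config_path",
    "dump_config",
    "no_limitation_variant",
    "load_config",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration parse/validation failure; message lists all problems."""


@dataclass(frozen=True)
class SpeciesConfig:
    """Raw per-species configuration prior to calibration.

    ``habitat_lat_range`` bounds the species' habitat by the grid's latitude
    proxy in [0, 1]; ``satiety_fraction`` places the satiety threshold as a
    fraction of the climatological mean accessible biomass (resolved at a
    quarter of the maturation mass).  All remaining keys are passed through to
    :class:`~minnow.bioenergetics.SpeciesParams`.
    """

    params: dict
    habitat_lat_range: tuple[float, float] | None = None
    satiety_fraction: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Validated desk-scale run configuration."""

    seed: int = 0
    n_years: float = 20.0
    spin_up_years: float = 10.0
    steps_per_year: int = 24
    energy_density: float = 1.0
    n_spawn_schools: int = 3
    n_init_schools: int = 10
    min_abundance: float = 1.0e-3
    # grid
    n_rows: int = 10
    n_cols: int = 10
    cell_size: float = 30.0
    # forcing
    forcing_preset: str = "covarying"
    forcing_overrides: dict = field(default_factory=dict)
    # calibration
    e_mobil: float = 0.8
    beta_maint: float = 0.8
    decline_feasibility: float = 0.65
    # analysis
    eps_guard: float = 0.01
    bin_width: float = 0.5
    # trophic
    base_tls: dict = field(
        default_factory=lambda: {
            "phytoplankton": 1.0,
            "zooplankton": 2.0,
            "macrozooplankton": 2.5,
            "benthos": 2.5,
        }
    )
    species: tuple[SpeciesConfig, ...] = ()

    def build_grid(self) -> Grid:
        return make_grid(self.n_rows, self.n_cols, self.cell_size)


def demo_config_path() -> Path:
    """Path of the packaged three-species demo configuration."""
    return Path(__file__).parent / "data" / "demo.toml"


_RUN_KEYS = {
    "seed": int, "n_years": float, "spin_up_years": float, "steps_per_year": int,
    "energy_density": float, "n_spawn_schools": int, "n_init_schools": int,
    "min_abundance": float,
}
_GRID_KEYS = {"n_rows": int, "n_cols": int, "cell_size": float}
_CAL_KEYS = {"e_mobil": float, "beta_maint": float, "decline_feasibility": float}
_ANALYSIS_KEYS = {"eps_guard": float, "bin_width": float}


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Raises :class:`ConfigError` whose message lists every failing field with
    its path rather than stopping at the first.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc

    problems: list[str] = []
    kwargs: dict = {}

    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        problems.append(
            f"schema_version: expected {SCHEMA_VERSION}, got {raw.get('schema_version')}"
        )

    def take(section: str, keys: dict) -> None:
        table = raw.get(section, {})
        if not isinstance(table, dict):
            problems.append(f"{section}: expected a table")
            return
        for k, v in table.items():
            if k not in keys:
                problems.append(f"{section}.{k}: unknown key")
            else:
                try:
                    kwargs[k] = keys[k](v)
                except (TypeError, ValueError):
                    problems.append(f"{section}.{k}: cannot coerce {v!r}")

    take("run", _RUN_KEYS)
    take("grid", _GRID_KEYS)
    take("calibration", _CAL_KEYS)
    take("analysis", _ANALYSIS_KEYS)

    forcing = raw.get("forcing", {})
    preset = forcing.get("preset", "covarying")
    if preset not in PRESET_NAMES:
        problems.append(f"forcing.preset: unknown preset {preset!r}")
    kwargs["forcing_preset"] = preset
    kwargs["forcing_overrides"] = {
        k: v for k, v in forcing.items() if k != "preset"
    }

    if "trophic" in raw:
        base = raw["trophic"].get("base_tls", {})
        if not all(isinstance(v, (int, float)) and v >= 1 for v in base.values()):
            problems.append("trophic.base_tls: levels must be numbers >= 1")
        else:
            kwargs["base_tls"] = {k: float(v) for k, v in base.items()}

    species_cfgs: list[SpeciesConfig] = []
    valid_fields = {f.name for f in dataclasses.fields(SpeciesParams)}
    for i, sp in enumerate(raw.get("species", [])):
        label = sp.get("name", f"#{i}")
        extra = {}
        params = {}
        for k, v in sp.items():
            if k == "habitat_lat_range":
                if not (isinstance(v, list) and len(v) == 2):
                    problems.append(f"species[{label}].habitat_lat_range: need [lo, hi]")
                else:
                    extra["habitat_lat_range"] = (float(v[0]), float(v[1]))
            elif k == "satiety_fraction":
                extra["satiety_fraction"] = float(v)
            elif k == "ltl_accessibility":
                params[k] = tuple((str(g), float(c)) for g, c in dict(v).items())
            elif k in ("spawning_steps", "habitat"):
                params[k] = tuple(int(x) for x in v)
            elif k not in valid_fields:
                problems.append(f"species[{label}].{k}: unknown key")
            else:
                params[k] = v
        try:
            SpeciesParams(**params)  # runs the dataclass validation
        except (TypeError, ValueError) as exc:
            problems.append(f"species[{label}]: {exc}")
        else:
            species_cfgs.append(SpeciesConfig(params=params, **extra))
    kwargs["species"] = tuple(species_cfgs)

    cfg = RunConfig(**{k: v for k, v in kwargs.items()})
    if cfg.spin_up_years >= cfg.n_years:
        problems.append("run.spin_up_years: must be smaller than run.n_years")
    if problems:
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(problems)
        )
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {v!r} to TOML")


def dump_config(cfg: RunConfig, path) -> None:
    """Write a configuration back to TOML (round-trips through load_config)."""
    lines = [f"schema_version = {SCHEMA_VERSION}", ""]

    def table(name: str, items: dict) -> None:
        lines.append(f"[{name}]")
        for k, v in items.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")

    table("run", {k: getattr(cfg, k) for k in _RUN_KEYS})
    table("grid", {k: getattr(cfg, k) for k in _GRID_KEYS})
    table("calibration", {k: getattr(cfg, k) for k in _CAL_KEYS})
    table("analysis", {k: getattr(cfg, k) for k in _ANALYSIS_KEYS})
    table("forcing", {"preset": cfg.forcing_preset, **cfg.forcing_overrides})
    lines.append("[trophic]")
    inner = ", ".join(f'"{k}" = {_toml_value(v)}' for k, v in cfg.base_tls.items())
    lines.append("base_tls = {" + inner + "}")
    lines.append("")
    for sp in cfg.species:
        lines.append("[[species]]")
        for k, v in sp.params.items():
            if k == "ltl_accessibility":
                inner = ", ".join(f'"{g}" = {_toml_value(c)}' for g, c in v)
                lines.append("ltl_accessibility = {" + inner + "}")
            else:
                lines.append(f"{k} = {_toml_value(v)}")
        if sp.habitat_lat_range is not None:
            lines.append(f"habitat_lat_range = {_toml_value(list(sp.habitat_lat_range))}")
        lines.append(f"satiety_fraction = {_toml_value(sp.satiety_fraction)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _habitat_cells(grid: Grid, lat_range: tuple[float, float] | None):
    if lat_range is None:
        return None
    lo, hi = lat_range
    lat = grid.lat01
    cells = np.nonzero((lat >= lo) & (lat <= hi))[0]
    return tuple(int(c) for c in cells)


def mean_accessible_biomass(
    species: SpeciesParams, forcing: ForcingClimatology, w: float | None = None
) -> float:
    """Climatological mean accessible LTL biomass (grams per cell).

    Evaluated at ``w`` (default: 0.15 times the maturation mass, a
    mid-juvenile body size), through the species' vertical reach, size window
    and accessibility coefficients.
    """
    if w is None:
        w = 0.15 * float(species.mass_from_length(species.rn_intercept))
    coeffs = _ltl_access_coeffs(species, w, forcing.groups)
    total = 0.0
    for g, c in zip(forcing.groups, coeffs):
        total += c * float(forcing.ltl_biomass[g.name].mean()) * 1.0e6
    return total


def assemble_community(
    cfg: RunConfig,
) -> tuple[Grid, ForcingClimatology, list[SpeciesParams]]:
    """Grid, climatology and calibrated species list for a configuration.

    Calibrates each species' thermal parameters to its (T_min, T_opt, T_max)
    targets, resolves habitat latitude ranges to cell sets, and places the
    satiety threshold at the configured fraction of the mean accessible
    biomass under the generated forcing.
    """
    grid = cfg.build_grid()
    scenario = make_scenario(
        cfg.forcing_preset, grid=grid, seed=cfg.seed, **cfg.forcing_overrides
    )
    forcing = generate_forcing(grid, scenario, cfg.steps_per_year)
    # The satiety threshold is defined against the "covarying" climatology for
    # every preset: it is a property of the species in its reference
    # environment, so that the "optimal" preset's inflated pools saturate
    # every consumer instead of inflating the threshold with them.
    if cfg.forcing_preset == "covarying":
        ref_forcing = forcing
    else:
        ref_forcing = generate_forcing(
            grid, make_scenario("covarying", grid=grid, seed=cfg.seed),
            cfg.steps_per_year,
        )
    species: list[SpeciesParams] = []
    for sp_cfg in cfg.species:
        sp = SpeciesParams(**sp_cfg.params)
        sp = replace(sp, habitat=_habitat_cells(grid, sp_cfg.habitat_lat_range))
        sp = calibrate_thermal_params(
            sp,
            e_mobil=cfg.e_mobil,
            beta_maint=cfg.beta_maint,
            decline_feasibility=cfg.decline_feasibility,
        )
        mean_acc = mean_accessible_biomass(sp, ref_forcing)
        sp = replace(
            sp,
            satiety_biomass=resolve_satiety_biomass(
                sp, mean_acc, sp_cfg.satiety_fraction
            ),
        )
        species.append(sp)
    return grid, forcing, species


def no_limitation_variant(cfg: RunConfig, egg_survival_scale: float = 0.02) -> RunConfig:
    """Configuration for the fundamental-equals-realised equivalence run.

    Switches the forcing to the ``optimal`` preset (unlimited food, 100 %
    oxygen saturation).  Because that removes predation and starvation as
    demographic brakes, egg survival is scaled down so the unchecked
    community stays demographically closed - and therefore far inside the
    non-limiting regime - over the simulated period.  The bioenergetic
    parameters are untouched.
    """
    species = tuple(
        replace(
            sc,
            params={**sc.params,
                    "egg_survival": sc.params.get("egg_survival", 1e-3)
                    * egg_survival_scale},
        )
        for sc in cfg.species
    )
    return replace(cfg, forcing_preset="optimal", forcing_overrides={}, species=species)
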