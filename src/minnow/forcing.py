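"""Synthetic gridded seasonal forcing: temperature, oxygen, plankton/benthos biomass.

Stands in for the coupled hydrodynamic-biogeochemical climatology that drives
the community simulation.  A :class:`ForcingScenario` fully determines, given
a seed, a periodic within-year climatology on a regular grid: temperature is a
latitudinal gradient plus a seasonal sinusoid plus seeded noise; dissolved
oxygen is a baseline minus optional seasonal and hypoxic-patch depressions,
clamped at zero; each low-trophic-level (LTL) prey group follows a seasonal
bloom modulated by ``exp(rho * z(T))`` where ``z(T)`` is the standardised
spatial temperature anomaly at that time step, so ``rho`` controls how
strongly prey biomass covaries with temperature (``rho = 0`` decouples them).

Three presets isolate the mechanisms of interest: ``optimal`` (unlimited food,
full oxygen saturation everywhere - the realised niche should collapse onto
the fundamental one), ``uniform_limitation`` (prey pinned to a fixed fraction
of a supplied satiety level, full oxygen), and ``covarying`` (seasonal blooms
covarying with temperature, plus a seasonal hypoxic patch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "LTLGroup",
    "HypoxicPatch",
    "ForcingScenario",
    "ForcingClimatology",
    "make_grid",
    "make_scenario",
    "generate_forcing",
    "PRESET_NAMES",
]

TONNES_TO_GRAMS = 1.0e6


@dataclass(frozen=True)
class Grid:
    """Regular rectangular grid; cells indexed row-major."""

    n_rows: int
    n_cols: int
    cell_size: float = 30.0  # km

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        """Cell area in km^2."""
        return self.cell_size**2

    def cell_index(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise IndexError("row/col outside grid")
        return row * self.n_cols + col

    def rowcol(self, index) -> tuple[np.ndarray, np.ndarray]:
        index = np.asarray(index)
        if np.any((index < 0) | (index >= self.n_cells)):
            raise IndexError("cell index outside grid")
        return index // self.n_cols, index % self.n_cols

    @property
    def lat01(self) -> np.ndarray:
        """Per-cell latitude proxy in [0, 1] (row-normalised; row 0 = south)."""
        rows = np.arange(self.n_cells) // self.n_cols
        if self.n_rows == 1:
            return np.full(self.n_cells, 0.5)
        return rows / (self.n_rows - 1)

    def neighbours(self, index: int) -> np.ndarray:
        """4-neighbourhood cell indices (for random-walk movement)."""
        r, c = int(index) // self.n_cols, int(index) % self.n_cols
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return np.asarray(out, dtype=int)


def make_grid(n_rows: int, n_cols: int, cell_size: float = 30.0) -> Grid:
    """Build a regular grid of ``n_rows * n_cols`` cells of side ``cell_size`` km."""
    return Grid(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size)


@dataclass(frozen=True)
class LTLGroup:
    """One low-trophic-level prey group supplied by the forcing.

    ``mean_biomass`` is tonnes per cell.  ``item_mass`` (g) is the nominal
    individual mass used by the predator size window.  ``rho`` is the signed
    temperature-covariation coefficient of biomass with the standardised
    spatial temperature anomaly.
    """

    name: str
    vertical: str  # "planktonic" | "benthic"
    trophic_level: float
    mean_biomass: float
    item_mass: float
    bloom_amplitude: float = 0.0  # relative seasonal amplitude, in [0, 1]
    bloom_phase: float = 0.25  # fraction of year of bloom peak
    rho: float = 0.0
    noise_cv: float = 0.0  # lognormal noise scale

    def __post_init__(self) -> None:
        if self.vertical not in ("planktonic", "benthic"):
            raise ValueError(f"LTL group {self.name!r}: bad vertical class {self.vertical!r}")
        if not 0 <= self.bloom_amplitude <= 1:
            raise ValueError(f"LTL group {self.name!r}: bloom amplitude must be in [0, 1]")
        if self.mean_biomass < 0 or self.item_mass <= 0:
            raise ValueError(f"LTL group {self.name!r}: bad biomass/item mass")
        if self.trophic_level < 1:
            raise ValueError(f"LTL group {self.name!r}: trophic level must be >= 1")
        if not np.isfinite(self.rho):
            raise ValueError(f"LTL group {self.name!r}: rho must be finite")


@dataclass(frozen=True)
class HypoxicPatch:
    """Seasonal oxygen depression over a set of cells.

    ``severity`` is subtracted from both integrated and bottom saturation
    during steps-of-year in ``[step_start, step_stop)``.
    """

    cells: tuple[int, ...]
    severity: float
    step_start: int
    step_stop: int


@dataclass(frozen=True)
class ForcingScenario:
    """Complete, seedable specification of a synthetic climatology."""

    name: str
    # temperature (degC)
    t_mean: float = 12.0
    t_lat_range: float = 8.0  # south-minus-north difference across the grid
    t_season_amp: float = 4.0
    t_season_phase: float = 0.55  # fraction of year of the warm peak
    t_noise_sd: float = 0.0
    # oxygen (% saturation)
    o2_baseline: float = 100.0
    o2_season_amp: float = 0.0
    o2_season_phase: float = 0.6
    hypoxic_patch: HypoxicPatch | None = None
    # bottom-vs-integrated offsets
    bottom_temp_offset: float = -2.0
    bottom_o2_offset: float = -10.0
    # prey
    ltl_groups: tuple[LTLGroup, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class ForcingClimatology:
    """Periodic within-year climatology on a grid.

    All field arrays have shape ``(steps_per_year, n_cells)``.  LTL biomass is
    tonnes per cell; temperatures degC; oxygen % saturation.  Accessors wrap
    the time index, so the climatology is periodic by construction.
    """

    grid: Grid
    steps_per_year: int
    t_int: np.ndarray
    t_bot: np.ndarray
    o2_int: np.ndarray
    o2_bot: np.ndarray
    ltl_biomass: dict[str, np.ndarray]
    groups: tuple[LTLGroup, ...]

    def __post_init__(self) -> None:
        shape = (self.steps_per_year, self.grid.n_cells)
        for nm in ("t_int", "t_bot", "o2_int", "o2_bot"):
            arr = np.asarray(getattr(self, nm), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{nm} has shape {arr.shape}, expected {shape}")
            object.__setattr__(self, nm, arr)
        for g in self.groups:
            if self.ltl_biomass[g.name].shape != shape:
                raise ValueError(f"LTL field {g.name!r} has wrong shape")
        if min(self.o2_int.min(), self.o2_bot.min()) < 0:
            raise ValueError("negative oxygen saturation")
        if min(b.min() for b in self.ltl_biomass.values()) < 0 if self.groups else False:
            raise ValueError("negative LTL biomass")

    def step_of_year(self, step: int) -> int:
        return int(step) % self.steps_per_year

    def temperature(self, step: int, vertical: str) -> np.ndarray:
        """Per-cell forcing temperature for a vertical class at a time step."""
        s = self.step_of_year(step)
        return self.t_bot[s] if vertical == "benthic" else self.t_int[s]

    def oxygen(self, step: int, vertical: str) -> np.ndarray:
        s = self.step_of_year(step)
        return self.o2_bot[s] if vertical == "benthic" else self.o2_int[s]

    def biomass(self, step: int, group: str) -> np.ndarray:
        return self.ltl_biomass[group][self.step_of_year(step)]

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: step, row, col, variable, value."""
        rows_idx, cols_idx = self.grid.rowcol(np.arange(self.grid.n_cells))
        frames = []
        named = {"t_int": self.t_int, "t_bot": self.t_bot,
                 "o2_int": self.o2_int, "o2_bot": self.o2_bot}
        named.update({f"ltl:{g.name}": self.ltl_biomass[g.name] for g in self.groups})
        for var, arr in named.items():
            steps = np.repeat(np.arange(self.steps_per_year), self.grid.n_cells)
            frames.append(pd.DataFrame({
                "step": steps,
                "row": np.tile(rows_idx, self.steps_per_year),
                "col": np.tile(cols_idx, self.steps_per_year),
                "variable": var,
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, grid: Grid, steps_per_year: int,
        groups: tuple[LTLGroup, ...],
    ) -> "ForcingClimatology":
        def pivot(var: str) -> np.ndarray:
            sub = df[df["variable"] == var]
            out = np.full((steps_per_year, grid.n_cells), np.nan)
            idx = grid.cell_index(sub["row"].to_numpy(), sub["col"].to_numpy())
            out[sub["step"].to_numpy(), idx] = sub["value"].to_numpy()
            if np.any(np.isnan(out)):
                raise ValueError(f"incomplete forcing variable {var!r}")
            return out

        return cls(
            grid=grid, steps_per_year=steps_per_year,
            t_int=pivot("t_int"), t_bot=pivot("t_bot"),
            o2_int=pivot("o2_int"), o2_bot=pivot("o2_bot"),
            ltl_biomass={g.name: pivot(f"ltl:{g.name}") for g in groups},
            groups=tuple(groups),
        )

    def to_xarray(self):
        import xarray as xr

        shape3 = (self.steps_per_year, self.grid.n_rows, self.grid.n_cols)
        dims = ("time_step", "row", "col")
        data = {nm: (dims, getattr(self, nm).reshape(shape3))
                for nm in ("t_int", "t_bot", "o2_int", "o2_bot")}
        for g in self.groups:
            data[f"ltl_{g.name}"] = (dims, self.ltl_biomass[g.name].reshape(shape3))
        return xr.Dataset(
            data,
            coords={"time_step": np.arange(self.steps_per_year),
                    "row": np.arange(self.grid.n_rows),
                    "col": np.arange(self.grid.n_cols)},
            attrs={"cell_size_km": self.grid.cell_size},
        )

    def to_netcdf(self, path) -> None:
        # the scipy engine writes classic netCDF without extra dependencies
        self.to_xarray().to_netcdf(path, engine="scipy")


PRESET_NAMES = ("optimal", "uniform_limitation", "covarying")

_DEFAULT_GROUP_TEMPLATES = (
    dict(name="phytoplankton", vertical="planktonic", trophic_level=1.0,
         item_mass=1.0e-6),
    dict(name="zooplankton", vertical="planktonic", trophic_level=2.0,
         item_mass=1.0e-3),
    dict(name="macrozooplankton", vertical="planktonic", trophic_level=2.5,
         item_mass=0.05),
    dict(name="benthos", vertical="benthic", trophic_level=2.5,
         item_mass=50.0),
)


def make_scenario(
    preset: str,
    grid: Grid | None = None,
    seed: int = 0,
    food_factor: float = 0.5,
    satiety_level: float = 50.0,
    mean_biomass: dict[str, float] | None = None,
    **overrides,
) -> ForcingScenario:
    """Build one of the named preset scenarios.

    ``optimal``
        Oxygen pinned at 100 % everywhere (integrated and bottom) and every
        LTL group effectively unlimited, aseasonal and temperature-independent.
    ``uniform_limitation``
        Oxygen at 100 %; every LTL group's biomass constant at
        ``food_factor * satiety_level`` tonnes per cell (the caller supplies
        the satiety-equivalent biomass of its consumers of interest).
    ``covarying``
        Seasonal plankton blooms covarying with the spatial temperature
        anomaly (``rho > 0``), a weakly seasonal benthos, and a late-summer
        hypoxic patch over the southern rows.

    Additional keyword overrides are applied to the resulting scenario.
    """
    if preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESET_NAMES}")
    biomass = {"phytoplankton": 8000.0, "zooplankton": 1800.0,
               "macrozooplankton": 1500.0, "benthos": 9000.0}
    biomass.update(mean_biomass or {})

    if preset == "optimal":
        groups = tuple(
            LTLGroup(mean_biomass=1.0e9, **t) for t in _DEFAULT_GROUP_TEMPLATES
        )
        base = ForcingScenario(
            name="optimal", o2_baseline=100.0, o2_season_amp=0.0,
            bottom_o2_offset=0.0, t_noise_sd=0.0, ltl_groups=groups, seed=seed,
        )
    elif preset == "uniform_limitation":
        level = food_factor * satiety_level
        groups = tuple(
            LTLGroup(mean_biomass=level, **t) for t in _DEFAULT_GROUP_TEMPLATES
        )
        base = ForcingScenario(
            name="uniform_limitation", t_lat_range=0.0, t_season_amp=0.0,
            o2_baseline=100.0, bottom_o2_offset=0.0, t_noise_sd=0.0,
            ltl_groups=groups, seed=seed,
        )
    else:  # covarying
        bloom = {"phytoplankton": dict(bloom_amplitude=0.95, bloom_phase=0.3,
                                       rho=0.7, noise_cv=0.25),
                 "zooplankton": dict(bloom_amplitude=0.5, bloom_phase=0.45,
                                     rho=0.35, noise_cv=0.2),
                 "macrozooplankton": dict(bloom_amplitude=0.45, bloom_phase=0.55,
                                          rho=0.2, noise_cv=0.15),
                 "benthos": dict(bloom_amplitude=0.05, bloom_phase=0.6,
                                 rho=0.0, noise_cv=0.05)}
        groups = tuple(
            LTLGroup(mean_biomass=biomass[t["name"]], **t, **bloom[t["name"]])
            for t in _DEFAULT_GROUP_TEMPLATES
        )
        patch = None
        if grid is not None:
            south = tuple(int(c) for c in np.nonzero(grid.lat01 <= 0.26)[0])
            patch = HypoxicPatch(cells=south, severity=50.0, step_start=12, step_stop=20)
        base = ForcingScenario(
            name="covarying", t_noise_sd=0.3, o2_baseline=100.0,
            o2_season_amp=8.0, hypoxic_patch=patch, ltl_groups=groups, seed=seed,
        )
    return replace(base, **overrides) if overrides else base


def generate_forcing(
    grid: Grid, scenario: ForcingScenario, steps_per_year: int = 24
) -> ForcingClimatology:
    """Generate the periodic climatology determined by (grid, scenario, seed)."""
    if steps_per_year < 1:
        raise ValueError("steps_per_year must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    s_frac = np.arange(steps_per_year)[:, None] / steps_per_year  # (S, 1)
    lat = grid.lat01[None, :]  # (1, C)

    season = np.sin(2 * np.pi * (s_frac - scenario.t_season_phase + 0.25))
    t_noise = (
        rng.normal(0.0, scenario.t_noise_sd, size=(steps_per_year, grid.n_cells))
        if scenario.t_noise_sd > 0 else 0.0
    )
    t_int = (
        scenario.t_mean
        + scenario.t_lat_range * (0.5 - lat)
        + scenario.t_season_amp * season
        + t_noise
    )
    t_bot = t_int + scenario.bottom_temp_offset

    o2_season = np.sin(2 * np.pi * (s_frac - scenario.o2_season_phase + 0.25))
    o2_int = np.broadcast_to(
        scenario.o2_baseline - scenario.o2_season_amp * np.maximum(o2_season, 0.0),
        (steps_per_year, grid.n_cells),
    ).copy()
    if scenario.hypoxic_patch is not None:
        p = scenario.hypoxic_patch
        steps = np.arange(steps_per_year)
        window = (steps >= p.step_start) & (steps < p.step_stop)
        cells = np.asarray(p.cells, dtype=int)
        o2_int[np.ix_(window, cells)] -= p.severity
    o2_bot = o2_int + scenario.bottom_o2_offset
    o2_int = np.clip(o2_int, 0.0, None)
    o2_bot = np.clip(o2_bot, 0.0, None)

    # standardised spatial temperature anomaly per step (z = 0 if uniform)
    sd = t_int.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (t_int - t_int.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)

    ltl: dict[str, np.ndarray] = {}
    for g in scenario.ltl_groups:
        bloom = 1.0 + g.bloom_amplitude * np.sin(2 * np.pi * (s_frac - g.bloom_phase + 0.25))
        fld = g.mean_biomass * bloom * np.exp(g.rho * z)
        if g.noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + g.noise_cv**2))
            fld = fld * rng.lognormal(-0.5 * sigma**2, sigma,
                                      size=(steps_per_year, grid.n_cells))
        else:
            fld = np.broadcast_to(fld, (steps_per_year, grid.n_cells)).copy()
        ltl[g.name] = np.clip(fld, 0.0, None)

    return ForcingClimatology(
        grid=grid, steps_per_year=steps_per_year,
        t_int=np.broadcast_to(t_int, (steps_per_year, grid.n_cells)).copy(),
        t_bot=np.broadcast_to(t_bot, (steps_per_year, grid.n_cells)).copy(),
        o2_int=o2_int, o2_bot=o2_bot, ltl_biomass=ltl,
        groups=tuple(scenario.ltl_groups),
    )
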