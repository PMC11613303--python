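"""End-to-end orchestration: forcing -> calibration -> simulation -> TPC -> stats.

Each stage reads its inputs from and writes its outputs to one artifact
directory, so the stages can be run separately (via the command line) or all
at once with :func:`run_all`.  A ``manifest.json`` written at the end records
the configuration hash, seed and package version; every output is regenerable
from the configuration file and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .bioenergetics import SpeciesParams, ThermalParams, fundamental_tpc
from .config import RunConfig, assemble_community, dump_config
from .forcing import ForcingClimatology
from .simulation import SimulationResult, run_simulation
from .stages import STAGES
from .tpc import binned_realised_curve, collect_samples, deviation_stats
from .trophic import ancova_fit, trophic_level

__all__ = [
    "export_thermal_params",
    "import_thermal_params",
    "run_all",
    "FORCING_FILE",
    "RECORDS_FILE",
    "DIET_FILE",
]

log = logging.getLogger("minnow")

FORCING_FILE = "forcing.csv"
CALIBRATION_FILE = "calibrated_params.csv"
RECORDS_FILE = "records.csv"
DIET_FILE = "diet.csv"
SAMPLES_FILE = "tpc_samples.csv"
DEVIATIONS_FILE = "deviation_stats.csv"
CURVES_FILE = "tpc_curves.csv"
TL_FILE = "trophic_levels.csv"
ANCOVA_FILE = "ancova_coefficients.csv"
MANIFEST_FILE = "manifest.json"


def export_thermal_params(species: list[SpeciesParams]) -> pd.DataFrame:
    """Calibrated thermal parameters as a flat (species, parameter, value) table."""
    rows = []
    for sp in species:
        if sp.thermal is None:
            raise ValueError(f"species {sp.name!r} is not calibrated")
        for f in dataclasses.fields(ThermalParams):
            rows.append(
                {"species": sp.name, "parameter": f.name,
                 "value": getattr(sp.thermal, f.name)}
            )
        rows.append({"species": sp.name, "parameter": "satiety_biomass",
                     "value": sp.satiety_biomass})
    return pd.DataFrame(rows)


def import_thermal_params(
    species: list[SpeciesParams], table: pd.DataFrame
) -> list[SpeciesParams]:
    """Re-attach exported thermal parameters to uncalibrated species."""
    out = []
    for sp in species:
        sub = table[table["species"] == sp.name].set_index("parameter")["value"]
        thermal = ThermalParams(
            **{f.name: float(sub[f.name]) for f in dataclasses.fields(ThermalParams)}
        )
        out.append(
            dataclasses.replace(
                sp, thermal=thermal,
                satiety_biomass=float(sub.get("satiety_biomass", sp.satiety_biomass)),
            )
        )
    return out


def _fundamental_curves(species: list[SpeciesParams], samples: pd.DataFrame) -> pd.DataFrame:
    """Dense fundamental TPCs at each stage's mean sampled mass."""
    frames = []
    for sp in species:
        for stage in STAGES:
            sub = samples[(samples["species"] == sp.name) & (samples["stage"] == stage)]
            if len(sub) == 0:
                continue
            mult = sp.eta_early if stage == "early" else 1.0
            curve = fundamental_tpc(
                sp, w=float(sub["w"].mean()), stage_multiplier=mult, step=0.05
            )
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp.name, "stage": stage, "kind": "fundamental",
                        "temperature": curve.temperature, "ep_mean": curve.net_energy,
                        "n": 0,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_all(cfg: RunConfig, out_dir) -> Path:
    """Run the full pipeline and write all artifacts to ``out_dir``.

    Stages: forcing generation, thermal calibration, community simulation,
    TPC sample collection and deviation statistics, trophic-level estimation
    and the stage ANCOVA.  Returns the artifact directory.  A stage failure
    propagates with the stage name in the log; earlier outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=assemble: calibrating %d species", len(cfg.species))
    grid, forcing, species = assemble_community(cfg)

    log.info("stage=forcing: writing climatology (%d steps x %d cells)",
             forcing.steps_per_year, grid.n_cells)
    forcing.to_dataframe().to_csv(out / FORCING_FILE, index=False)
    export_thermal_params(species).to_csv(out / CALIBRATION_FILE, index=False)

    log.info("stage=simulate: %s years (spin-up %s), seed %d",
             cfg.n_years, cfg.spin_up_years, cfg.seed)
    result: SimulationResult = run_simulation(
        species, forcing,
        n_years=cfg.n_years, spin_up_years=cfg.spin_up_years, seed=cfg.seed,
        energy_density=cfg.energy_density, n_spawn_schools=cfg.n_spawn_schools,
        n_init_schools=cfg.n_init_schools, min_abundance=cfg.min_abundance,
    )
    result.records.to_csv(out / RECORDS_FILE, index=False)
    result.diet.to_csv(out / DIET_FILE, index=False)
    log.info("stage=simulate: %d record rows, conservation overdraw %.2e",
             len(result.records), result.max_overdraw)

    log.info("stage=tpc: collecting samples")
    samples = collect_samples(result.records, species, forcing)
    samples.to_csv(out / SAMPLES_FILE, index=False)
    stats = deviation_stats(
        samples, species, eps_frac=cfg.eps_guard, bin_width=cfg.bin_width
    )
    stats.to_csv(out / DEVIATIONS_FILE, index=False)
    curves = pd.concat(
        [
            binned_realised_curve(samples, cfg.bin_width).assign(kind="realised"),
            _fundamental_curves(species, samples),
        ],
        ignore_index=True,
    )
    curves.to_csv(out / CURVES_FILE, index=False)

    log.info("stage=analyse: trophic levels and ANCOVA")
    tl = trophic_level(result.diet, cfg.base_tls)
    tl.to_csv(out / TL_FILE, index=False)
    ancova_rows = []
    try:
        fit = ancova_fit(stats, tl)
        for stage in fit.slopes:
            ancova_rows.append(
                {
                    "stage": stage,
                    "intercept_pct": fit.intercepts[stage],
                    "slope_pct_per_tl": fit.slopes[stage],
                    "slope_se": fit.slope_se[stage],
                }
            )
    except ValueError as exc:
        log.warning("stage=analyse: ANCOVA not fitted (%s)", exc)
    pd.DataFrame(ancova_rows).to_csv(out / ANCOVA_FILE, index=False)

    dump_config(cfg, out / "config.toml")
    cfg_hash = hashlib.sha256((out / "config.toml").read_bytes()).hexdigest()
    manifest = {
        "package": "minnow",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg_hash,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "n_record_rows": int(len(result.records)),
        "max_overdraw": result.max_overdraw,
        "max_imbalance": result.max_imbalance,
    }
    (out / MANIFEST_FILE).write_text(json.dumps(manifest, indent=2))
    log.info("stage=done: artifacts in %s", out)
    return out
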