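"""Shared fixtures: calibrated species, demo community runs, analysis products.

The expensive community runs are session-scoped and shared between the module
tests and the acceptance suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from minnow.bioenergetics import SpeciesParams, calibrate_thermal_params
from minnow.config import (
    assemble_community,
    demo_config_path,
    load_config,
    no_limitation_variant,
)
from minnow.simulation import run_simulation
from minnow.tpc import collect_samples, deviation_stats
from minnow.trophic import trophic_level


@pytest.fixture(scope="session")
def demo_cfg():
    return load_config(demo_config_path())


@pytest.fixture(scope="session")
def toy_species():
    """One generic calibrated species used by the bioenergetics unit tests."""
    sp = SpeciesParams(name="toy", t_min=5.0, t_opt=12.0, t_max=20.0,
                       i_max=35.0, w_ref=200.0, eta_early=1.6)
    return calibrate_thermal_params(sp)


def _run(cfg):
    grid, forcing, species = assemble_community(cfg)
    result = run_simulation(
        species, forcing, n_years=cfg.n_years, spin_up_years=cfg.spin_up_years,
        seed=cfg.seed, energy_density=cfg.energy_density,
        n_spawn_schools=cfg.n_spawn_schools, n_init_schools=cfg.n_init_schools,
        min_abundance=cfg.min_abundance,
    )
    samples = collect_samples(result.records, species, forcing)
    stats = deviation_stats(samples, species, eps_frac=cfg.eps_guard,
                            bin_width=cfg.bin_width)
    return {
        "cfg": cfg, "grid": grid, "forcing": forcing, "species": species,
        "result": result, "samples": samples, "stats": stats,
        "tl": trophic_level(result.diet, cfg.base_tls),
    }


@pytest.fixture(scope="session")
def covarying_runs(demo_cfg):
    """Demo community under the covarying preset for three seeds."""
    return {
        seed: _run(dataclasses.replace(demo_cfg, seed=seed)) for seed in (1, 2, 3)
    }


@pytest.fixture(scope="session")
def covarying_run(covarying_runs):
    return covarying_runs[1]


@pytest.fixture(scope="session")
def optimal_run(demo_cfg):
    """Demo community with unlimited food and full oxygen saturation."""
    return _run(no_limitation_variant(demo_cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
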