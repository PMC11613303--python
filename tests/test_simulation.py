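"""Community-simulation mechanics on small constructed states."""

import numpy as np
import pytest
from scipy.stats import chisquare

from minnow.bioenergetics import (
    SpeciesParams,
    calibrate_thermal_params,
    max_ingestion,
    maintenance_rate,
    oxygen_factor,
    temperature_factor,
)
from minnow.forcing import ForcingClimatology, LTLGroup, make_grid
from minnow.simulation import (
    EcosystemState,
    School,
    accessible_prey,
    bioenergetics_step,
    maturation_and_reproduction_step,
    move_schools,
    predation_step,
    run_simulation,
)

DT = 1.0 / 24


def flat_forcing(grid, groups=(), biomass=100.0, t=12.0, o2=100.0, steps=24):
    shape = (steps, grid.n_cells)
    return ForcingClimatology(
        grid=grid, steps_per_year=steps,
        t_int=np.full(shape, t), t_bot=np.full(shape, t),
        o2_int=np.full(shape, o2), o2_bot=np.full(shape, o2),
        ltl_biomass={g.name: np.full(shape, biomass) for g in groups},
        groups=tuple(groups),
    )


def predator_species(**kw):
    base = dict(
        name="pred", t_min=5.0, t_opt=12.0, t_max=20.0, i_max=10.0, w_ref=100.0,
        r_min=10.0, r_max=1e4, satiety_biomass=1.0,  # effectively always satiated
        m_background=0.0, m_larval=0.0, vertical="demersal",
    )
    base.update(kw)
    return calibrate_thermal_params(SpeciesParams(**base))


ZOO = LTLGroup(name="zooplankton", vertical="planktonic", trophic_level=2.0,
               mean_biomass=100.0, item_mass=1.0)
BEN = LTLGroup(name="benthos", vertical="benthic", trophic_level=2.5,
               mean_biomass=100.0, item_mass=5.0)


class TestMovement:
    def test_single_cell_habitat_pins_the_school(self):
        grid = make_grid(3, 3)
        sp = predator_species(habitat=(4,))
        state = EcosystemState.from_schools(
            [School("pred", 2.0, 50.0, 0.0, 10.0, 4)], [sp], grid, seed=0
        )
        for _ in range(200):
            move_schools(state)
        assert state.cell[0] == 4

    def test_fixed_seed_reproduces_the_trajectory(self):
        grid = make_grid(4, 4)
        sp = predator_species()
        paths = []
        for _ in range(2):
            state = EcosystemState.from_schools(
                [School("pred", 2.0, 50.0, 0.0, 10.0, 5)], [sp], grid, seed=11
            )
            path = []
            for _ in range(100):
                move_schools(state)
                path.append(int(state.cell[0]))
            paths.append(path)
        assert paths[0] == paths[1]

    def test_long_run_occupancy_is_uniform_over_the_habitat(self):
        # lazy symmetric random walk: stationary distribution uniform
        grid = make_grid(3, 3)
        sp = predator_species()
        state = EcosystemState.from_schools(
            [School("pred", 2.0, 50.0, 0.0, 10.0, 4)], [sp], grid, seed=5
        )
        counts = np.zeros(grid.n_cells)
        for _ in range(10_000):
            move_schools(state)
            counts[state.cell[0]] += 1
        assert chisquare(counts).pvalue > 0.01


class TestAccessiblePrey:
    def test_empty_cell_and_no_ltl_gives_zero(self):
        grid = make_grid(1, 1)
        sp = predator_species(vertical="pelagic")
        state = EcosystemState.from_schools(
            [School("pred", 2.0, 50.0, 0.0, 10.0, 0)], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid)
        state.refresh_ltl_pools(forcing)
        total, comp = accessible_prey(0, state, forcing)
        assert total == 0.0 and len(comp) == 0

    def test_mass_window_bounds_are_closed(self):
        grid = make_grid(1, 1)
        sp = predator_species(r_min=10.0, r_max=100.0)
        prey_exact_upper = School("pred", 1.0, 5.0, 0.0, 3.0, 0)  # w/r_min exactly
        prey_exact_lower = School("pred", 1.0, 0.5, 0.0, 4.0, 0)  # w/r_max exactly
        hunter = School("pred", 3.0, 50.0, 0.0, 1.0, 0)
        state = EcosystemState.from_schools(
            [hunter, prey_exact_upper, prey_exact_lower], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid)
        state.refresh_ltl_pools(forcing)
        total, comp = accessible_prey(0, state, forcing)
        assert total == pytest.approx(5.0 * 3.0 + 0.5 * 4.0)

    def test_hand_enumerated_composition(self):
        grid = make_grid(1, 1)
        sp = predator_species(r_min=10.0, r_max=100.0, vertical="demersal")
        hunter = School("pred", 3.0, 50.0, 0.0, 1.0, 0)  # window [0.5, 5] g
        in_range = School("pred", 1.0, 2.0, 0.0, 7.0, 0)
        too_small = School("pred", 0.5, 0.01, 0.0, 100.0, 0)
        too_big = School("pred", 5.0, 40.0, 0.0, 2.0, 0)
        state = EcosystemState.from_schools(
            [hunter, in_range, too_small, too_big], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid, groups=[ZOO, BEN], biomass=2e-4)  # 200 g pools
        state.refresh_ltl_pools(forcing)
        total, comp = accessible_prey(0, state, forcing)
        # in-range school biomass + both LTL pools (items 1 g and 5 g in window)
        assert total == pytest.approx(2.0 * 7.0 + 200.0 + 200.0)
        assert set(comp["prey"]) == {"pred:juvenile", "ltl:zooplankton", "ltl:benthos"}


class TestPredation:
    def test_single_predator_with_abundant_prey_reaches_satiety(self):
        grid = make_grid(1, 1)
        sp = predator_species(vertical="benthic")
        state = EcosystemState.from_schools(
            [School("pred", 3.0, 50.0, 0.0, 100.0, 0)], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid, groups=[BEN], biomass=1.0)  # 1e6 g pool
        state.refresh_ltl_pools(forcing)
        predation_step(state, forcing, DT)
        assert state.intake[0] == pytest.approx(max_ingestion(50.0, 1.0, sp))

    def test_two_identical_predators_split_a_scarce_pool_in_half(self):
        grid = make_grid(1, 1)
        sp = predator_species(vertical="benthic")
        n, w = 100.0, 50.0
        demand = float(max_ingestion(w, 1.0, sp)) * DT * n  # grams per school
        pool_tonnes = demand / 1e6
        state = EcosystemState.from_schools(
            [School("pred", 3.0, w, 0.0, n, 0), School("pred", 3.0, w, 0.0, n, 0)],
            [sp], grid, seed=0,
        )
        forcing = flat_forcing(grid, groups=[BEN], biomass=pool_tonnes)
        state.refresh_ltl_pools(forcing)
        predation_step(state, forcing, DT)
        np.testing.assert_allclose(
            state.intake, max_ingestion(w, 1.0, sp) / 2.0, rtol=1e-9
        )

    def test_three_unequal_demands_share_proportionally(self):
        # arithmetic oracle: allocation_i = demand_i * pool / total_demand
        grid = make_grid(1, 1)
        sp = predator_species(vertical="benthic")
        ns = np.array([10.0, 30.0, 60.0])
        w = 50.0
        per_school = float(max_ingestion(w, 1.0, sp)) * DT
        demands = per_school * ns
        pool = 0.5 * demands.sum()
        state = EcosystemState.from_schools(
            [School("pred", 3.0, w, 0.0, float(n), 0) for n in ns], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid, groups=[BEN], biomass=pool / 1e6)
        state.refresh_ltl_pools(forcing)
        predation_step(state, forcing, DT)
        expected_g = demands * pool / demands.sum()
        realised_g = state.intake * DT * ns
        np.testing.assert_allclose(realised_g, expected_g, rtol=1e-9)
        # the pool is emptied exactly
        assert state.ltl_pools["benthos"][0] == pytest.approx(0.0, abs=1e-6 * pool)

    def test_predation_removes_prey_individuals(self):
        grid = make_grid(1, 1)
        sp = predator_species(satiety_biomass=1.0)
        hunter = School("pred", 3.0, 50.0, 0.0, 1000.0, 0)
        prey = School("pred", 1.0, 2.0, 0.0, 50.0, 0)
        state = EcosystemState.from_schools([hunter, prey], [sp], grid, seed=0)
        forcing = flat_forcing(grid)
        state.refresh_ltl_pools(forcing)
        n_before = state.n[1]
        predation_step(state, forcing, DT)
        eaten_g = state.intake[0] * DT * state.n[0]
        assert state.n[1] == pytest.approx(n_before - eaten_g / 2.0)
        assert state.n[1] >= 0


class TestBioenergeticsStep:
    def test_immature_growth_goes_entirely_to_soma(self):
        grid = make_grid(1, 1)
        sp = predator_species()
        state = EcosystemState.from_schools(
            [School("pred", 2.0, 50.0, 0.0, 10.0, 0, mature=False)], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid, t=12.0)
        intake = float(max_ingestion(50.0, 1.0, sp))
        state.intake = np.array([intake])
        em = intake * sp.assim_eff * float(oxygen_factor(100.0, sp.k_o2, sp.h_o2)) \
            * float(temperature_factor(12.0, sp.thermal))
        net = em - float(maintenance_rate(50.0, 12.0, sp))
        assert net > 0
        bioenergetics_step(state, forcing, DT)
        assert state.w[0] == pytest.approx(50.0 + net * DT)
        assert state.gonad[0] == 0.0

    def test_mature_allocation_fraction(self):
        grid = make_grid(1, 1)
        sp = predator_species(gonad_allocation=0.3)
        state = EcosystemState.from_schools(
            [School("pred", 4.0, 50.0, 1.0, 10.0, 0, mature=True)], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid)
        state.intake = np.array([float(max_ingestion(50.0, 1.0, sp))])
        w0, g0 = state.w[0], state.gonad[0]
        bioenergetics_step(state, forcing, DT)
        dw, dg = state.w[0] - w0, state.gonad[0] - g0
        assert dg / (dw + dg) == pytest.approx(0.3)

    def test_starvation_mortality_matches_the_deficit_formula(self):
        grid = make_grid(1, 1)
        sp = predator_species(m_starvation=5.0)
        state = EcosystemState.from_schools(
            [School("pred", 2.0, 50.0, 0.0, 100.0, 0)], [sp], grid, seed=0
        )
        forcing = flat_forcing(grid, t=12.0)
        maint = float(maintenance_rate(50.0, 12.0, sp))
        # intake tuned so mobilisation covers 90 % of maintenance
        factor = sp.assim_eff * float(oxygen_factor(100.0, sp.k_o2, sp.h_o2)) \
            * float(temperature_factor(12.0, sp.thermal))
        state.intake = np.array([0.9 * maint / factor])
        bioenergetics_step(state, forcing, DT)
        assert state.n[0] == pytest.approx(100.0 * np.exp(-5.0 * 0.1 * DT), rel=1e-9)
        assert state.w[0] == 50.0  # no shrinkage


class TestMaturationAndReproduction:
    def test_school_below_the_reaction_norm_never_matures(self):
        grid = make_grid(1, 1)
        sp = predator_species(rn_intercept=30.0, rn_slope=0.0, spawning_steps=())
        state = EcosystemState.from_schools(
            [School("pred", 2.0, 50.0, 0.0, 10.0, 0)], [sp], grid, seed=0
        )  # length(50 g) ~ 17 cm < 30 cm
        for step in range(48):
            state.step = step
            maturation_and_reproduction_step(state, 24)
        assert not state.mature[0]

    def test_zero_gonads_spawn_no_offspring(self):
        grid = make_grid(1, 1)
        sp = predator_species(rn_intercept=1.0, spawning_steps=(0,))
        state = EcosystemState.from_schools(
            [School("pred", 4.0, 50.0, 0.0, 10.0, 0, mature=True)], [sp], grid, seed=0
        )
        state.step = 0
        maturation_and_reproduction_step(state, 24)
        assert state.n_schools == 1

    def test_egg_count_is_gonad_mass_over_egg_mass(self):
        grid = make_grid(1, 1)
        sp = predator_species(rn_intercept=1.0, spawning_steps=(0,),
                              egg_mass=1e-3, egg_survival=1.0)
        state = EcosystemState.from_schools(
            [School("pred", 4.0, 50.0, 10.0, 1.0, 0, mature=True)], [sp], grid, seed=0
        )
        state.step = 0
        maturation_and_reproduction_step(state, 24, n_spawn_schools=1)
        assert state.n_schools == 2
        assert state.n[1] == pytest.approx(10.0 / 1e-3)  # 10,000 eggs
        assert state.gonad[0] == 0.0
        assert state.age[1] == 0.0 and state.w[1] == pytest.approx(1e-3)


class TestRunSimulation:
    def test_zero_species_returns_empty_outputs_without_error(self):
        grid = make_grid(2, 2)
        forcing = flat_forcing(grid, groups=[ZOO])
        with pytest.warns(RuntimeWarning):
            res = run_simulation([], forcing, n_years=1.0, spin_up_years=0.5, seed=0)
        assert res.records.empty

    def test_fixed_seed_gives_bit_identical_records(self, demo_cfg):
        import dataclasses

        from minnow.config import assemble_community

        cfg = dataclasses.replace(demo_cfg, n_years=3.0, spin_up_years=1.0)
        _, forcing, species = assemble_community(cfg)
        a = run_simulation(species, forcing, 3.0, 1.0, seed=9)
        b = run_simulation(species, forcing, 3.0, 1.0, seed=9)
        assert a.records.equals(b.records)
        assert a.diet.equals(b.diet)

    def test_schools_stay_inside_their_habitat(self, covarying_run):
        rec = covarying_run["result"].records
        for sp in covarying_run["species"]:
            if sp.habitat is None:
                continue
            cells = rec.loc[rec["species"] == sp.name, "cell"].unique()
            assert set(cells) <= set(sp.habitat)

    def test_no_negative_abundances_or_masses(self, covarying_run):
        rec = covarying_run["result"].records
        assert (rec["abundance"] >= 0).all()
        assert (rec["w"] > 0).all()
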