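# Desk-scale demonstration community: three teleost species with contrasting
# thermal preferences and trophic ecology on a 10 x 10 grid, 20 simulated
# years with a 10-year spin-up. Runs in a few minutes on one CPU.

schema_version = 1

[run]
seed = 1
n_years = 20.0
spin_up_years = 10.0
steps_per_year = 24
energy_density = 1.0
n_spawn_schools = 3
n_init_schools = 10
min_abundance = 1e-3

[grid]
n_rows = 10
n_cols = 10
cell_size = 30.0

[calibration]
e_mobil = 0.8
beta_maint = 0.8
decline_feasibility = 0.65

[analysis]
eps_guard = 0.01
bin_width = 0.5

[forcing]
preset = "covarying"

[trophic]
base_tls = {"phytoplankton" = 1.0, "zooplankton" = 2.0, "macrozooplankton" = 2.5, "benthos" = 2.5}

# Cool-water planktivore (sprat-like): filter-feeds phytoplankton when small,
# zooplankton and macrozooplankton later; short-lived, northern habitat.
[[species]]
name = "sprat"
t_min = 3.0
t_opt = 11.0
t_max = 17.0
i_max = 18.0
w_ref = 280.0
eta_early = 1.8
r_min = 450.0
r_max = 8e6
rn_intercept = 22.0
rn_slope = 0.0
egg_mass = 1e-3
spawning_steps = [6, 7, 8, 9]
egg_survival = 1.5e-3
m_background = 0.9
m_larval = 2.0
max_age = 5.0
init_abundance = 1e8
vertical = "pelagic"
gonad_allocation = 0.35
ltl_accessibility = {"phytoplankton" = 0.12, "zooplankton" = 0.06, "macrozooplankton" = 0.3}
habitat_lat_range = [0.4, 1.0]
satiety_fraction = 0.8

# Mid-trophic demersal (whiting-like): zooplankton and macrozooplankton as a
# juvenile, benthos and small fish as an adult.
[[species]]
name = "whiting"
t_min = 5.0
t_opt = 13.0
t_max = 20.0
i_max = 20.0
w_ref = 1800.0
eta_early = 1.8
r_min = 15.0
r_max = 1e6
rn_intercept = 35.0
rn_slope = 0.0
egg_mass = 1e-3
spawning_steps = [5, 6, 7, 8]
egg_survival = 6e-4
m_background = 0.7
m_larval = 2.0
max_age = 8.0
init_abundance = 1e6
vertical = "demersal"
gonad_allocation = 0.3
ltl_accessibility = {"phytoplankton" = 0.35, "zooplankton" = 0.3, "macrozooplankton" = 0.3, "benthos" = 0.15}
habitat_lat_range = [0.1, 0.9]
satiety_fraction = 0.6

# Warm-preferring piscivore (saithe-like): large eggs, macrozooplankton as a
# juvenile, large benthos and fish as an adult; southern habitat.
[[species]]
name = "saithe"
t_min = 6.0
t_opt = 14.5
t_max = 22.0
i_max = 16.0
w_ref = 4500.0
eta_early = 1.9
r_min = 11.0
r_max = 3e4
rn_intercept = 45.0
rn_slope = 0.0
egg_mass = 5e-3
spawning_steps = [4, 5, 6, 7]
egg_survival = 1e-3
m_background = 0.45
m_larval = 2.0
max_age = 12.0
init_abundance = 1e5
vertical = "demersal"
gonad_allocation = 0.25
ltl_accessibility = {"phytoplankton" = 0.35, "zooplankton" = 0.15, "macrozooplankton" = 0.3, "benthos" = 0.08}
habitat_lat_range = [0.0, 0.75]
satiety_fraction = 0.65
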