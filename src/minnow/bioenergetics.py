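"""Individual-level bioenergetics: ingestion, mobilisation, maintenance, net energy.

The energy budget of an individual of somatic mass ``w`` (g) follows the
aerobic-scope view of fish energetics.  Ingested energy follows a Holling
type-1 functional response with a satiety plateau scaling as ``I_max * w**beta``.
A fixed fraction ``assim_eff`` of ingestion is assimilated.  Assimilated energy
is mobilised at a rate limited jointly by dissolved-oxygen saturation (a Hill
dose-response) and temperature (Arrhenius increase up to a peak temperature
``T_peak``, exponential decline above it).  Maintenance follows an Arrhenius
law in temperature and an allometric law in mass.  The net energy available
for tissue production is mobilisation minus maintenance; plotted against
temperature at maximum ingestion and full oxygen saturation it traces the
*fundamental* thermal performance curve (TPC), a dome with zeros at the
species' ``T_min`` and ``T_max`` and its maximum at ``T_opt``.

Energy is measured in grams of tissue equivalent per year (the simulation
converts net energy to growth through a single energy-density constant), so
``I_max`` has units of energy * g**(-beta) * yr**-1.

Temperatures are degrees Celsius at every public interface; conversion to
Kelvin happens only inside the Arrhenius exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_EV",
    "CELSIUS_TO_KELVIN",
    "CalibrationError",
    "EnergyFluxes",
    "SpeciesParams",
    "ThermalParams",
    "TPCCurve",
    "calibrate_thermal_params",
    "fundamental_net_energy",
    "fundamental_tpc",
    "ingestion_rate",
    "maintenance_rate",
    "max_ingestion",
    "mobilised_energy",
    "net_energy",
    "net_energy_from_intake",
    "oxygen_factor",
    "temperature_factor",
]

#: Boltzmann constant in eV / K (activation energies are in eV).
BOLTZMANN_EV = 8.617333262e-5
CELSIUS_TO_KELVIN = 273.15


class CalibrationError(RuntimeError):
    """Raised when thermal calibration cannot meet its targets."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermalParams:
    """Calibrated temperature-response parameters for one species.

    Attributes
    ----------
    e_mobil : float
        Activation energy (eV) of the Arrhenius rise of energy mobilisation.
    t_ref : float
        Reference temperature (degC) at which the mobilisation Arrhenius term
        is normalised to 1.
    t_peak : float
        Temperature (degC) above which mobilisation declines.
    decline : float
        Exponential decline rate of mobilisation above ``t_peak`` (1/degC).
    c_maint : float
        Maintenance coefficient (energy * g**(-beta_maint) * yr**-1 before the
        Arrhenius factor).
    beta_maint : float
        Allometric exponent of maintenance on mass.
    e_maint : float
        Activation energy (eV) of maintenance.
    """

    e_mobil: float
    t_ref: float
    t_peak: float
    decline: float
    c_maint: float
    beta_maint: float
    e_maint: float


@dataclass(frozen=True)
class SpeciesParams:
    """All per-species physiological, life-history and habitat parameters.

    ``thermal`` is ``None`` until :func:`calibrate_thermal_params` has been
    run; operations that need the temperature responses raise on an
    uncalibrated species.
    """

    name: str
    # fundamental TPC characteristic points (degC)
    t_min: float
    t_opt: float
    t_max: float
    # ingestion
    i_max: float  # mass-specific maximum ingestion rate, energy g^-beta yr^-1
    beta: float = 0.75
    eta_early: float = 1.6  # early-life I_max multiplier, in [1.4, 1.9]
    assim_eff: float = 0.7
    # accessible biomass (g per cell) at which the satiety plateau is reached;
    # the implied clearance coefficient is stage_mult * I_max * w**beta / satiety_biomass,
    # so the threshold biomass is the same for every body size of the species
    satiety_biomass: float = 1.0e6
    # oxygen dose-response
    k_o2: float = 30.0  # half-saturation, % saturation
    h_o2: float = 2.0  # Hill shape exponent
    # length-mass allometry  w = cond_factor * L**allom_b  (w in g, L in cm)
    cond_factor: float = 0.01
    allom_b: float = 3.0
    # predator/prey mass-ratio bounds (prey mass in [w/r_max, w/r_min])
    r_min: float = 10.0
    r_max: float = 1.0e5
    # maturation reaction norm midpoint: L_mat(age) = rn_intercept + rn_slope*age
    rn_intercept: float = 20.0
    rn_slope: float = 0.0
    # reproduction
    egg_mass: float = 1.0e-3  # g
    gonad_allocation: float = 0.3  # post-maturation share of net energy
    spawning_steps: tuple[int, ...] = (6, 7, 8, 9)  # steps-of-year
    egg_survival: float = 1.0e-3  # pre-recruitment survival folded into spawning
    # mortality closure
    max_age: float = 10.0  # longevity, years
    m_background: float = 0.4  # yr^-1, all ages
    m_larval: float = 2.0  # yr^-1, additional while age < 1
    m_starvation: float = 5.0  # yr^-1 at full maintenance deficit
    # habitat / forcing coupling
    init_abundance: float = 1.0e6  # individuals per school at age 0, for seeding
    vertical: str = "pelagic"  # pelagic | demersal | benthic
    # accessibility matrix row: fraction of each LTL group's biomass available
    # to this species (name -> coefficient); groups not listed default to 1
    ltl_accessibility: tuple[tuple[str, float], ...] = ()
    habitat: tuple[int, ...] | None = None  # cell indices; None = whole grid
    # calibration reference mass (g)
    w_ref: float = 100.0
    thermal: ThermalParams | None = None

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError(
                f"species {self.name!r}: characteristic points must satisfy "
                f"T_min < T_opt < T_max, got ({self.t_min}, {self.t_opt}, {self.t_max})"
            )
        if self.i_max <= 0:
            raise ValueError(f"species {self.name!r}: i_max must be positive")
        if not 0 < self.assim_eff <= 1:
            raise ValueError(f"species {self.name!r}: assim_eff must be in (0, 1]")
        if self.eta_early < 1:
            raise ValueError(f"species {self.name!r}: eta_early must be >= 1")
        if not self.r_min < self.r_max:
            raise ValueError(f"species {self.name!r}: need r_min < r_max")
        if self.vertical not in ("pelagic", "demersal", "benthic"):
            raise ValueError(f"species {self.name!r}: unknown vertical class {self.vertical!r}")

    @property
    def calibrated(self) -> bool:
        return self.thermal is not None

    def stage_multiplier(self, age) -> np.ndarray:
        """Ingestion multiplier: ``eta_early`` before age 1, then 1."""
        return np.where(np.asarray(age, dtype=float) < 1.0, self.eta_early, 1.0)

    def length_from_mass(self, w) -> np.ndarray:
        return (np.asarray(w, dtype=float) / self.cond_factor) ** (1.0 / self.allom_b)

    def mass_from_length(self, length) -> np.ndarray:
        return self.cond_factor * np.asarray(length, dtype=float) ** self.allom_b

    def maturation_length(self, age) -> np.ndarray:
        """Reaction-norm midpoint length at a given age."""
        return self.rn_intercept + self.rn_slope * np.asarray(age, dtype=float)

    def ltl_coeff(self, group_name: str) -> float:
        """Accessibility coefficient of an LTL group for this species."""
        return dict(self.ltl_accessibility).get(group_name, 1.0)


@dataclass(frozen=True)
class EnergyFluxes:
    """Energy-flux breakdown for one individual (energy / yr).

    ``net = mobilised - maintenance`` and may be negative; all other fluxes
    are nonnegative with ``assimilated = assim_eff * ingestion`` and
    ``mobilised <= assimilated``.
    """

    ingestion: np.ndarray
    assimilated: np.ndarray
    mobilised: np.ndarray
    maintenance: np.ndarray
    net: np.ndarray


# ---------------------------------------------------------------------------
# Elementary responses
# ---------------------------------------------------------------------------


def oxygen_factor(o2, k_o2: float, h: float = 2.0) -> np.ndarray:
    """Hill dose-response of energy mobilisation to dissolved-oxygen saturation.

    ``f = o2**h / (o2**h + k_o2**h)``; equals 1/2 at ``o2 == k_o2`` for any
    shape ``h`` and saturates towards 1 in well-oxygenated water.
    """
    o2 = np.asarray(o2, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("oxygen saturation must be nonnegative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(o2 > 0, (k_o2 / np.where(o2 > 0, o2, 1.0)) ** h, np.inf)
    return 1.0 / (1.0 + ratio)


def _arrhenius(t_c, e_act: float, t_ref_c: float) -> np.ndarray:
    """exp(E/k * (1/T_ref - 1/T)) with temperatures in degC, equals 1 at T_ref."""
    t_k = np.asarray(t_c, dtype=float) + CELSIUS_TO_KELVIN
    t_ref_k = t_ref_c + CELSIUS_TO_KELVIN
    return np.exp(e_act / BOLTZMANN_EV * (1.0 / t_ref_k - 1.0 / t_k))


def temperature_factor(t_c, thermal: ThermalParams) -> np.ndarray:
    """Temperature response of mobilisation: Arrhenius rise, decline above peak."""
    t_c = np.asarray(t_c, dtype=float)
    below = _arrhenius(np.minimum(t_c, thermal.t_peak), thermal.e_mobil, thermal.t_ref)
    above = np.exp(-thermal.decline * np.maximum(t_c - thermal.t_peak, 0.0))
    return below * above


def max_ingestion(w, stage_multiplier, species: SpeciesParams) -> np.ndarray:
    """Satiety-plateau ingestion rate ``stage_multiplier * I_max * w**beta``."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("somatic mass must be positive")
    return np.asarray(stage_multiplier, dtype=float) * species.i_max * w**species.beta


def ingestion_rate(p_accessible, w, stage_multiplier, species: SpeciesParams) -> np.ndarray:
    """Holling type-1 ingestion with a plateau.

    ``I = min(kappa * P, stage_multiplier * I_max * w**beta)`` with the
    clearance coefficient ``kappa = I_max * w**beta / satiety_biomass``:
    linear in accessible prey biomass ``P``, constant beyond the satiety
    threshold.  Tying ``kappa`` to the mass-specific rate (but not to the
    stage multiplier) makes the threshold biomass the same for every body
    size within a stage, while early-life fish - whose plateau is
    ``eta_early`` times higher at unchanged clearance - need correspondingly
    denser prey to satiate.
    """
    p = np.asarray(p_accessible, dtype=float)
    if np.any(p < 0):
        raise ValueError("accessible prey biomass must be nonnegative")
    base = max_ingestion(w, 1.0, species)
    sat = np.asarray(stage_multiplier, dtype=float) * base
    return np.minimum(base * p / species.satiety_biomass, sat)


def maintenance_rate(w, t_c, species: SpeciesParams) -> np.ndarray:
    """Arrhenius maintenance cost ``c_m * w**beta_m * exp(-E_m / (k_B T_K))``."""
    th = _require_thermal(species)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("somatic mass must be positive")
    t_k = np.asarray(t_c, dtype=float) + CELSIUS_TO_KELVIN
    return th.c_maint * w**th.beta_maint * np.exp(-th.e_maint / (BOLTZMANN_EV * t_k))


def mobilised_energy(assimilated, t_c, o2, species: SpeciesParams) -> np.ndarray:
    """Energy mobilised from the assimilated flux under (T, O2) co-limitation."""
    th = _require_thermal(species)
    a = np.asarray(assimilated, dtype=float)
    if np.any(a < 0):
        raise ValueError("assimilated energy must be nonnegative")
    return a * oxygen_factor(o2, species.k_o2, species.h_o2) * temperature_factor(t_c, th)


def net_energy_from_intake(ingestion, w, t_c, o2, species: SpeciesParams) -> EnergyFluxes:
    """Compose the budget downstream of a realised ingestion rate."""
    ingestion = np.asarray(ingestion, dtype=float)
    assimilated = species.assim_eff * ingestion
    mobilised = mobilised_energy(assimilated, t_c, o2, species)
    maintenance = maintenance_rate(w, t_c, species)
    return EnergyFluxes(
        ingestion=ingestion,
        assimilated=assimilated,
        mobilised=mobilised,
        maintenance=maintenance,
        net=mobilised - maintenance,
    )


def net_energy(
    p_accessible, w, stage_multiplier, t_c, o2, species: SpeciesParams
) -> EnergyFluxes:
    """Full budget from accessible prey biomass to net (production) energy."""
    intake = ingestion_rate(p_accessible, w, stage_multiplier, species)
    return net_energy_from_intake(intake, w, t_c, o2, species)


def fundamental_net_energy(t_c, w, stage_multiplier, species: SpeciesParams) -> np.ndarray:
    """Net energy at maximum ingestion and 100 % oxygen saturation."""
    intake = max_ingestion(w, stage_multiplier, species)
    return net_energy_from_intake(intake, w, t_c, 100.0, species).net


# ---------------------------------------------------------------------------
# Fundamental TPC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TPCCurve:
    """A thermal performance curve sampled on a strictly increasing grid."""

    temperature: np.ndarray
    net_energy: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        e = np.asarray(self.net_energy, dtype=float)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("temperature and net_energy must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "net_energy", e)

    @property
    def t_opt(self) -> float:
        """Grid temperature of the curve maximum (ties break to the lower T)."""
        return float(self.temperature[int(np.argmax(self.net_energy))])

    @property
    def e_max(self) -> float:
        return float(np.max(self.net_energy))

    def zeros(self) -> np.ndarray:
        """Temperatures of sign changes, by linear interpolation between nodes."""
        e, t = self.net_energy, self.temperature
        sign = np.sign(e)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        frac = e[idx] / (e[idx] - e[idx + 1])
        interior = t[idx] + frac * (t[idx + 1] - t[idx])
        exact = t[np.nonzero(e == 0.0)[0]]
        return np.sort(np.concatenate([interior, exact]))

    def n_sign_changes_of_slope(self) -> int:
        """Number of sign changes of successive differences (1 for a dome)."""
        d = np.diff(self.net_energy)
        s = np.sign(d)
        s = s[s != 0]
        return int(np.count_nonzero(s[:-1] * s[1:] < 0))


def fundamental_tpc(
    species: SpeciesParams,
    w: float | None = None,
    stage_multiplier: float = 1.0,
    t_grid: Sequence[float] | None = None,
    step: float = 0.01,
    margin: float = 2.0,
) -> TPCCurve:
    """Fundamental TPC of net energy for one species at a given mass and stage.

    Evaluated at maximum ingestion (satiety plateau for the stage) and 100 %
    dissolved-oxygen saturation on a dense temperature grid spanning
    ``[T_min - margin, T_max + margin]`` by default.
    """
    _require_thermal(species)
    if w is None:
        w = species.w_ref
    if t_grid is None:
        t_grid = np.arange(species.t_min - margin, species.t_max + margin + step / 2, step)
    t_grid = np.asarray(t_grid, dtype=float)
    e_p = fundamental_net_energy(t_grid, w, stage_multiplier, species)
    return TPCCurve(
        temperature=t_grid,
        net_energy=e_p,
        meta={"species": species.name, "w": float(w), "stage_multiplier": float(stage_multiplier)},
    )


# ---------------------------------------------------------------------------
# Calibration to (T_min, T_opt, T_max)
# ---------------------------------------------------------------------------


def _require_thermal(species: SpeciesParams) -> ThermalParams:
    if species.thermal is None:
        raise CalibrationError(
            f"species {species.name!r} has no calibrated thermal parameters; "
            "run calibrate_thermal_params first"
        )
    return species.thermal


def calibrate_thermal_params(
    species: SpeciesParams,
    e_mobil: float = 0.8,
    beta_maint: float = 0.8,
    decline: float | None = None,
    decline_feasibility: float = 0.65,
    tol_flux: float = 1.0e-6,
    tol_topt: float = 0.1,
    grid_step: float = 0.01,
) -> SpeciesParams:
    """Solve thermal parameters so the fundamental TPC hits its target points.

    At the reference mass ``w_ref`` (adult stage), the returned parameters make
    the fundamental net-energy curve vanish at ``T_min`` and ``T_max`` and peak
    at ``T_opt``.  The construction is closed-form: with mobilisation
    normalised at ``T_ref = T_opt`` and its decline starting at
    ``T_peak = T_opt``, the two zero conditions determine the maintenance
    activation energy and coefficient exactly, and the curve maximum falls at
    the decline onset.  The decline rate defaults to the fraction
    ``decline_feasibility`` of the largest rate compatible with a positive
    maintenance activation energy (maintenance must increase with
    temperature).  A dense-grid verification enforces ``|E_P| < tol_flux``
    (relative to the curve maximum) at the zeros and an argmax within
    ``tol_topt`` of ``T_opt``; if the argmax check fails, ``T_peak`` is
    refined by one-dimensional search before giving up.

    Returns a calibrated copy of ``species``; raises
    :class:`CalibrationError` on infeasible targets.
    """
    t_min, t_opt, t_max = species.t_min, species.t_opt, species.t_max
    t_min_k = t_min + CELSIUS_TO_KELVIN
    t_opt_k = t_opt + CELSIUS_TO_KELVIN
    t_max_k = t_max + CELSIUS_TO_KELVIN

    # Arrhenius rise of mobilisation between T_min and T_opt (log scale)
    rise = e_mobil / BOLTZMANN_EV * (1.0 / t_min_k - 1.0 / t_opt_k)
    max_decline = rise / (t_max - t_opt)
    if decline is None:
        decline = decline_feasibility * max_decline
    elif not 0 < decline < max_decline:
        raise CalibrationError(
            f"species {species.name!r}: decline rate {decline:.4f} outside the feasible "
            f"range (0, {max_decline:.4f}) for increasing maintenance"
        )

    def solve(t_peak: float) -> ThermalParams:
        th0 = ThermalParams(
            e_mobil=e_mobil, t_ref=t_opt, t_peak=t_peak, decline=decline,
            c_maint=1.0, beta_maint=beta_maint, e_maint=0.0,
        )
        a_star = species.assim_eff * max_ingestion(species.w_ref, 1.0, species)
        f100 = float(oxygen_factor(100.0, species.k_o2, species.h_o2))
        m_min = a_star * f100 * float(temperature_factor(t_min, th0))
        m_max = a_star * f100 * float(temperature_factor(t_max, th0))
        # zero conditions: maintenance equals mobilisation at both T_min and T_max
        log_ratio = np.log(m_max / m_min)
        e_maint = BOLTZMANN_EV * log_ratio / (1.0 / t_min_k - 1.0 / t_max_k)
        if e_maint <= 0:
            raise CalibrationError(
                f"species {species.name!r}: infeasible targets (maintenance would "
                "decrease with temperature); reduce the decline rate"
            )
        c_maint = m_min / (
            species.w_ref**beta_maint * np.exp(-e_maint / (BOLTZMANN_EV * t_min_k))
        )
        return replace(th0, c_maint=float(c_maint), e_maint=float(e_maint))

    def verified(th: ThermalParams) -> SpeciesParams | None:
        cand = replace(species, thermal=th)
        curve = fundamental_tpc(cand, step=grid_step, margin=0.0)
        scale = curve.e_max
        if scale <= 0:
            return None
        e_at_ends = np.abs(
            fundamental_net_energy(np.array([t_min, t_max]), species.w_ref, 1.0, cand)
        )
        if np.any(e_at_ends > tol_flux * scale):
            return None
        if abs(curve.t_opt - t_opt) > tol_topt:
            return None
        return cand

    result = verified(solve(t_opt))
    if result is None:
        # refine the decline-onset temperature by 1-D search on the argmax error
        from scipy.optimize import minimize_scalar

        def argmax_err(t_peak: float) -> float:
            try:
                cand = replace(species, thermal=solve(t_peak))
            except CalibrationError:
                return np.inf
            return abs(fundamental_tpc(cand, step=grid_step, margin=0.0).t_opt - t_opt)

        opt = minimize_scalar(
            argmax_err, bounds=(t_opt - 1.0, min(t_opt + 1.0, t_max - 1e-6)),
            method="bounded", options={"xatol": 1e-3},
        )
        result = verified(solve(float(opt.x)))
    if result is None:
        raise CalibrationError(
            f"species {species.name!r}: calibration did not meet tolerances "
            f"(tol_flux={tol_flux}, tol_topt={tol_topt})"
        )
    return result
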