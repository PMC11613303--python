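"""Fundamental vs realised TPCs and the deviation statistic with its decomposition.

The simulator records, for every school and post-spin-up time step, the
realised net energy rate together with the forcing temperature and oxygen it
experienced.  This module aggregates those records into *samples* - one per
occupied (species, life stage, cell, time step) - and compares three
quantities per sample:

``ep``
    the realised net energy, averaged across the schools in the sample;
``ep_fund``
    the fundamental net energy (maximum ingestion, 100 % oxygen saturation)
    evaluated at each school's mass and stage and averaged the same way;
``ep_cf``
    the food-optimal counterfactual: maximum ingestion but the oxygen
    actually present in the cell, again averaged across schools.

The total deviation of the realised from the fundamental curve for a species
and stage is the mean relative difference

    D_total = (1/n) * sum_j (ep_fund_j - ep_j) / ep_fund_j ,

the oxygen share ``D_oxygen`` replaces ``ep`` by ``ep_cf``, and the food
share is the exact remainder ``D_food = D_total - D_oxygen`` (energy fluxes
are additive, so the decomposition is exact on a common sample set).
Samples whose fundamental value is within a small guard fraction of zero are
excluded from all three statistics (the relative difference diverges at the
TPC zeros); their count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioenergetics import (
    SpeciesParams,
    fundamental_net_energy,
    fundamental_tpc,
    max_ingestion,
    net_energy_from_intake,
)
from .forcing import ForcingClimatology
from .stages import STAGES, classify_stage  # noqa: F401  (re-exported)

__all__ = [
    "STAGES",
    "classify_stage",
    "collect_samples",
    "counterfactual_oxygen_deviation",
    "decompose",
    "deviation",
    "deviation_stats",
    "realised_topt",
]

SAMPLE_KEYS = ["species", "stage", "cell", "step"]


def _stage_multiplier(stage: pd.Series, species: SpeciesParams) -> np.ndarray:
    return np.where(stage.to_numpy() == "early", species.eta_early, 1.0)


def collect_samples(
    records: pd.DataFrame,
    species: list[SpeciesParams],
    forcing: ForcingClimatology | None = None,
) -> pd.DataFrame:
    """Aggregate school-level records into one sample per (species, stage, cell, step).

    Averages are plain school means.  The fundamental and food-optimal
    counterfactual net energies are evaluated per school (at its own mass and
    stage multiplier) before averaging, so the three columns of every sample
    refer to exactly the same individuals.  When ``forcing`` is given, the
    counterfactual oxygen is looked up from the climatology at the sample's
    cell and step; otherwise the oxygen stored in the records is used (they
    coincide by construction of the simulation records).
    """
    cols = ["ep", "ep_fund", "ep_cf", "w", "temperature", "oxygen"]
    if records.empty:
        return pd.DataFrame(columns=SAMPLE_KEYS + cols + ["n_schools"])
    by_name = {s.name: s for s in species}
    parts = []
    for name, sub in records.groupby("species", sort=True, observed=True):
        spp = by_name[name]
        sub = sub.copy()
        mult = _stage_multiplier(sub["stage"], spp)
        t = sub["temperature"].to_numpy()
        w = sub["w"].to_numpy()
        if forcing is not None:
            o2_field = {
                s: forcing.oxygen(s, spp.vertical) for s in sub["step"].unique()
            }
            o2 = np.array(
                [o2_field[s][c] for s, c in zip(sub["step"], sub["cell"])]
            )
        else:
            o2 = sub["oxygen"].to_numpy()
        sub["ep_fund"] = fundamental_net_energy(t, w, mult, spp)
        sub["ep_cf"] = net_energy_from_intake(
            max_ingestion(w, mult, spp), w, t, o2, spp
        ).net
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True)
    grouped = df.groupby(SAMPLE_KEYS, sort=True, observed=True)
    out = grouped.agg(
        ep=("ep", "mean"),
        ep_fund=("ep_fund", "mean"),
        ep_cf=("ep_cf", "mean"),
        w=("w", "mean"),
        temperature=("temperature", "first"),
        oxygen=("oxygen", "first"),
        n_schools=("ep", "size"),
    ).reset_index()
    return out


def _guard_mask(
    samples: pd.DataFrame, species: SpeciesParams, eps_frac: float
) -> np.ndarray:
    """Retain samples whose fundamental value clears the near-zero guard.

    The guard threshold is ``eps_frac`` times the species' fundamental-curve
    maximum evaluated at each sample's mean mass and stage (the curve peaks at
    the calibrated optimum temperature for any mass in this model family).
    """
    mult = _stage_multiplier(samples["stage"], species)
    e_max = fundamental_net_energy(
        species.thermal.t_peak, samples["w"].to_numpy(), mult, species
    )
    return samples["ep_fund"].to_numpy() > eps_frac * np.maximum(e_max, 0.0)


def deviation(
    samples: pd.DataFrame, value_col: str = "ep", fund_col: str = "ep_fund"
) -> tuple[float, int]:
    """Mean relative difference of ``value_col`` from the fundamental value.

    ``D = (1/n) sum_j (fund_j - value_j) / fund_j`` over the given (already
    guarded) samples; returns ``(nan, 0)`` on an empty set rather than zero.
    """
    fund = samples[fund_col].to_numpy(dtype=float)
    val = samples[value_col].to_numpy(dtype=float)
    n = fund.size
    if n == 0:
        return float("nan"), 0
    return float(np.mean((fund - val) / fund)), int(n)


def counterfactual_oxygen_deviation(
    samples: pd.DataFrame,
    species: SpeciesParams | None = None,
    forcing: ForcingClimatology | None = None,
) -> tuple[float, int]:
    """Deviation attributable to oxygen alone, on the same retained samples.

    Uses the stored food-optimal counterfactual (maximum ingestion at the
    sample's actual oxygen).  If ``species`` and ``forcing`` are supplied the
    counterfactual is recomputed from the climatology at each sample's cell
    and step and the sample's mean mass - the forcing-driven route; the two
    agree whenever the records came from the simulator.
    """
    if species is not None and forcing is not None:
        sub = samples.copy()
        o2 = np.array(
            [
                forcing.oxygen(int(s), species.vertical)[int(c)]
                for s, c in zip(sub["step"], sub["cell"])
            ]
        )
        mult = _stage_multiplier(sub["stage"], species)
        w = sub["w"].to_numpy()
        sub["ep_cf"] = net_energy_from_intake(
            max_ingestion(w, mult, species), w, sub["temperature"].to_numpy(), o2, species
        ).net
        return deviation(sub, value_col="ep_cf")
    return deviation(samples, value_col="ep_cf")


def decompose(d_total: float, d_oxygen: float) -> float:
    """Food-limitation share as the exact remainder ``D_total - D_oxygen``."""
    return d_total - d_oxygen


def realised_topt(samples: pd.DataFrame, bin_width: float = 0.5) -> float:
    """Temperature of the highest binned mean realised net energy.

    Samples are binned by temperature (bin centres at odd multiples of half
    the width); ties break towards the lower temperature.  NaN on empty input.
    """
    if len(samples) == 0:
        return float("nan")
    t = samples["temperature"].to_numpy(dtype=float)
    ep = samples["ep"].to_numpy(dtype=float)
    idx = np.floor(t / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    uniq, starts = np.unique(idx[order], return_index=True)
    means = np.array([ep[order[s:e]].mean() for s, e in zip(starts, list(starts[1:]) + [len(t)])])
    best = uniq[np.nonzero(np.isclose(means, means.max()))[0][0]]  # ties -> lower bin
    return float((best + 0.5) * bin_width)


@dataclass(frozen=True)
class DeviationStats:
    """Deviation decomposition for one species and life stage."""

    species: str
    stage: str
    d_total: float
    d_oxygen: float
    d_food: float
    n: int
    excluded_n: int
    realised_topt: float
    fundamental_topt: float


def deviation_stats(
    samples: pd.DataFrame,
    species: list[SpeciesParams],
    eps_frac: float = 0.01,
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Per species x stage deviation statistics (total, oxygen, food shares).

    All three statistics share one retained sample set, so the decomposition
    ``d_food = d_total - d_oxygen`` is exact by construction.  Stages with no
    retained samples report NaN statistics with ``n = 0``.
    """
    by_name = {s.name: s for s in species}
    rows = []
    for name, spp in by_name.items():
        for stage in STAGES:
            sub = samples[(samples["species"] == name) & (samples["stage"] == stage)]
            if len(sub) == 0:
                continue
            keep = _guard_mask(sub, spp, eps_frac)
            retained = sub[keep]
            d_tot, n = deviation(retained)
            d_o2, n2 = deviation(retained, value_col="ep_cf")
            assert n == n2
            mult = spp.eta_early if stage == "early" else 1.0
            if len(retained):
                curve = fundamental_tpc(
                    spp, w=float(retained["w"].mean()), stage_multiplier=mult, step=0.01
                )
                fund_topt = curve.t_opt
            else:
                fund_topt = float("nan")
            rows.append(
                DeviationStats(
                    species=name, stage=stage,
                    d_total=d_tot, d_oxygen=d_o2,
                    d_food=decompose(d_tot, d_o2),
                    n=n, excluded_n=int(len(sub) - n),
                    realised_topt=realised_topt(retained, bin_width),
                    fundamental_topt=fund_topt,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def binned_realised_curve(
    samples: pd.DataFrame, bin_width: float = 0.5
) -> pd.DataFrame:
    """Binned mean realised TPC per species x stage, for plotting/export."""
    if len(samples) == 0:
        return pd.DataFrame(columns=["species", "stage", "temperature", "ep_mean", "n"])
    df = samples.copy()
    df["t_bin"] = (np.floor(df["temperature"] / bin_width) + 0.5) * bin_width
    out = (
        df.groupby(["species", "stage", "t_bin"], observed=True)
        .agg(ep_mean=("ep", "mean"), n=("ep", "size"))
        .reset_index()
        .rename(columns={"t_bin": "temperature"})
    )
    return out
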