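"""Trophic-level estimation from simulated diets and the stage ANCOVA.

The trophic level of a consumer is the flow-weighted standard definition
``TL = 1 + sum_p f_p * TL_p`` with ``f_p`` the biomass fraction of prey ``p``
in the diet aggregated over the analysis window.  Low-trophic-level forcing
groups carry fixed base levels (phytoplankton 1, zooplankton and benthos as
configured); fish species x stage nodes are solved to a fixed point, which on
any web without pathological cycles coincides with the direct linear solve.

The food-limitation deviation is then regressed on trophic level with life
stage as a categorical factor and a stage-specific slope (an ANCOVA with
interaction), via ordinary least squares.  Slopes are reported in percentage
points of deviation per trophic-level unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import STAGES

__all__ = ["AncovaFit", "TrophicConvergenceError", "ancova_fit", "trophic_level"]

_LTL_PREFIX = "ltl:"


class TrophicConvergenceError(RuntimeError):
    """Raised when the trophic-level fixed point fails to converge."""


def trophic_level(
    diet: pd.DataFrame,
    base_tls: dict[str, float],
    tol: float = 1.0e-6,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Flow-weighted trophic level per species x stage from a diet matrix.

    ``diet`` is the simulator's output: one row per predator species x stage,
    columns ``predator_species``, ``predator_stage`` and one column per prey
    item (``"<species>:<stage>"`` or ``"ltl:<group>"``) holding biomass eaten.
    ``base_tls`` maps LTL group names to their fixed trophic levels.

    Returns a table with columns ``species``, ``stage``, ``trophic_level`` and
    ``diet_total`` (biomass).  Nodes with an empty diet get NaN and are
    excluded from other nodes' diet fractions (their fractions renormalised).
    """
    prey_cols = [c for c in diet.columns if c not in ("predator_species", "predator_stage")]
    nodes = [f"{r.predator_species}:{r.predator_stage}" for r in diet.itertuples()]
    flows = diet[prey_cols].to_numpy(dtype=float)
    if np.any(flows < 0):
        raise ValueError("diet biomasses must be nonnegative")
    totals = flows.sum(axis=1)

    # fixed prey levels for LTL columns; fish columns point into the node list
    node_index = {n: i for i, n in enumerate(nodes)}
    ltl_tl = np.full(len(prey_cols), np.nan)
    fish_col_node = np.full(len(prey_cols), -1)
    for j, c in enumerate(prey_cols):
        if c.startswith(_LTL_PREFIX):
            name = c[len(_LTL_PREFIX):]
            if name not in base_tls:
                raise ValueError(f"no base trophic level configured for LTL group {name!r}")
            ltl_tl[j] = base_tls[name]
        elif c in node_index:
            fish_col_node[j] = node_index[c]

    tl = np.full(len(nodes), 3.0)
    empty = totals <= 0
    tl[empty] = np.nan
    for _ in range(max_iter):
        prey_tl = np.where(fish_col_node >= 0, tl[fish_col_node], ltl_tl)
        defined = np.isfinite(prey_tl)
        eff = np.where(defined[None, :], flows, 0.0)
        eff_tot = eff.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            new = 1.0 + np.where(
                eff_tot > 0,
                (eff * np.where(defined, prey_tl, 0.0)[None, :]).sum(axis=1)
                / np.where(eff_tot > 0, eff_tot, 1.0),
                np.nan,
            )
        new[empty] = np.nan
        live = ~empty
        if np.all(np.abs(new[live] - tl[live]) < tol):
            tl = new
            break
        tl = new
    else:
        raise TrophicConvergenceError(
            f"trophic-level fixed point did not converge in {max_iter} iterations"
        )
    return pd.DataFrame(
        {
            "species": diet["predator_species"].to_numpy(),
            "stage": diet["predator_stage"].to_numpy(),
            "trophic_level": tl,
            "diet_total": totals,
        }
    )


@dataclass(frozen=True)
class AncovaFit:
    """Stage-wise linear response of the food-limitation deviation to trophic level."""

    intercepts: dict[str, float]  # percentage points, per stage
    slopes: dict[str, float]  # percentage points per TL unit, per stage
    slope_se: dict[str, float]
    resid_std: float
    n: int
    results: object  # the underlying statsmodels results

    def predict(self, stage: str, tl) -> np.ndarray:
        """Fitted deviation (percentage points) for a stage at trophic levels ``tl``."""
        return self.intercepts[stage] + self.slopes[stage] * np.asarray(tl, dtype=float)

    def summary(self):
        return self.results.summary()


def ancova_fit(dev_table: pd.DataFrame, tl_table: pd.DataFrame) -> AncovaFit:
    """ANCOVA of the food-limitation deviation on trophic level x life stage.

    ``dev_table`` needs columns ``species``, ``stage``, ``d_food`` (fraction);
    ``tl_table`` columns ``species``, ``stage``, ``trophic_level``.  Fits
    ``100 * d_food ~ stage + stage:TL`` (separate intercept and slope per
    stage) by OLS and reports coefficients in percentage points.
    """
    import statsmodels.formula.api as smf

    df = dev_table.merge(tl_table, on=["species", "stage"], how="inner").dropna(
        subset=["d_food", "trophic_level"]
    )
    if df.empty:
        raise ValueError("no overlapping (species, stage) rows between tables")
    df = df.assign(d_food_pct=100.0 * df["d_food"], TL=df["trophic_level"])
    stages_present = [s for s in STAGES if s in set(df["stage"])]
    for s in stages_present:
        if df[df["stage"] == s]["TL"].nunique() < 2:
            raise ValueError(f"stage {s!r} has fewer than 2 distinct trophic levels")
    res = smf.ols("d_food_pct ~ 0 + C(stage) + C(stage):TL", data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    intercepts, slopes, slope_se = {}, {}, {}
    for s in stages_present:
        intercepts[s] = float(res.params[f"C(stage)[{s}]"])
        slopes[s] = float(res.params[f"C(stage)[{s}]:TL"])
        slope_se[s] = float(res.bse[f"C(stage)[{s}]:TL"])
    return AncovaFit(
        intercepts=intercepts, slopes=slopes, slope_se=slope_se,
        resid_std=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else float("nan"),
        n=int(res.nobs), results=res,
    )
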