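"""Inference of minimal enzyme rate constants per growth condition.

For each condition (a disulfide demand, a set of Dsb enzyme levels and a
growth rate) the question is: what are the smallest apparent rate constants
that still let the cell double its disulfide proteome once per generation?
Feasibility of a candidate parameter set is judged by simulation against two
stopping criteria: no substrate species may accumulate beyond 0.5% of its
cumulative synthesis over one doubling time, and the theoretical proteome
doubling time may exceed the reported one by at most 5%.

The search first bisects each rate constant individually between zero and a
biochemical ceiling while all other constants sit at the ceiling — this gives
the minimal requirement each reaction imposes on its own, a lower bound no
feasible parameter set can undercut.  Because these per-parameter minima each
assume maximal support from the rest of the network, their combination is
usually not jointly feasible; a second bisection scales the whole vector up
uniformly (capped at the ceilings) until the simulation passes both criteria.
The procedure is deterministic and restart-stable.

Because the minimal constants are apparent association constants, multiplying
them by the partner enzyme's concentration yields pseudo-first-order
substrate-processing rates (per minute) that are comparable across
conditions; these form the per-condition rate table with its summary rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disulfides import Category, FoldingDemand
from .enzymes import DsbLevels
from .model import (
    CATS,
    DsbFoldingModel,
    ModelParameters,
    ModelState,
    association_rate_to_cell_units,
    build_model,
    substrate_influx_rates,
)
from .proteome import CellGeometry, CellSizeVariant

__all__ = [
    "RATE_COLUMNS",
    "FeasibilityCriteria",
    "FeasibilityResult",
    "InfeasibleConditionError",
    "EnzymePools",
    "enzyme_pools",
    "default_ceilings",
    "evaluate_feasibility",
    "infer_minimal_rates",
    "pseudo_first_order_rate",
    "pseudo_first_order",
    "build_rate_table",
    "summarize_rate_table",
    "correlate_with_growth_rate",
    "load_published_rate_table",
    "write_rate_table",
]

#: Columns of the per-condition pseudo-first-order rate table (per minute).
RATE_COLUMNS = ["R2", "R3", "R4_cat1", "R45_cat2", "R5_cat3", "R678_cat2", "R678_cat3"]

LN2 = math.log(2.0)


class InfeasibleConditionError(RuntimeError):
    """Raised when a condition cannot be sustained even at ceiling rates."""


@dataclass(frozen=True)
class FeasibilityCriteria:
    """Stopping criteria for the minimal-rate search."""

    accumulation_threshold: float = 0.005
    doubling_slack: float = 0.05
    accumulation_norm: str = "synthesis"  # or "steady_state"

    def __post_init__(self) -> None:
        if not 0 < self.accumulation_threshold < 1:
            raise ValueError("accumulation_threshold must be in (0, 1)")
        if not 0 < self.doubling_slack < 1:
            raise ValueError("doubling_slack must be in (0, 1)")


@dataclass(frozen=True)
class FeasibilityResult:
    feasible: bool
    accumulation: Mapping[Category, float]
    doubling_time_min: float
    reported_doubling_min: float
    binding: str = ""


@dataclass(frozen=True)
class EnzymePools:
    """Total enzyme copies per cell entering the model."""

    dsba: float
    dsbb: float
    dsbcg: float  # pooled DsbC + DsbG
    dsbd: float

    def __post_init__(self) -> None:
        for name in ("dsba", "dsbb", "dsbcg", "dsbd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} pool must be non-negative")


def enzyme_pools(levels: DsbLevels | EnzymePools) -> EnzymePools:
    """Collapse per-enzyme levels into the four model pools."""
    if isinstance(levels, EnzymePools):
        return levels
    def copies(enzyme):
        return levels.copies(enzyme) if enzyme in levels else None

    dsba, dsbb, dsbd = copies("DsbA"), copies("DsbB"), copies("DsbD")
    dsbc, dsbg = copies("DsbC"), copies("DsbG")
    if dsba is None or dsbb is None or dsbd is None:
        missing = [e for e, v in (("DsbA", dsba), ("DsbB", dsbb), ("DsbD", dsbd)) if v is None]
        raise ValueError(f"missing enzyme concentrations for {missing}")
    if dsbc is None and dsbg is None:
        raise ValueError("missing enzyme concentrations for the DsbC/DsbG pool")
    return EnzymePools(dsba, dsbb, (dsbc or 0.0) + (dsbg or 0.0), dsbd)


def default_ceilings(
    mu: float,
    *,
    association_molar: float = 1.0e6,
    first_order_per_min: float = 6.0e3,
    compartment_fraction: float = 0.2,
) -> np.ndarray:
    """Biochemical ceilings for the nine rate constants, in model units.

    The association ceiling (default 1e6 M^-1 s^-1, the order of the fastest
    reported Dsb association constants) is converted to per-(molecules/cell)
    per-minute units using the periplasmic volume at this growth rate.
    """
    geometry = CellGeometry.from_growth_rate(mu, CellSizeVariant.COVERAGE)
    k_assoc = association_rate_to_cell_units(
        association_molar, geometry.volume_litres * compartment_fraction
    )
    k_first = first_order_per_min
    # order: k2, k3, k45 (cat1-3), k678 (cat2-3), k9, k10
    return np.array(
        [k_first, k_assoc, k_assoc, k_assoc, k_assoc, k_assoc, k_assoc, k_assoc, k_first]
    )


def _params_from_rates(
    rates: np.ndarray,
    v_syn: Mapping[Category, float],
    f_futile: float,
    f_success: float,
    f_reduce: float,
) -> ModelParameters:
    base = ModelParameters(
        k2=1.0, k3=1.0,
        k45={c: 1.0 for c in CATS},
        k678={Category.CAT2: 1.0, Category.CAT3: 1.0},
        k9=1.0, k10=1.0,
        v_syn=v_syn,
        f_futile=f_futile, f_success=f_success, f_reduce=f_reduce,
    )
    return base.with_rate_vector(rates)


def evaluate_feasibility(
    params: ModelParameters,
    pools: EnzymePools,
    mu: float,
    *,
    criteria: FeasibilityCriteria = FeasibilityCriteria(),
    rtol: float = 1e-7,
) -> FeasibilityResult:
    """Simulate one doubling time and test both stopping criteria.

    Substrate pools start empty with all enzymes in their active redox form;
    accumulation is evaluated at the reported doubling time, and the
    doubling-time criterion asks that cumulative correctly-folded output reach
    ln2 x demand within (1 + slack) reported doubling times.
    """
    td = 60.0 * LN2 / mu
    model = build_model(
        params, ModelState.fresh(pools.dsba, pools.dsbb, pools.dsbcg, pools.dsbd)
    )
    v = np.array([params.v_syn[c] for c in CATS])
    n_bonds = v.sum() * 60.0 / mu * 1.0  # N = v / mu_per_min
    target = LN2 * n_bonds

    def doubled(t, y):
        return y[6] + y[7] + y[8] - target

    doubled.direction = 1.0
    doubled.terminal = False

    horizon = (1.0 + criteria.doubling_slack) * td
    sol = model.simulate(horizon, n_points=0, events=[doubled], rtol=rtol)
    y_td = sol.sol(td)

    accumulation = {}
    for i, cat in enumerate(CATS):
        if v[i] <= 0:
            accumulation[cat] = 0.0
        elif criteria.accumulation_norm == "synthesis":
            accumulation[cat] = max(float(y_td[i] + y_td[3 + i]), 0.0) / (v[i] * td)
        else:  # steady_state: normalise to the category's standing pool v/mu
            accumulation[cat] = max(float(y_td[i] + y_td[3 + i]), 0.0) / (v[i] * 60.0 / mu)

    doubling = float(sol.t_events[0][0]) if len(sol.t_events[0]) else math.inf

    binding = ""
    worst = max(accumulation.values(), default=0.0)
    if worst > criteria.accumulation_threshold:
        cat = max(accumulation, key=accumulation.get)
        binding = f"accumulation of {cat.value} ({accumulation[cat]:.3%})"
    elif doubling > (1.0 + criteria.doubling_slack) * td:
        binding = "proteome doubling time"
    return FeasibilityResult(
        feasible=binding == "",
        accumulation=accumulation,
        doubling_time_min=doubling,
        reported_doubling_min=td,
        binding=binding,
    )


def infer_minimal_rates(
    demand: FoldingDemand | Mapping[Category, float],
    enzymes: DsbLevels | EnzymePools,
    mu: float,
    *,
    ceilings: np.ndarray | None = None,
    tol: float = 0.01,
    criteria: FeasibilityCriteria = FeasibilityCriteria(),
    f_futile: float = 1.0 / 3.0,
    f_success: float = 1.0 / 3.0,
    f_reduce: float = 1.0 / 3.0,
    rtol: float = 1e-7,
) -> ModelParameters:
    """Minimal apparent rate constants sustaining proteome doubling.

    Returns the parameter set described in the module docstring: per-parameter
    bisection (others at ceiling) to relative tolerance ``tol``, then a joint
    uniform scale-up bisection to restore feasibility.  Raises
    :class:`InfeasibleConditionError` (naming the binding constraint) if the
    condition fails even with every constant at its ceiling.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    pools = enzyme_pools(enzymes)
    v_syn = substrate_influx_rates(demand, mu)
    if ceilings is None:
        ceilings = default_ceilings(mu)
    ceilings = np.asarray(ceilings, dtype=float)

    def feasible(rates: np.ndarray) -> bool:
        params = _params_from_rates(rates, v_syn, f_futile, f_success, f_reduce)
        return evaluate_feasibility(
            params, pools, mu, criteria=criteria, rtol=rtol
        ).feasible

    ceiling_result = evaluate_feasibility(
        _params_from_rates(ceilings, v_syn, f_futile, f_success, f_reduce),
        pools, mu, criteria=criteria, rtol=rtol,
    )
    if not ceiling_result.feasible:
        raise InfeasibleConditionError(
            f"condition infeasible even at ceiling rates; binding constraint: "
            f"{ceiling_result.binding}"
        )

    # phase 1: per-parameter minimal requirement with full support elsewhere
    minima = np.zeros(len(ceilings))
    floor_frac = 1e-9
    for p in range(len(ceilings)):
        trial = ceilings.copy()
        trial[p] = 0.0
        if feasible(trial):
            minima[p] = 0.0  # this reaction is not needed for this condition
            continue
        lo, hi = 0.0, ceilings[p]
        while hi - lo > tol * hi:
            mid = 0.5 * (lo + hi)
            trial[p] = mid
            if feasible(trial):
                hi = mid
            else:
                lo = mid
        minima[p] = hi

    # phase 2: uniform scale-up of the minima vector to joint feasibility
    scale_base = np.where(minima > 0, minima, floor_frac * ceilings)

    def scaled(lam: float) -> np.ndarray:
        return np.minimum(lam * scale_base, ceilings)

    if feasible(scaled(1.0)):
        final = scaled(1.0)
    else:
        lam_lo, lam = 1.0, 2.0
        while not (feasible(scaled(lam)) or np.all(scaled(lam) >= ceilings)):
            lam_lo = lam
            lam *= 2.0
        lam_hi = lam  # feasible: either by simulation or fully capped at ceilings
        while lam_hi - lam_lo > tol * lam_hi:
            lam_mid = math.sqrt(lam_lo * lam_hi)
            if feasible(scaled(lam_mid)):
                lam_hi = lam_mid
            else:
                lam_lo = lam_mid
        final = scaled(lam_hi)

    return _params_from_rates(final, v_syn, f_futile, f_success, f_reduce)


# ---------------------------------------------------------------------------
# pseudo-first-order rate tables

def pseudo_first_order_rate(k_association: float, enzyme_concentration: float) -> float:
    """k_assoc x [enzyme]: the substrate-processing rate at that enzyme level.

    Units multiply through: M^-1 s^-1 with M gives s^-1; cell units with
    copies/cell give min^-1.
    """
    if k_association < 0 or enzyme_concentration < 0:
        raise ValueError("rate constant and concentration must be non-negative")
    return k_association * enzyme_concentration


def pseudo_first_order(
    params: ModelParameters, enzymes: DsbLevels | EnzymePools
) -> dict[str, float]:
    """One rate-table row: per-minute pseudo-first-order processing rates.

    R3 uses the DsbB pool (partner of reduced DsbA), R4/R5 the DsbA pool,
    R6-R8 the pooled isomerases; R2 (and k10) are already first-order.
    """
    pools = enzyme_pools(enzymes)
    return {
        "R2": params.k2,
        "R3": pseudo_first_order_rate(params.k3, pools.dsbb),
        "R4_cat1": pseudo_first_order_rate(params.k45[Category.CAT1], pools.dsba),
        "R45_cat2": pseudo_first_order_rate(params.k45[Category.CAT2], pools.dsba),
        "R5_cat3": pseudo_first_order_rate(params.k45[Category.CAT3], pools.dsba),
        "R678_cat2": pseudo_first_order_rate(params.k678[Category.CAT2], pools.dsbcg),
        "R678_cat3": pseudo_first_order_rate(params.k678[Category.CAT3], pools.dsbcg),
    }


def build_rate_table(
    rows: Mapping[str, Mapping[str, float]],
    growth_rates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble per-condition pseudo-first-order rows into a rate table."""
    frame = pd.DataFrame.from_dict(rows, orient="index")[RATE_COLUMNS]
    frame.index.name = "condition_label"
    if growth_rates:
        frame.insert(0, "growth_rate", pd.Series(growth_rates))
    return frame


def summarize_rate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Median, fold range (max/min) and inter-quartile fold (Q3/Q1) per rate.

    Quartiles use linear interpolation; for an even number of conditions the
    median is the mean of the central order statistics.  Non-positive entries
    make the fold statistics undefined and raise.
    """
    columns = [c for c in RATE_COLUMNS if c in table.columns]
    if len(table) < 2:
        raise ValueError("need at least two conditions to summarise")
    values = table[columns].astype(float)
    if (values <= 0).any().any():
        raise ValueError("fold statistics undefined for non-positive rates")
    summary = pd.DataFrame(
        {
            "median": values.median(),
            "range_fold": values.max() / values.min(),
            "iqr_fold": values.quantile(0.75) / values.quantile(0.25),
        }
    ).T
    summary.index.name = "statistic"
    return summary


def correlate_with_growth_rate(
    table: pd.DataFrame, column: str, growth_col: str = "growth_rate"
) -> float:
    """Pearson product-moment correlation of one rate column with growth rate."""
    sub = table[[growth_col, column]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least three conditions with growth rates")
    x, y = sub[growth_col].to_numpy(), sub[column].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def load_published_rate_table() -> pd.DataFrame:
    """The published per-condition rate table shipped with the package."""
    with resources.files("dsbfold.data").joinpath("published_rate_table.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return frame.set_index("condition_label")


def write_rate_table(table: pd.DataFrame, path: str | Path, summary: bool = True) -> None:
    """Write a rate table as TSV, optionally appending the summary rows."""
    out = table.copy()
    if summary:
        stats_frame = summarize_rate_table(table)
        stats_frame = stats_frame.rename(
            index={"median": "Median", "range_fold": "Range (fold)",
                   "iqr_fold": "Inter quartile range (fold)"}
        )
        out = pd.concat([out, stats_frame])
    out.to_csv(path, sep="\t")
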