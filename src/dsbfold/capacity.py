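"""Recombinant disulfide-protein production capacity.

Given a condition whose minimal native rate constants are known, how much
additional disulfide-bonded recombinant protein can the cell's oxidative
folding machinery absorb?  A recombinant substrate of a chosen folding
difficulty is added to the model as a fourth substrate species sharing the
category's kinetic constants, with no regulatory adaptation of enzyme levels
or rate constants.  Its synthesis rate is raised by bisection until any
native substrate species accumulates beyond the threshold (0.5% of its
cumulative synthesis over one doubling time by default).  The largest
tolerable rate is reported as a percentage of the cell's overall protein
production rate, so values above 100% mean more recombinant protein than the
entire native proteome synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .disulfides import Category, FoldingDemand, KINETIC_CATEGORIES
from .enzymes import DsbLevels
from .inference import EnzymePools, FeasibilityCriteria, enzyme_pools
from .model import CATS, DsbFoldingModel, ModelParameters, ModelState, SubstrateClass

__all__ = ["ConditionModel", "CapacityResult", "capacity_scan", "capacity_table"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ConditionModel:
    """Everything capacity scanning needs to know about one condition."""

    label: str
    params: ModelParameters  # includes native v_syn
    enzymes: EnzymePools | DsbLevels
    mu: float  # 1/h
    total_protein_copies: float  # whole-proteome copies per cell

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("growth rate must be positive")
        if self.total_protein_copies <= 0:
            raise ValueError("total protein copies must be positive")

    @property
    def pools(self) -> EnzymePools:
        return enzyme_pools(self.enzymes)

    @property
    def total_synthesis_rate(self) -> float:
        """Whole-proteome synthesis rate, proteins/cell/min (dilution balance)."""
        return self.mu / 60.0 * self.total_protein_copies


@dataclass(frozen=True)
class CapacityResult:
    condition_label: str
    recombinant_category: Category
    max_synthesis_fraction: float  # percent of overall protein production
    threshold_used: float
    native_feasible: bool
    at_search_bound: bool = False
    recombinant_rate: float = 0.0  # bonds/cell/min


def _native_ok(
    model: DsbFoldingModel,
    v_native: np.ndarray,
    td: float,
    threshold: float,
    count_recombinant: bool,
    v_rec: float,
    rtol: float,
) -> bool:
    sol = model.simulate(td, n_points=2, rtol=rtol)
    y = sol.y[:, -1]
    n = model.n_classes
    for i in range(3):
        if v_native[i] <= 0:
            continue
        backlog = max(y[i] + y[n + i], 0.0)
        if backlog / (v_native[i] * td) > threshold:
            return False
    if count_recombinant and v_rec > 0:
        backlog = max(y[3] + y[n + 3], 0.0)
        if backlog / (v_rec * td) > threshold:
            return False
    return True


def capacity_scan(
    condition: ConditionModel,
    recombinant_category: Category | str | int,
    *,
    threshold: float = 0.005,
    bonds_per_protein: float = 1.0,
    count_recombinant: bool = False,
    rel_tol: float = 0.01,
    upper_factor: float = 10.0,
    rtol: float = 1e-7,
) -> CapacityResult:
    """Largest recombinant synthesis rate before native substrates accumulate.

    ``bonds_per_protein`` converts the recombinant bond-synthesis rate into a
    protein-synthesis rate for the percentage denominator.  By default only
    the host's own substrate species are monitored against the threshold;
    ``count_recombinant=True`` also constrains the recombinant's backlog.
    A condition already at the threshold reports zero capacity, flagged via
    ``native_feasible``.
    """
    if isinstance(recombinant_category, int):
        recombinant_category = Category(f"cat{recombinant_category}")
    recombinant_category = Category(recombinant_category)
    if recombinant_category not in KINETIC_CATEGORIES:
        raise ValueError("recombinant category must be cat1, cat2 or cat3")

    params = condition.params
    pools = condition.pools
    td = 60.0 * LN2 / condition.mu
    v_native = np.array([params.v_syn[c] for c in CATS])
    initial = ModelState.fresh(pools.dsba, pools.dsbb, pools.dsbcg, pools.dsbd)

    def check(v_rec: float) -> bool:
        extra = SubstrateClass(
            v_syn=v_rec,
            k45=params.k45[recombinant_category],
            k678=params.k678[recombinant_category],
            p_correct=params.p_correct[recombinant_category],
        )
        model = DsbFoldingModel(params, initial, extra_classes=[extra])
        return _native_ok(model, v_native, td, threshold, count_recombinant, v_rec, rtol)

    def result(v_rec: float, native_ok: bool, capped: bool = False) -> CapacityResult:
        protein_rate = v_rec / bonds_per_protein if bonds_per_protein > 0 else 0.0
        percent = 100.0 * protein_rate / condition.total_synthesis_rate
        return CapacityResult(
            condition.label,
            recombinant_category,
            percent,
            threshold,
            native_feasible=native_ok,
            at_search_bound=capped,
            recombinant_rate=v_rec,
        )

    if not check(0.0):
        return result(0.0, native_ok=False)

    # bound in bond units: 10x the cell's total protein synthesis rate
    upper = upper_factor * condition.total_synthesis_rate * max(bonds_per_protein, 1e-12)
    if check(upper):
        return result(upper, native_ok=True, capped=True)

    lo, hi = 0.0, upper
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if check(mid):
            lo = mid
        else:
            hi = mid
    return result(lo, native_ok=True)


def capacity_table(
    conditions: Sequence[ConditionModel],
    categories: Sequence[Category | str | int] = KINETIC_CATEGORIES,
    **scan_kwargs,
) -> pd.DataFrame:
    """Capacity scans over a grid of conditions and recombinant difficulties.

    Conditions whose native system is already at threshold are flagged in the
    ``native_feasible`` column rather than silently reported as zero.
    """
    rows = []
    for condition in conditions:
        for category in categories:
            res = capacity_scan(condition, category, **scan_kwargs)
            rows.append(
                {
                    "condition_label": res.condition_label,
                    "recombinant_category": res.recombinant_category.value,
                    "max_synthesis_percent": res.max_synthesis_fraction,
                    "native_feasible": res.native_feasible,
                    "at_search_bound": res.at_search_bound,
                }
            )
    return pd.DataFrame(rows)
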