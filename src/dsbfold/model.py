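"""Mass-action ODE model of periplasmic oxidative folding in *E. coli*.

Substrates enter the periplasm unfolded and reduced (UF), grouped into three
folding-difficulty categories, at rates set by growth dilution of the
disulfide proteome.  Oxidation by DsbA (reactions R4/R5) yields the correctly
folded product FP with probability p_cat (1.0 / 0.5 / 0.0 for cat1/2/3) or a
misfolded species MFP otherwise, reducing DsbA in the process.  DsbA is
reoxidised by DsbB (R3), which in turn is reoxidised by quinone (R2,
pseudo-first-order).  MFP engages the pooled isomerases DsbC/DsbG (R6/R7/R8)
with three outcomes: successful isomerisation to FP, a futile cycle leaving
MFP unchanged, or reduction back to UF which oxidises the isomerase.  The
oxidised isomerase is re-reduced by DsbD (R9), itself regenerated by
thioredoxin (R10, pseudo-first-order).  Quinone and thioredoxin are clamped
boundary pools folded into k2 and k10.

Units: concentrations in molecules per cell, time in minutes.  Association
constants are second-order in these units; :func:`association_rate_to_cell_units`
converts from M^-1 s^-1 given a (sub-)cellular volume.

The four enzyme redox pairs are conserved moieties.  The integrator works on
a reduced state (one member of each pair), so the conservation sums hold
exactly along every trajectory; the full state is reconstructed on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .disulfides import Category, FoldingDemand, KINETIC_CATEGORIES

__all__ = [
    "P_CORRECT",
    "ModelParameters",
    "ModelState",
    "SubstrateClass",
    "Trajectory",
    "DsbFoldingModel",
    "build_model",
    "substrate_influx_rates",
    "simulate",
    "accumulation_fraction",
    "proteome_doubling_time",
    "association_rate_to_cell_units",
    "association_rate_to_molar_units",
]

#: Probability that DsbA-mediated oxidation immediately yields the correct fold.
P_CORRECT: dict[Category, float] = {
    Category.CAT1: 1.0,
    Category.CAT2: 0.5,
    Category.CAT3: 0.0,
}

CATS = KINETIC_CATEGORIES  # (cat1, cat2, cat3)
ISOMERASE_CATS = (Category.CAT2, Category.CAT3)


def _catdict(values: Mapping, cats: Sequence[Category], name: str) -> dict[Category, float]:
    """Normalise {Category|int|str: float} onto the given categories."""
    out = {}
    for key, value in values.items():
        if isinstance(key, int):
            key = Category(f"cat{key}")
        else:
            key = Category(key)
        out[key] = float(value)
    missing = [c for c in cats if c not in out]
    if missing:
        raise ValueError(f"{name} missing categories {[c.value for c in missing]}")
    return {c: out[c] for c in cats}


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic parameters of the oxidative folding network.

    Association constants (k3, k45, k678, k9) are in (molecules/cell)^-1
    min^-1; k2 and k10 are pseudo-first-order in min^-1.  ``f_futile``,
    ``f_success`` and ``f_reduce`` split the isomerase flux and must sum to 1.
    ``v_syn`` are per-category substrate synthesis rates in bonds/cell/min.
    """

    k2: float
    k3: float
    k45: Mapping[Category, float]
    k678: Mapping[Category, float]
    k9: float
    k10: float
    v_syn: Mapping[Category, float]
    f_futile: float = 1.0 / 3.0
    f_success: float = 1.0 / 3.0
    f_reduce: float = 1.0 / 3.0
    p_correct: Mapping[Category, float] = field(default_factory=lambda: dict(P_CORRECT))

    def __post_init__(self) -> None:
        object.__setattr__(self, "k45", _catdict(self.k45, CATS, "k45"))
        object.__setattr__(
            self, "k678", _catdict({**{Category.CAT1: 0.0}, **dict(self.k678)}, CATS, "k678")
        )
        object.__setattr__(self, "v_syn", _catdict(self.v_syn, CATS, "v_syn"))
        object.__setattr__(self, "p_correct", _catdict(self.p_correct, CATS, "p_correct"))
        for name in ("k2", "k3", "k9", "k10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for mapping in (self.k45, self.k678, self.v_syn):
            if any(v < 0 for v in mapping.values()):
                raise ValueError("rates must be non-negative")
        total = self.f_futile + self.f_success + self.f_reduce
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"isomerase outcome fractions must sum to 1 (got {total})"
            )

    def with_rates(self, **updates) -> "ModelParameters":
        return replace(self, **updates)

    def rate_vector(self) -> np.ndarray:
        """The nine tunable rate constants in canonical order."""
        return np.array(
            [
                self.k2,
                self.k3,
                self.k45[Category.CAT1],
                self.k45[Category.CAT2],
                self.k45[Category.CAT3],
                self.k678[Category.CAT2],
                self.k678[Category.CAT3],
                self.k9,
                self.k10,
            ]
        )

    @staticmethod
    def rate_names() -> list[str]:
        return ["k2", "k3", "k45_cat1", "k45_cat2", "k45_cat3",
                "k678_cat2", "k678_cat3", "k9", "k10"]

    def with_rate_vector(self, rates: np.ndarray) -> "ModelParameters":
        k2, k3, a1, a2, a3, i2, i3, k9, k10 = (float(r) for r in rates)
        return replace(
            self,
            k2=k2,
            k3=k3,
            k45={Category.CAT1: a1, Category.CAT2: a2, Category.CAT3: a3},
            k678={Category.CAT2: i2, Category.CAT3: i3},
            k9=k9,
            k10=k10,
        )


@dataclass(frozen=True)
class ModelState:
    """Full model state (molecules per cell)."""

    UF: Mapping[Category, float]
    MFP: Mapping[Category, float]
    FP: Mapping[Category, float]
    DsbAo: float = 0.0
    DsbAr: float = 0.0
    DsbBo: float = 0.0
    DsbBr: float = 0.0
    DsbCGr: float = 0.0
    DsbCGo: float = 0.0
    DsbDr: float = 0.0
    DsbDo: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "UF", _catdict(self.UF, CATS, "UF"))
        object.__setattr__(self, "MFP", _catdict(self.MFP, CATS, "MFP"))
        object.__setattr__(self, "FP", _catdict(self.FP, CATS, "FP"))
        for name in ("DsbAo", "DsbAr", "DsbBo", "DsbBr",
                     "DsbCGr", "DsbCGo", "DsbDr", "DsbDo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for m in (self.UF, self.MFP, self.FP) for v in m.values()):
            raise ValueError("substrate pools must be non-negative")

    @classmethod
    def fresh(
        cls,
        dsba: float,
        dsbb: float,
        dsbcg: float,
        dsbd: float,
    ) -> "ModelState":
        """All enzymes in their active form, no substrate present."""
        zero = {c: 0.0 for c in CATS}
        return cls(
            UF=zero, MFP=dict(zero), FP=dict(zero),
            DsbAo=dsba, DsbBo=dsbb, DsbCGr=dsbcg, DsbDr=dsbd,
        )

    @property
    def totals(self) -> tuple[float, float, float, float]:
        return (
            self.DsbAo + self.DsbAr,
            self.DsbBo + self.DsbBr,
            self.DsbCGr + self.DsbCGo,
            self.DsbDr + self.DsbDo,
        )


STATE_COLUMNS = (
    ["UF_cat1", "UF_cat2", "UF_cat3",
     "MFP_cat1", "MFP_cat2", "MFP_cat3",
     "FP_cat1", "FP_cat2", "FP_cat3",
     "DsbAo", "DsbBo", "DsbCGr", "DsbDr"]
)
FULL_COLUMNS = STATE_COLUMNS + ["DsbAr", "DsbBr", "DsbCGo", "DsbDo"]

FLUX_COLUMNS = (
    ["R1_cat1", "R1_cat2", "R1_cat3", "R2", "R3",
     "R4_cat1", "R4_cat2", "R4_cat3", "R5_cat1", "R5_cat2", "R5_cat3",
     "R6_cat2", "R6_cat3", "R7_cat2", "R7_cat3", "R8_cat2", "R8_cat3",
     "R9", "R10"]
)


@dataclass
class Trajectory:
    """Integration result: time grid (min), states and per-reaction fluxes."""

    t: np.ndarray
    states: pd.DataFrame
    fluxes: pd.DataFrame
    params: ModelParameters

    @property
    def final(self) -> pd.Series:
        return self.states.iloc[-1]

    def conservation_drift(self) -> dict[str, float]:
        """Max relative drift of each enzyme moiety sum (exact by construction)."""
        out = {}
        for pair, total_name in (
            (("DsbAo", "DsbAr"), "DsbA"),
            (("DsbBo", "DsbBr"), "DsbB"),
            (("DsbCGr", "DsbCGo"), "DsbCG"),
            (("DsbDr", "DsbDo"), "DsbD"),
        ):
            sums = self.states[pair[0]] + self.states[pair[1]]
            ref = sums.iloc[0]
            out[total_name] = 0.0 if ref == 0 else float((sums - ref).abs().max() / ref)
        return out

    def cumulative_fp(self) -> np.ndarray:
        fp = self.states[["FP_cat1", "FP_cat2", "FP_cat3"]].sum(axis=1).to_numpy()
        return fp - fp[0]

    def to_tsv(self, path) -> None:
        frame = self.states.copy()
        frame.insert(0, "time_min", self.t)
        frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SubstrateClass:
    """An additional substrate species (e.g. a recombinant protein).

    Carries its own synthesis rate and the kinetic constants and correct-fold
    probability it shares with its folding-difficulty category.
    """

    v_syn: float
    k45: float
    k678: float
    p_correct: float
    label: str = "recombinant"

    def __post_init__(self) -> None:
        if min(self.v_syn, self.k45, self.k678) < 0:
            raise ValueError("substrate-class rates must be non-negative")
        if not 0 <= self.p_correct <= 1:
            raise ValueError("p_correct must be in [0, 1]")


class DsbFoldingModel:
    """The reaction network with fixed parameters and initial state.

    ``extra_classes`` appends substrate species beyond the three native
    categories; they start at zero concentration and share the enzyme pools.
    """

    def __init__(
        self,
        params: ModelParameters,
        initial: ModelState,
        extra_classes: Sequence[SubstrateClass] = (),
    ):
        self.params = params
        self.initial = initial
        self.totals = initial.totals
        self.extra_classes = tuple(extra_classes)

        p = params
        extras = self.extra_classes
        self._v = np.array([p.v_syn[c] for c in CATS] + [e.v_syn for e in extras])
        self._k45 = np.array([p.k45[c] for c in CATS] + [e.k45 for e in extras])
        self._k678 = np.array([p.k678[c] for c in CATS] + [e.k678 for e in extras])
        self._p = np.array([p.p_correct[c] for c in CATS] + [e.p_correct for e in extras])
        n = 3 + len(extras)
        self.n_classes = n
        self.uf_slice = slice(0, n)
        self.mfp_slice = slice(n, 2 * n)
        self.fp_slice = slice(2 * n, 3 * n)
        self._e = 3 * n  # offset of the enzyme block (Ao, Bo, CGr, Dr)

    # -- state vector helpers ------------------------------------------------

    def reduced_state(self, state: ModelState) -> np.ndarray:
        zeros = [0.0] * len(self.extra_classes)
        return np.array(
            [state.UF[c] for c in CATS] + zeros
            + [state.MFP[c] for c in CATS] + zeros
            + [state.FP[c] for c in CATS] + zeros
            + [state.DsbAo, state.DsbBo, state.DsbCGr, state.DsbDr]
        )

    def full_state(self, y: np.ndarray) -> np.ndarray:
        a_tot, b_tot, cg_tot, d_tot = self.totals
        e = self._e
        return np.concatenate(
            [y, [a_tot - y[e], b_tot - y[e + 1], cg_tot - y[e + 2], d_tot - y[e + 3]]]
        )

    def state_from_vector(self, y: np.ndarray) -> ModelState:
        if self.extra_classes:
            raise NotImplementedError(
                "ModelState covers the three native categories only"
            )
        a_tot, b_tot, cg_tot, d_tot = self.totals
        clip = lambda x: max(float(x), 0.0)
        return ModelState(
            UF={c: clip(y[i]) for i, c in enumerate(CATS)},
            MFP={c: clip(y[3 + i]) for i, c in enumerate(CATS)},
            FP={c: clip(y[6 + i]) for i, c in enumerate(CATS)},
            DsbAo=clip(y[9]), DsbAr=clip(a_tot - y[9]),
            DsbBo=clip(y[10]), DsbBr=clip(b_tot - y[10]),
            DsbCGr=clip(y[11]), DsbCGo=clip(cg_tot - y[11]),
            DsbDr=clip(y[12]), DsbDo=clip(d_tot - y[12]),
        )

    # -- dynamics ------------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        a_tot, b_tot, cg_tot, d_tot = self.totals
        e = self._e
        uf, mfp = y[self.uf_slice], y[self.mfp_slice]
        ao, bo, cgr, dr = y[e], y[e + 1], y[e + 2], y[e + 3]

        r45 = self._k45 * uf * ao
        r678 = self._k678 * mfp * cgr
        r3 = p.k3 * (a_tot - ao) * bo
        r2 = p.k2 * (b_tot - bo)
        r9 = p.k9 * (cg_tot - cgr) * dr
        r10 = p.k10 * (d_tot - dr)

        dy = np.empty(e + 4)
        dy[self.uf_slice] = self._v - r45 + p.f_reduce * r678
        dy[self.mfp_slice] = (1.0 - self._p) * r45 - (p.f_success + p.f_reduce) * r678
        dy[self.fp_slice] = self._p * r45 + p.f_success * r678
        dy[e] = r3 - r45.sum()
        dy[e + 1] = r2 - r3
        dy[e + 2] = r9 - p.f_reduce * r678.sum()
        dy[e + 3] = r10 - r9
        return dy

    def flux_vector(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction fluxes (order :data:`FLUX_COLUMNS`) at a reduced state."""
        if self.extra_classes:
            raise NotImplementedError("flux table covers the native model only")
        p = self.params
        a_tot, b_tot, cg_tot, d_tot = self.totals
        uf, mfp = y[0:3], y[3:6]
        ao, bo, cgr, dr = y[9], y[10], y[11], y[12]
        r45 = self._k45 * uf * ao
        r678 = self._k678 * mfp * cgr
        return np.concatenate(
            [
                self._v,
                [p.k2 * (b_tot - bo), p.k3 * (a_tot - ao) * bo],
                self._p * r45,
                (1.0 - self._p) * r45,
                [p.f_success * r678[1], p.f_success * r678[2]],
                [p.f_futile * r678[1], p.f_futile * r678[2]],
                [p.f_reduce * r678[1], p.f_reduce * r678[2]],
                [p.k9 * (cg_tot - cgr) * dr, p.k10 * (d_tot - dr)],
            ]
        )

    def fluxes(self, state: ModelState) -> pd.Series:
        return pd.Series(
            self.flux_vector(self.reduced_state(state)), index=FLUX_COLUMNS
        )

    # -- integration ---------------------------------------------------------

    def simulate(
        self,
        horizon: float,
        n_points: int = 200,
        rtol: float = 1e-8,
        atol: float | None = None,
        events: list[Callable] | None = None,
        method: str = "LSODA",
    ):
        """Integrate for ``horizon`` minutes; returns the raw solver result."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        y0 = self.reduced_state(self.initial)
        if atol is None:
            scale = max(float(y0.max()), float(self._v.sum()) * horizon, 1.0)
            atol = 1e-12 * scale
        t_eval = np.linspace(0.0, horizon, n_points) if n_points else None
        sol = solve_ivp(
            self.rhs,
            (0.0, horizon),
            y0,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            events=events,
            dense_output=events is not None,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed at t={sol.t[-1] if len(sol.t) else 0} min: "
                f"{sol.message}"
            )
        return sol

    def trajectory(self, horizon: float, n_points: int = 200, **kwargs) -> Trajectory:
        if self.extra_classes:
            raise NotImplementedError("Trajectory tables cover the native model only")
        sol = self.simulate(horizon, n_points=n_points, **kwargs)
        full = np.array([self.full_state(y) for y in sol.y.T])
        fluxes = np.array([self.flux_vector(y) for y in sol.y.T])
        return Trajectory(
            t=sol.t,
            states=pd.DataFrame(full, columns=FULL_COLUMNS),
            fluxes=pd.DataFrame(fluxes, columns=FLUX_COLUMNS),
            params=self.params,
        )

    def find_steady_state(
        self, warmup: float = 1000.0, tol: float = 1e-12
    ) -> ModelState:
        """Locate the steady state of substrates and enzyme redox fractions.

        FP pools grow without bound, so the root search runs on the reduced
        state without FP; an integration warm-up provides the starting guess.
        """
        sol = self.simulate(warmup, n_points=0)
        y_end = sol.y[:, -1]
        n = self.n_classes
        idx = list(range(0, 2 * n)) + list(range(3 * n, 3 * n + 4))  # all but FP

        def residual(z):
            y = y_end.copy()
            y[idx] = z
            return self.rhs(0.0, y)[idx]

        result = root(residual, y_end[idx], method="hybr", tol=tol)
        if not result.success:
            raise RuntimeError(f"steady-state search failed: {result.message}")
        y = y_end.copy()
        y[idx] = result.x
        return self.state_from_vector(y)


def build_model(params: ModelParameters, initial: ModelState) -> DsbFoldingModel:
    """Assemble the mass-action network from parameters and an initial state."""
    return DsbFoldingModel(params, initial)


def simulate(model: DsbFoldingModel, horizon: float, **kwargs) -> Trajectory:
    """Integrate the model and return a :class:`Trajectory`."""
    return model.trajectory(horizon, **kwargs)


def substrate_influx_rates(
    demand: FoldingDemand | Mapping[Category, float], mu: float
) -> dict[Category, float]:
    """Per-category substrate synthesis rates (bonds/cell/min).

    At steady state, growth dilution sets the minimum synthesis rate
    v_i = mu * N_i, with mu converted from 1/h to 1/min.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    bonds = demand.kinetic_bonds if isinstance(demand, FoldingDemand) else _catdict(
        demand, CATS, "demand"
    )
    return {c: mu / 60.0 * bonds[c] for c in CATS}


def accumulation_fraction(
    traj: Trajectory,
    category: Category | str | int,
    *,
    norm: str = "synthesis",
    steady_state_pool: float | None = None,
) -> float:
    """Fraction of a substrate category left unprocessed at the horizon.

    Default normalisation ("synthesis"): (UF + MFP at the end) divided by the
    cumulative amount synthesised over the trajectory.  ``norm="steady_state"``
    divides by ``steady_state_pool`` (the category's steady-state abundance)
    instead.  Zero synthesis gives 0 by definition.
    """
    if isinstance(category, int):
        category = Category(f"cat{category}")
    category = Category(category)
    uf = float(traj.states[f"UF_{category.value}"].iloc[-1])
    mfp = float(traj.states[f"MFP_{category.value}"].iloc[-1])
    backlog = (uf - traj.states[f"UF_{category.value}"].iloc[0]) + (
        mfp - traj.states[f"MFP_{category.value}"].iloc[0]
    )
    if norm == "synthesis":
        synthesised = traj.params.v_syn[category] * (traj.t[-1] - traj.t[0])
        if synthesised <= 0:
            return 0.0
        return max(backlog, 0.0) / synthesised
    if norm == "steady_state":
        if not steady_state_pool or steady_state_pool <= 0:
            raise ValueError("steady_state norm needs a positive steady_state_pool")
        return max(backlog, 0.0) / steady_state_pool
    raise ValueError("norm must be 'synthesis' or 'steady_state'")


def proteome_doubling_time(
    traj: Trajectory, demand: FoldingDemand | Mapping[Category, float]
) -> float:
    """Time (min) for cumulative correct folding to match one doubling.

    Under dilution-balance influx v = mu*N the cell synthesises ln2*N of each
    pool over one reported doubling time, so the doubling-equivalent target
    for cumulative FP output is ln2 times the total kinetic bond demand.
    Returns ``math.inf`` if the target is not reached within the trajectory.
    """
    if isinstance(demand, FoldingDemand):
        target = math.log(2.0) * demand.total_kinetic_bonds
    else:
        target = math.log(2.0) * sum(demand.values())
    if target <= 0:
        return math.inf
    cum = traj.cumulative_fp()
    if cum[-1] < target:
        return math.inf
    return float(np.interp(target, cum, traj.t))


# ---------------------------------------------------------------------------
# unit conversions

def association_rate_to_cell_units(
    k_molar_per_second: float, volume_litres: float
) -> float:
    """Convert a second-order constant from M^-1 s^-1 to (molec/cell)^-1 min^-1."""
    if volume_litres <= 0:
        raise ValueError("volume must be positive")
    return k_molar_per_second * 60.0 / (Avogadro * volume_litres)


def association_rate_to_molar_units(
    k_cell_per_minute: float, volume_litres: float
) -> float:
    """Inverse of :func:`association_rate_to_cell_units`."""
    if volume_litres <= 0:
        raise ValueError("volume must be positive")
    return k_cell_per_minute * Avogadro * volume_litres / 60.0
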