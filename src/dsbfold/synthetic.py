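"""Synthetic proteomes, disulfide annotations and ground-truth kinetic conditions.

Every stage of the analysis is testable without external downloads: this
module generates data with the statistical shape of the real inputs — a
log-normal protein abundance spectrum rescaled to the growth-rate-dependent
theoretical total protein count, Dsb enzymes injected at realistic ppm
levels, a disulfide sub-proteome split roughly 2/3 : 1/4 : 1/10 over the
folding-difficulty categories, three overlapping evidence pseudo-sources
whose per-bond detection probability rises with protein abundance, and
ground-truth kinetic conditions whose rate constants sit a literature-like
one to two orders of magnitude above the analytic minimal requirements, so
that minimal-rate inference has something real to recover.

All generators are pure functions of their spec (the seed fully determines
the output); separate deterministic substreams per stage keep outputs stable
under reordering of calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .disulfides import (
    Category,
    FoldingDemand,
    ProteinDisulfideProfile,
    build_profiles,
    folding_demand,
    merge_bond_sources,
)
from .enzymes import DSB_UNIPROT, DsbLevels, extract_dsb_levels
from .inference import (
    EnzymePools,
    FeasibilityCriteria,
    default_ceilings,
    enzyme_pools,
    evaluate_feasibility,
)
from .model import CATS, ModelParameters, substrate_influx_rates
from .proteome import (
    DEFAULT_PROTEIN_DENSITY,
    CellSizeVariant,
    QuantitativeProteome,
    cell_size_from_growth_rate,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticAnnotations",
    "GroundTruthCondition",
    "generate_proteome",
    "generate_disulfide_annotations",
    "generate_synthesis_rates",
    "ground_truth_condition",
    "write_dataset",
]

LN2 = math.log(2.0)

#: Mean Dsb enzyme levels across published quantitative proteomes (ppm).
DEFAULT_DSB_PPM: dict[str, float] = {
    "DsbA": 696.0,
    "DsbB": 139.0,
    "DsbC": 144.0,
    "DsbD": 29.0,
    "DsbG": 27.0,
}

#: Default folding-difficulty mix: two thirds of disulfide proteins have
#: exactly the two cysteines of their bond.
DEFAULT_CATEGORY_MIX: dict[Category, float] = {
    Category.CAT1: 20.0 / 30.0,
    Category.CAT2: 7.0 / 30.0,
    Category.CAT3: 3.0 / 30.0,
}

_STAGE = {"proteome": 101, "bonds": 202, "detect": 203, "truth": 303, "synthesis": 404}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    growth_rate: float = 0.7  # 1/h
    n_proteins: int = 2000
    abundance_sigma: float = 2.0  # natural-log scale of the log-normal spectrum
    category_mix: Mapping[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    dsb_ppm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DSB_PPM))
    enzyme_noise_sigma: float = 0.15  # log-normal jitter on enzyme ppm
    n_disulfide_proteins: int = 80
    dsb_bond_fraction: float = 0.003  # disulfide bonds per total protein copies
    intermolecular_fraction: float = 0.05
    periplasmic_fraction: float = 0.9
    density: float = DEFAULT_PROTEIN_DENSITY
    low_coverage: bool = False  # emit a proteome failing the 50% coverage filter
    detect_midpoint_log10: float = 2.0  # copies at 50% per-source detection
    detect_slope: float = 1.2
    detect_max: float = 0.95
    margin_range: tuple[float, float] = (30.0, 180.0)
    f_futile: float = 1.0 / 3.0
    f_success: float = 1.0 / 3.0
    f_reduce: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        mix = {Category(k) if not isinstance(k, Category) else k: float(v)
               for k, v in self.category_mix.items()}
        if not math.isclose(sum(mix.values()), 1.0, rel_tol=1e-9):
            raise ValueError("category_mix must sum to 1")
        object.__setattr__(self, "category_mix", mix)
        if self.growth_rate <= 0:
            raise ValueError("growth rate must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE[stage], self.seed])


@dataclass(frozen=True)
class _BondPlan:
    protein_id: str
    category: Category
    cysteines: tuple[int, ...]
    bonds: tuple[tuple[int, object], ...]  # (cys_a, cys_b | "SELF")
    count_value: float


def _plan_disulfides(spec: SyntheticSpec) -> list[_BondPlan]:
    """Deterministic per-protein bond layout for the disulfide sub-proteome."""
    rng = spec.rng("bonds")
    cats = list(CATS)
    probs = [spec.category_mix[c] for c in cats]
    plans = []
    for i in range(spec.n_disulfide_proteins):
        pid = f"DSBP{i:04d}"
        if rng.random() < spec.intermolecular_fraction:
            pos = int(rng.integers(5, 200))
            plans.append(_BondPlan(pid, Category.CAT4, (pos,), ((pos, "SELF"),), 0.5))
            continue
        cat = cats[rng.choice(len(cats), p=probs)]
        if cat is Category.CAT1:
            cys = tuple(sorted(rng.choice(np.arange(5, 250), size=2, replace=False)))
            bonds = ((int(cys[0]), int(cys[1])),)
            count = 1.0
        elif cat is Category.CAT2:
            n_cys = int(rng.integers(3, 7))
            cys = tuple(sorted(rng.choice(np.arange(5, 250), size=n_cys, replace=False)))
            j = int(rng.integers(0, n_cys - 1))
            bonds = ((int(cys[j]), int(cys[j + 1])),)
            count = 1.0
        else:  # CAT3: bond skips at least one intervening cysteine
            n_cys = int(rng.integers(3, 7))
            cys = tuple(sorted(rng.choice(np.arange(5, 250), size=n_cys, replace=False)))
            j = int(rng.integers(0, n_cys - 2))
            k = int(rng.integers(j + 2, n_cys))
            bonds = ((int(cys[j]), int(cys[k])),)
            count = 1.0
        plans.append(_BondPlan(pid, cat, tuple(int(c) for c in cys), bonds, count))
    return plans


def generate_proteome(spec: SyntheticSpec) -> QuantitativeProteome:
    """A quantitative proteome at the theoretical total for its growth rate.

    Background abundances follow a log-normal spectrum; Dsb enzymes are
    injected at their (jittered) target ppm and the disulfide sub-proteome is
    rescaled so its abundance-weighted bond count is ``dsb_bond_fraction`` of
    total protein copies.  Total copies equal density x cell volume exactly
    (45% of it for a deliberately low-coverage proteome).
    """
    rng = spec.rng("proteome")
    volume = cell_size_from_growth_rate(spec.growth_rate, CellSizeVariant.COVERAGE)
    total = spec.density * volume
    if spec.low_coverage:
        total *= 0.45

    enzyme_ppm = {
        name: ppm * rng.lognormal(0.0, spec.enzyme_noise_sigma)
        for name, ppm in spec.dsb_ppm.items()
    }
    enzyme_copies = {
        DSB_UNIPROT[name]: ppm * total / 1e6 for name, ppm in enzyme_ppm.items()
    }

    plans = _plan_disulfides(spec)
    dsb_raw = pd.Series(
        rng.lognormal(0.0, spec.abundance_sigma, len(plans)),
        index=[p.protein_id for p in plans],
    )
    counts = pd.Series({p.protein_id: p.count_value for p in plans})
    target_bonds = spec.dsb_bond_fraction * total
    weighted = float((dsb_raw * counts).sum())
    dsb_copies = dsb_raw * (target_bonds / weighted)

    background_ids = [f"SYNP{i:04d}" for i in range(spec.n_proteins)]
    background = pd.Series(
        rng.lognormal(0.0, spec.abundance_sigma, spec.n_proteins), index=background_ids
    )
    remainder = total - sum(enzyme_copies.values()) - float(dsb_copies.sum())
    background *= remainder / background.sum()

    abundances = pd.concat([background, dsb_copies, pd.Series(enzyme_copies)])
    return QuantitativeProteome(
        condition_label=f"synthetic-mu{spec.growth_rate:g}-seed{spec.seed}",
        abundances=abundances,
        growth_rate=spec.growth_rate,
        strain="synthetic",
        source_study="dsbfold.synthetic",
    )


@dataclass(frozen=True)
class SyntheticAnnotations:
    """Bond evidence tables plus the ground truth behind them."""

    bond_tables: dict[str, pd.DataFrame]  # per pseudo-source
    location_table: dict[str, str]
    cysteines: dict[str, tuple[int, ...]]
    true_profiles: list[ProteinDisulfideProfile]


def generate_disulfide_annotations(
    spec: SyntheticSpec, proteome: QuantitativeProteome
) -> SyntheticAnnotations:
    """Three overlapping pseudo-source bond tables for the planned bonds.

    Each source observes each bond independently with a logistic detection
    probability in log10 abundance, echoing the better cross-study agreement
    for highly expressed proteins.  Bonds missed by all sources are assigned
    to the source with the highest draw so the union covers the truth.
    """
    rng = spec.rng("detect")
    plans = _plan_disulfides(spec)
    sources = ["uniprot", "labelling_ms_1", "labelling_ms_2"]

    location, cysteines, rows = {}, {}, {s: [] for s in sources}
    true_records = []
    for plan in plans:
        copies = proteome.copies(plan.protein_id) or 0.0
        logc = math.log10(max(copies, 1e-3))
        p_detect = spec.detect_max / (
            1.0 + math.exp(-spec.detect_slope * (logc - spec.detect_midpoint_log10))
        )
        periplasmic = rng.random() < spec.periplasmic_fraction
        location[plan.protein_id] = "secreted" if periplasmic else "cytoplasmic"
        cysteines[plan.protein_id] = plan.cysteines
        for cys_a, cys_b in plan.bonds:
            draws = rng.random(len(sources))
            hits = draws < p_detect
            if not hits.any():
                hits[int(draws.argmin())] = True
            for s, hit in zip(sources, hits):
                if hit:
                    rows[s].append(
                        {"protein_id": plan.protein_id, "cys_a": cys_a, "cys_b": cys_b}
                    )
            true_records.append((plan.protein_id, cys_a, cys_b))

    tables = {
        s: pd.DataFrame(rows[s], columns=["protein_id", "cys_a", "cys_b"])
        for s in sources
    }
    merged_truth = merge_bond_sources(
        {"truth": pd.DataFrame(true_records, columns=["protein_id", "cys_a", "cys_b"])}
    )
    true_profiles = build_profiles(merged_truth, cysteines, location)
    return SyntheticAnnotations(tables, location, cysteines, true_profiles)


def generate_synthesis_rates(
    spec: SyntheticSpec, proteome: QuantitativeProteome, ratio: float = 100.0
) -> dict[str, float]:
    """Ribosome-footprint-style synthesis rates for the Dsb enzymes.

    abundance = ratio x synthesis rate, with mild log-normal noise on the
    soluble enzymes; membrane enzymes get noise-free rates so the anchor
    estimate has a recoverable target.
    """
    rng = spec.rng("synthesis")
    out = {}
    for name, accession in DSB_UNIPROT.items():
        copies = proteome.copies(accession)
        if copies is None:
            continue
        noise = 1.0 if name in ("DsbB", "DsbD") else rng.lognormal(0.0, 0.05)
        out[accession] = copies / ratio * noise
    return out


@dataclass(frozen=True)
class GroundTruthCondition:
    """A feasible kinetic condition with known ground-truth rate constants."""

    label: str
    mu: float
    demand: FoldingDemand
    enzymes: DsbLevels
    pools: EnzymePools
    truth: ModelParameters
    proteome: QuantitativeProteome


def _analytic_rate_scales(
    v: np.ndarray,
    pools: EnzymePools,
    mu: float,
    spec: SyntheticSpec,
    threshold: float,
) -> np.ndarray:
    """Back-of-envelope minimal rates: flux / (pool x partner-pool or backlog cap)."""
    td = 60.0 * LN2 / mu
    j_total = v.sum()
    p_correct = np.array([1.0, 0.5, 0.0])
    j_iso = ((1.0 - p_correct) * v).sum()
    cap = threshold * td  # backlog cap per unit synthesis rate
    a, b, cg, d = pools.dsba, pools.dsbb, pools.dsbcg, pools.dsbd
    k45 = np.where(v > 0, 1.0 / (a * cap), 0.0)
    k678 = np.where(v[1:] > 0, (1.0 - p_correct[1:]) / (cg * cap), 0.0)
    return np.array(
        [
            j_total / b,  # k2
            j_total / (a * b),  # k3
            k45[0], k45[1], k45[2],
            k678[0], k678[1],
            spec.f_reduce * j_iso / (cg * d) if j_iso > 0 else 0.0,  # k9
            spec.f_reduce * j_iso / d if j_iso > 0 else 0.0,  # k10
        ]
    )


def ground_truth_condition(spec: SyntheticSpec) -> GroundTruthCondition:
    """Generate a condition guaranteed feasible under its own true rates.

    True rate constants are the analytic minimal scales multiplied by
    per-parameter margins drawn log-uniformly from ``spec.margin_range``
    (capped at the biochemical ceilings).  Feasibility under the truth is
    verified by simulation before the condition is emitted; an infeasible
    draw raises rather than returning a broken fixture.
    """
    rng = spec.rng("truth")
    proteome = generate_proteome(spec)
    annotations = generate_disulfide_annotations(spec, proteome)
    periplasmic = [p for p in annotations.true_profiles if p.periplasmic]
    demand = folding_demand(periplasmic, proteome)

    enzymes = extract_dsb_levels(proteome)
    pools = enzyme_pools(enzymes)
    mu = spec.growth_rate
    v = np.array(list(substrate_influx_rates(demand, mu).values()))

    criteria = FeasibilityCriteria()
    scales = _analytic_rate_scales(v, pools, mu, spec, criteria.accumulation_threshold)
    lo, hi = spec.margin_range
    margins = np.exp(rng.uniform(math.log(lo), math.log(hi), len(scales)))
    ceilings = default_ceilings(mu)
    rates = np.minimum(scales * margins, ceilings)
    # unconstrained reactions still get a positive literature-scale constant
    rates = np.where(rates > 0, rates, 0.1 * ceilings)

    base = ModelParameters(
        k2=1.0, k3=1.0, k45={c: 1.0 for c in CATS},
        k678={Category.CAT2: 1.0, Category.CAT3: 1.0}, k9=1.0, k10=1.0,
        v_syn=substrate_influx_rates(demand, mu),
        f_futile=spec.f_futile, f_success=spec.f_success, f_reduce=spec.f_reduce,
    )
    truth = base.with_rate_vector(rates)

    check = evaluate_feasibility(truth, pools, mu, criteria=criteria)
    if not check.feasible:
        raise RuntimeError(
            f"ground-truth condition (seed {spec.seed}) infeasible under its own "
            f"rates; binding constraint: {check.binding}"
        )
    return GroundTruthCondition(
        label=proteome.condition_label,
        mu=mu,
        demand=demand,
        enzymes=enzymes,
        pools=pools,
        truth=truth,
        proteome=proteome,
    )


def write_dataset(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Write the synthetic tables in the same TSV schemas the readers consume."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(spec)
    annotations = generate_disulfide_annotations(spec, proteome)
    synthesis = generate_synthesis_rates(spec, proteome)

    paths = {}
    frame = proteome.abundances.rename("copies_per_cell").rename_axis("protein_id").reset_index()
    frame["condition_label"] = proteome.condition_label
    frame["growth_rate"] = proteome.growth_rate
    paths["proteome"] = str(outdir / "proteome.tsv")
    frame.to_csv(paths["proteome"], sep="\t", index=False)

    for source, table in annotations.bond_tables.items():
        key = f"bonds_{source}"
        paths[key] = str(outdir / f"{key}.tsv")
        table.to_csv(paths[key], sep="\t", index=False)

    loc = pd.DataFrame(
        sorted(annotations.location_table.items()), columns=["protein_id", "location"]
    )
    paths["locations"] = str(outdir / "locations.tsv")
    loc.to_csv(paths["locations"], sep="\t", index=False)

    cys = pd.DataFrame(
        [
            {"protein_id": pid, "cysteines": ",".join(map(str, positions))}
            for pid, positions in sorted(annotations.cysteines.items())
        ]
    )
    paths["cysteines"] = str(outdir / "cysteines.tsv")
    cys.to_csv(paths["cysteines"], sep="\t", index=False)

    syn = pd.DataFrame(sorted(synthesis.items()), columns=["protein_id", "synthesis_rate"])
    paths["synthesis"] = str(outdir / "synthesis_rates.tsv")
    syn.to_csv(paths["synthesis"], sep="\t", index=False)
    return paths
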