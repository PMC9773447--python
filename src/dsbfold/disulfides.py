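"""The *E. coli* disulfide proteome: merging, counting and classifying bonds.

Disulfide-bond evidence comes from several sources (database curation and
labelling proteomics) that all identify the specific cysteine pair of each
bond, so records can be merged on (protein, cys_a, cys_b).  Counting rules for
the quantitative demand:

* alternative partners of a single cysteine collapse to one counted bond;
* a cysteine pairing with itself on another copy of the same protein counts 0.5;
* bonds between different proteins are tabulated but excluded from demand.

Bonds are classified into "folding difficulty" categories by the relative
position of the bonded cysteines among all cysteines of the protein: cat1
(exactly two cysteines, no mispairing possible), cat2 (bond between
consecutive cysteines but further cysteines present), cat3 (bond between
non-consecutive cysteines), cat4 (intermolecular; not considered for
kinetics).  Abundance-weighting the per-protein bond counts gives the
cell-wide oxidative folding demand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteome import QuantitativeProteome

__all__ = [
    "BondKind",
    "Category",
    "DisulfideRecord",
    "ProteinDisulfideProfile",
    "FoldingDemand",
    "merge_bond_sources",
    "count_protein_disulfides",
    "max_potential_disulfides",
    "classify_bond",
    "classify_difficulty",
    "build_profiles",
    "periplasmic_subset",
    "confidence_filter",
    "folding_demand",
    "read_bond_table",
    "read_dsb_sheet",
    "write_category_summary",
    "PERIPLASMIC_LABELS",
]

logger = logging.getLogger(__name__)

#: Location labels that qualify a protein as a potential Dsb substrate.
PERIPLASMIC_LABELS = frozenset({"secreted", "secreted outer membrane"})

#: Markers accepted in bond tables for non-standard partners.
SELF_MARKER = "SELF"
INTER_MARKER = "OTHER-PROTEIN"


class BondKind(str, Enum):
    INTRAMOLECULAR = "intramolecular"
    SELF_PAIR = "self_pair"          # one cysteine bonding its twin on another copy
    INTERMOLECULAR = "intermolecular"


class Category(str, Enum):
    """Folding-difficulty categories, in increasing risk of misfolding."""

    CAT1 = "cat1"
    CAT2 = "cat2"
    CAT3 = "cat3"
    CAT4 = "cat4"

    @property
    def rank(self) -> int:
        return int(self.value[-1])


KINETIC_CATEGORIES = (Category.CAT1, Category.CAT2, Category.CAT3)


@dataclass(frozen=True)
class DisulfideRecord:
    """One disulfide bond with its evidence sources.

    ``cys_a``/``cys_b`` are 1-based residue indices.  For a self-pairing bond
    ``cys_b`` equals ``cys_a`` and ``kind`` is SELF_PAIR; for an intermolecular
    bond ``cys_b`` is None.
    """

    protein_id: str
    cys_a: int
    cys_b: int | None
    kind: BondKind = BondKind.INTRAMOLECULAR
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.cys_a < 1:
            raise ValueError(f"residue index must be >= 1, got {self.cys_a}")
        if self.kind is BondKind.INTRAMOLECULAR:
            if self.cys_b is None or self.cys_b < 1:
                raise ValueError("intramolecular bond needs two residue indices")
            if self.cys_a > self.cys_b:
                object.__setattr__(self, "cys_a", self.cys_b)
                object.__setattr__(self, "cys_b", self.cys_a)
        if not self.sources:
            raise ValueError("a disulfide record must name at least one source")

    @property
    def count_value(self) -> float:
        """Contribution to the quantitative bond count of its protein."""
        if self.kind is BondKind.SELF_PAIR:
            return 0.5
        if self.kind is BondKind.INTERMOLECULAR:
            return 0.0
        return 1.0

    @property
    def key(self) -> tuple:
        return (self.protein_id, self.kind, self.cys_a, self.cys_b)


def _parse_partner(value) -> tuple[int | None, BondKind]:
    """Interpret the cys_b field of a raw bond row."""
    if isinstance(value, str):
        token = value.strip().upper()
        if token == SELF_MARKER:
            return None, BondKind.SELF_PAIR
        if token in (INTER_MARKER, "INTER"):
            return None, BondKind.INTERMOLECULAR
        value = int(token)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, BondKind.INTERMOLECULAR
    return int(value), BondKind.INTRAMOLECULAR


def merge_bond_sources(
    tables: Iterable[tuple[str, pd.DataFrame]] | Mapping[str, pd.DataFrame],
) -> list[DisulfideRecord]:
    """Merge per-source bond tables into unified records.

    Each table needs columns ``protein_id``, ``cys_a``, ``cys_b`` (``cys_b``
    may hold a residue index, ``SELF`` or ``OTHER-PROTEIN``).  Records naming
    the same protein and cysteine pair are unified with the union of source
    labels; malformed rows are logged and skipped.  The merge is idempotent
    and independent of table order.
    """
    if isinstance(tables, Mapping):
        tables = tables.items()
    merged: dict[tuple, DisulfideRecord] = {}
    for source, frame in tables:
        for row in frame.itertuples(index=False):
            try:
                cys_a = int(row.cys_a)
                partner, kind = _parse_partner(row.cys_b)
                if kind is BondKind.SELF_PAIR:
                    record = DisulfideRecord(
                        str(row.protein_id), cys_a, cys_a, kind, frozenset({source})
                    )
                elif kind is BondKind.INTERMOLECULAR:
                    record = DisulfideRecord(
                        str(row.protein_id), cys_a, None, kind, frozenset({source})
                    )
                else:
                    record = DisulfideRecord(
                        str(row.protein_id),
                        min(cys_a, partner),
                        max(cys_a, partner),
                        kind,
                        frozenset({source}),
                    )
            except (ValueError, TypeError) as err:
                logger.warning("skipping malformed bond row %r from %s: %s", row, source, err)
                continue
            existing = merged.get(record.key)
            if existing is not None:
                record = replace(existing, sources=existing.sources | record.sources)
            merged[record.key] = record
    return sorted(merged.values(), key=lambda r: (r.protein_id, r.cys_a, r.cys_b or 0))


def count_protein_disulfides(records: Sequence[DisulfideRecord]) -> float:
    """Quantitative disulfide count for one protein.

    Bonds sharing a cysteine (alternative partners) collapse to a single
    counted bond — implemented as connected components of the intramolecular
    bond graph.  Self-pairings add 0.5 each; intermolecular bonds add 0.
    """
    if not records:
        return 0.0
    proteins = {r.protein_id for r in records}
    if len(proteins) > 1:
        raise ValueError(f"records span multiple proteins: {sorted(proteins)}")

    adjacency: dict[int, set[int]] = defaultdict(set)
    for rec in records:
        if rec.kind is BondKind.INTRAMOLECULAR:
            adjacency[rec.cys_a].add(rec.cys_b)
            adjacency[rec.cys_b].add(rec.cys_a)

    seen: set[int] = set()
    components = 0
    for node in adjacency:
        if node in seen:
            continue
        components += 1
        stack = [node]
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            seen.add(current)
            stack.extend(adjacency[current] - seen)

    self_pairs = sum(1 for r in records if r.kind is BondKind.SELF_PAIR)
    return float(components) + 0.5 * self_pairs


_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def max_potential_disulfides(sequence: str) -> int:
    """Upper bound on disulfides: number of cysteines // 2."""
    sequence = sequence.strip().upper()
    invalid = set(sequence) - _AMINO_ACIDS
    if invalid:
        raise ValueError(f"invalid amino-acid characters: {sorted(invalid)}")
    return sequence.count("C") // 2


@dataclass
class ProteinDisulfideProfile:
    """All disulfide information for one protein."""

    protein_id: str
    cysteine_positions: tuple[int, ...]
    bonds: list[DisulfideRecord] = field(default_factory=list)
    location: str = ""

    def __post_init__(self) -> None:
        self.cysteine_positions = tuple(sorted(self.cysteine_positions))

    @property
    def periplasmic(self) -> bool:
        return self.location in PERIPLASMIC_LABELS

    @property
    def bond_count(self) -> float:
        return count_protein_disulfides(self.bonds)

    @property
    def category(self) -> Category:
        return classify_difficulty(self)

    def bond_categories(self) -> list[Category]:
        return [classify_bond(bond, self.cysteine_positions) for bond in self.bonds]


def classify_bond(bond: DisulfideRecord, cysteines: Sequence[int]) -> Category:
    """Folding-difficulty category of a single bond.

    Intermolecular bonds (including self-pairings across protein copies) are
    cat4.  For intramolecular bonds: cat1 if the protein has exactly two
    cysteines; cat2 if the bonded cysteines are adjacent in the sorted list of
    all cysteine positions; cat3 otherwise.
    """
    if bond.kind is not BondKind.INTRAMOLECULAR:
        return Category.CAT4
    positions = sorted(cysteines)
    if bond.cys_a not in positions or bond.cys_b not in positions:
        raise ValueError(
            f"bond ({bond.cys_a}, {bond.cys_b}) of {bond.protein_id} references "
            f"residues outside the cysteine list {positions}"
        )
    if len(positions) == 2:
        return Category.CAT1
    if positions.index(bond.cys_b) - positions.index(bond.cys_a) == 1:
        return Category.CAT2
    return Category.CAT3


def classify_difficulty(profile: ProteinDisulfideProfile) -> Category:
    """Protein-level category: the hardest non-cat4 bond category.

    A protein whose bonds are all intermolecular is cat4.  Raises if the
    profile has no bonds.
    """
    cats = profile.bond_categories()
    if not cats:
        raise ValueError(f"protein {profile.protein_id} has no bonds to classify")
    intra = [c for c in cats if c is not Category.CAT4]
    if not intra:
        return Category.CAT4
    return max(intra, key=lambda c: c.rank)


def build_profiles(
    records: Iterable[DisulfideRecord],
    cysteines: Mapping[str, Sequence[int]],
    locations: Mapping[str, str] | None = None,
) -> list[ProteinDisulfideProfile]:
    """Group merged records into per-protein profiles.

    ``cysteines`` maps protein ID to all cysteine positions; proteins whose
    bonds reference unknown cysteine lists fall back to the bonded positions
    themselves (logged), which classifies their bonds conservatively as cat1
    only when no other cysteines are known.
    """
    locations = locations or {}
    by_protein: dict[str, list[DisulfideRecord]] = defaultdict(list)
    for rec in records:
        by_protein[rec.protein_id].append(rec)
    profiles = []
    for pid, bonds in sorted(by_protein.items()):
        if pid in cysteines:
            positions = tuple(cysteines[pid])
        else:
            positions = tuple(
                sorted(
                    {b.cys_a for b in bonds if b.kind is BondKind.INTRAMOLECULAR}
                    | {b.cys_b for b in bonds if b.kind is BondKind.INTRAMOLECULAR}
                )
            )
            logger.info("no cysteine list for %s; using bonded positions only", pid)
        profiles.append(
            ProteinDisulfideProfile(pid, positions, bonds, locations.get(pid, ""))
        )
    return profiles


def periplasmic_subset(
    profiles: Iterable[ProteinDisulfideProfile],
    location_table: Mapping[str, str],
    *,
    missing: str = "drop",
) -> list[ProteinDisulfideProfile]:
    """Restrict to proteins annotated 'secreted' or 'secreted outer membrane'.

    ``missing`` controls proteins absent from the location table: ``"drop"``
    (default) removes them, ``"keep"`` retains them with a warning.
    """
    if missing not in ("drop", "keep"):
        raise ValueError("missing must be 'drop' or 'keep'")
    kept = []
    for profile in profiles:
        label = location_table.get(profile.protein_id)
        if label is None:
            if missing == "keep":
                logger.warning(
                    "protein %s missing from location table; kept", profile.protein_id
                )
                kept.append(profile)
            continue
        if label in PERIPLASMIC_LABELS:
            kept.append(replace_location(profile, label))
    return kept


def replace_location(
    profile: ProteinDisulfideProfile, location: str
) -> ProteinDisulfideProfile:
    return ProteinDisulfideProfile(
        profile.protein_id, profile.cysteine_positions, list(profile.bonds), location
    )


def confidence_filter(
    records: Iterable[DisulfideRecord], min_sources: int = 2
) -> list[DisulfideRecord]:
    """Keep records supported by at least ``min_sources`` evidence sources."""
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    return [r for r in records if len(r.sources) >= min_sources]


@dataclass(frozen=True)
class FoldingDemand:
    """Abundance-weighted oxidative folding demand for one condition.

    ``bonds_per_cell`` holds, per category, the total number of disulfide
    bonds a cell maintains (sum over proteins of quantitative bond count times
    copies per cell).  ``protein_copies`` are the per-category protein copies.
    cat4 (intermolecular) is tabulated but excluded from kinetic demand.
    """

    condition_label: str
    bonds_per_cell: Mapping[Category, float]
    protein_copies: Mapping[Category, float]

    def __post_init__(self) -> None:
        for mapping in (self.bonds_per_cell, self.protein_copies):
            for value in mapping.values():
                if value < 0:
                    raise ValueError("demand totals must be non-negative")

    @property
    def kinetic_bonds(self) -> dict[Category, float]:
        """Per-category bond demand entering the kinetic model (cat1-3)."""
        return {c: float(self.bonds_per_cell.get(c, 0.0)) for c in KINETIC_CATEGORIES}

    @property
    def total_kinetic_bonds(self) -> float:
        return sum(self.kinetic_bonds.values())


def folding_demand(
    profiles: Iterable[ProteinDisulfideProfile],
    proteome: QuantitativeProteome,
) -> FoldingDemand:
    """Multiply per-protein bond counts by copies per cell, per category.

    A protein's demand lands entirely in its (hardest) category.  Proteins
    missing from the proteome contribute zero and are logged.
    """
    bonds = {c: 0.0 for c in Category}
    copies = {c: 0.0 for c in Category}
    for profile in profiles:
        abundance = proteome.copies(profile.protein_id)
        if abundance is None:
            logger.info(
                "protein %s absent from proteome %s; contributes no demand",
                profile.protein_id,
                proteome.condition_label,
            )
            continue
        cat = profile.category
        bonds[cat] += profile.bond_count * abundance
        copies[cat] += abundance
    return FoldingDemand(proteome.condition_label, bonds, copies)


# ---------------------------------------------------------------------------
# I/O

def read_bond_table(path: str | Path, source: str, sep: str | None = None) -> pd.DataFrame:
    """Read one source's bond table (columns protein_id, cys_a, cys_b)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    required = {"protein_id", "cys_a", "cys_b"}
    if not required <= set(frame.columns):
        raise ValueError(f"bond table {path} must have columns {sorted(required)}")
    frame.attrs["source"] = source
    return frame


def read_dsb_sheet(path: str | Path, sep: str = "\t") -> list[DisulfideRecord]:
    """Read a wide disulfide-proteome sheet with per-source evidence flags.

    Layout: columns ``protein_id``, ``cys_a``, ``cys_b`` plus one 0/1 flag
    column per source named ``src_<label>``.  Returns merged records.
    """
    frame = pd.read_csv(path, sep=sep)
    flag_cols = [c for c in frame.columns if c.startswith("src_")]
    if not flag_cols:
        raise ValueError("DSB sheet needs at least one src_<label> flag column")
    tables = []
    for col in flag_cols:
        sub = frame.loc[frame[col].astype(int) == 1, ["protein_id", "cys_a", "cys_b"]]
        tables.append((col[len("src_"):], sub))
    return merge_bond_sources(tables)


def write_category_summary(
    profiles: Iterable[ProteinDisulfideProfile],
    path: str | Path,
    proteome: QuantitativeProteome | None = None,
) -> pd.DataFrame:
    """Write a per-category summary (protein counts, bond counts, demand)."""
    rows = []
    profiles = list(profiles)
    demand = folding_demand(profiles, proteome) if proteome is not None else None
    for cat in Category:
        members = [p for p in profiles if p.category is cat]
        row = {
            "category": cat.value,
            "n_proteins": len(members),
            "n_bonds": sum(p.bond_count for p in members),
        }
        if demand is not None:
            row["bonds_per_cell"] = demand.bonds_per_cell[cat]
            row["protein_copies_per_cell"] = demand.protein_copies[cat]
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame
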