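"""Quantitative proteome handling.

Absolute quantitative proteomes of *E. coli* report protein copy numbers per
cell (or concentrations convertible to copy numbers) together with the growth
rate of the culture.  Because cell volume varies linearly with growth rate,
copy numbers, ppm (copies per million total proteins) and molar concentrations
are interconvertible once the growth rate is known.  This module provides the
container for one quantitative proteome, the two published linear cell-size
regressions, unit conversions, and the coverage filter used to decide whether
a proteome is quantitatively complete enough for modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy.constants import Avogadro

__all__ = [
    "CellSizeVariant",
    "CellGeometry",
    "QuantitativeProteome",
    "CoverageReport",
    "cell_size_from_growth_rate",
    "copies_to_concentration",
    "to_ppm",
    "coverage_report",
    "read_proteome_table",
    "write_coverage_reports",
    "DEFAULT_PROTEIN_DENSITY",
]

#: Approximate total cellular protein density used for the theoretical total
#: protein count (proteins per um^3 of cell volume).  Configurable wherever it
#: is consumed; the default approximates published whole-cell calculations.
DEFAULT_PROTEIN_DENSITY = 3.0e6


class CellSizeVariant(str, Enum):
    """Which linear cell-size regression to use.

    ``COVERAGE`` (slope 1.44 um^3 h, intercept 1.90 um^3) is calibrated on
    growth rates 0.1-1.9 1/h and is used for proteome-coverage evaluation.
    ``CONCENTRATION`` (slope 1.83, intercept 1.74) is calibrated on 0.1-1.0 1/h
    and is used when converting concentrations to copies per cell.
    """

    COVERAGE = "coverage"
    CONCENTRATION = "concentration"


_VARIANTS = {
    CellSizeVariant.COVERAGE: (1.44, 1.90, (0.1, 1.9)),
    CellSizeVariant.CONCENTRATION: (1.83, 1.74, (0.1, 1.0)),
}


@dataclass(frozen=True)
class CellGeometry:
    """A cell volume together with the regression that produced it."""

    volume_um3: float
    variant: CellSizeVariant = CellSizeVariant.COVERAGE

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError(f"cell volume must be positive, got {self.volume_um3}")

    @property
    def volume_litres(self) -> float:
        return self.volume_um3 * 1e-15

    @classmethod
    def from_growth_rate(
        cls, mu: float, variant: CellSizeVariant | str = CellSizeVariant.COVERAGE
    ) -> "CellGeometry":
        variant = CellSizeVariant(variant)
        return cls(cell_size_from_growth_rate(mu, variant), variant)


def cell_size_from_growth_rate(
    mu: float, variant: CellSizeVariant | str = CellSizeVariant.COVERAGE
) -> float:
    """Estimate cell volume (um^3) from growth rate (1/h).

    Evaluates the selected linear regression of cell size on growth rate.
    Growth rates outside the variant's calibrated range trigger a warning but
    are still evaluated; negative growth rates are invalid.
    """
    variant = CellSizeVariant(variant)
    if mu < 0:
        raise ValueError(f"growth rate must be non-negative, got {mu}")
    slope, intercept, (lo, hi) = _VARIANTS[variant]
    if not lo <= mu <= hi:
        warnings.warn(
            f"growth rate {mu} 1/h outside the calibrated range "
            f"[{lo}, {hi}] of the {variant.value} regression",
            stacklevel=2,
        )
    return slope * mu + intercept


def copies_to_concentration(
    copies: float,
    geometry: CellGeometry | float,
    compartment_fraction: float = 1.0,
) -> float:
    """Convert copies per cell to a molar concentration.

    ``geometry`` may be a :class:`CellGeometry` or a volume in um^3.
    ``compartment_fraction`` restricts the dilution volume to a sub-cellular
    compartment (e.g. ~0.2 for the periplasm); 1.0 means whole cell.
    """
    if copies < 0:
        raise ValueError("copy number must be non-negative")
    if not 0 < compartment_fraction <= 1:
        raise ValueError("compartment_fraction must be in (0, 1]")
    volume_um3 = geometry.volume_um3 if isinstance(geometry, CellGeometry) else float(geometry)
    if volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    litres = volume_um3 * 1e-15 * compartment_fraction
    return copies / (Avogadro * litres)


def to_ppm(abundances: Mapping[str, float] | pd.Series) -> pd.Series:
    """Normalise copies per cell to parts per million of total protein.

    Returns a Series summing to 1e6.  Raises on an empty or all-zero proteome.
    """
    series = pd.Series(abundances, dtype=float)
    total = series.sum()
    if len(series) == 0 or total <= 0:
        raise ValueError("cannot compute ppm for an empty or all-zero proteome")
    return series * (1e6 / total)


@dataclass
class QuantitativeProteome:
    """One quantitative proteome: copies per cell plus condition metadata."""

    condition_label: str
    abundances: pd.Series
    growth_rate: float | None = None
    strain: str = ""
    source_study: str = ""

    def __post_init__(self) -> None:
        self.abundances = pd.Series(self.abundances, dtype=float)
        if self.abundances.index.has_duplicates:
            dupes = self.abundances.index[self.abundances.index.duplicated()].unique()
            raise ValueError(f"duplicate protein IDs in proteome: {list(dupes)[:5]}")
        if (self.abundances < 0).any():
            raise ValueError("protein abundances must be non-negative")
        if self.growth_rate is not None and self.growth_rate <= 0:
            raise ValueError("growth rate must be positive when present")

    @property
    def total_copies(self) -> float:
        return float(self.abundances.sum())

    def ppm(self) -> pd.Series:
        return to_ppm(self.abundances)

    def copies(self, protein_id: str) -> float | None:
        if protein_id in self.abundances.index:
            return float(self.abundances[protein_id])
        return None


class MissingGrowthRateError(ValueError):
    """Raised when an operation requires a growth rate the proteome lacks."""


@dataclass(frozen=True)
class CoverageReport:
    """Quantitative coverage of a proteome against the theoretical total."""

    condition_label: str
    reported_total: float
    theoretical_total: float

    @property
    def coverage(self) -> float:
        return self.reported_total / self.theoretical_total

    @property
    def passes(self) -> bool:
        # proteomes below 50% quantitative coverage are not used for modelling
        return self.coverage >= 0.5


def coverage_report(
    proteome: QuantitativeProteome,
    density: float = DEFAULT_PROTEIN_DENSITY,
) -> CoverageReport:
    """Compare reported total protein count to the growth-rate-derived total.

    The theoretical total is ``density * cell volume``, with the volume from
    the coverage-variant regression.  Proteomes without a growth rate cannot
    be evaluated and raise :class:`MissingGrowthRateError`.
    """
    if proteome.growth_rate is None:
        raise MissingGrowthRateError(
            f"proteome {proteome.condition_label!r} has no reported growth rate"
        )
    volume = cell_size_from_growth_rate(proteome.growth_rate, CellSizeVariant.COVERAGE)
    theoretical = density * volume
    return CoverageReport(proteome.condition_label, proteome.total_copies, theoretical)


# ---------------------------------------------------------------------------
# I/O

def read_proteome_table(
    path: str | Path,
    *,
    protein_col: str = "protein_id",
    copies_col: str = "copies_per_cell",
    condition_col: str = "condition_label",
    growth_rate_col: str = "growth_rate",
    strain_col: str = "strain",
    source_col: str = "source_study",
    sep: str | None = None,
) -> list[QuantitativeProteome]:
    """Read a delimited proteome table (one row per protein and condition).

    The delimiter is sniffed from the extension unless given.  Unknown columns
    are ignored.  If the condition column is absent the whole table is one
    proteome labelled after the file stem.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    if protein_col not in frame or copies_col not in frame:
        raise ValueError(
            f"proteome table needs columns {protein_col!r} and {copies_col!r}; "
            f"found {list(frame.columns)}"
        )
    if condition_col not in frame:
        frame = frame.assign(**{condition_col: path.stem})

    proteomes = []
    for label, group in frame.groupby(condition_col, sort=False):
        def _meta(col):
            if col in group:
                value = group[col].iloc[0]
                return None if pd.isna(value) else value
            return None

        mu = _meta(growth_rate_col)
        proteomes.append(
            QuantitativeProteome(
                condition_label=str(label),
                abundances=group.set_index(protein_col)[copies_col],
                growth_rate=float(mu) if mu is not None else None,
                strain=str(_meta(strain_col) or ""),
                source_study=str(_meta(source_col) or ""),
            )
        )
    return proteomes


def write_coverage_reports(reports: list[CoverageReport], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "condition_label": [r.condition_label for r in reports],
            "reported_total": [r.reported_total for r in reports],
            "theoretical_total": [r.theoretical_total for r in reports],
            "coverage": [r.coverage for r in reports],
            "passes": [r.passes for r in reports],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
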