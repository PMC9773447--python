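"""Dsb enzyme abundance: extraction from proteomes and membrane-enzyme estimation.

The soluble enzymes (DsbA, DsbC, DsbG) are well represented in quantitative
proteomes and are read out directly by Uniprot accession.  The membrane-bound
DsbB and DsbD are systematically under-reported, so their steady-state levels
are estimated from ribosome-footprint synthesis rates: assuming the synthesis
rate to steady-state abundance ratio is similar across Dsb proteins, the
ratio observed for anchor enzymes (DsbA and DsbG by default) is applied to
the membrane enzymes' synthesis rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteome import QuantitativeProteome

__all__ = [
    "DSB_UNIPROT",
    "EnzymeLevel",
    "DsbLevels",
    "extract_dsb_levels",
    "estimate_membrane_abundance",
    "summarize_levels",
    "read_synthesis_rates",
]

logger = logging.getLogger(__name__)

#: Uniprot accessions of the Dsb enzymes in E. coli K-12.
DSB_UNIPROT: dict[str, str] = {
    "DsbA": "P0AEG4",
    "DsbB": "P0A6M2",
    "DsbC": "P0AEG6",
    "DsbD": "P36655",
    "DsbG": "P77202",
}

MEMBRANE_ENZYMES = ("DsbB", "DsbD")
DEFAULT_ANCHORS = ("DsbA", "DsbG")


@dataclass(frozen=True)
class EnzymeLevel:
    """Abundance of one enzyme: ppm and copies per cell, with provenance."""

    ppm: float
    copies: float
    provenance: str = "measured"  # or "estimated"
    anchors: tuple[str, ...] = ()
    high_variance: bool = False

    def __post_init__(self) -> None:
        if self.ppm < 0 or self.copies < 0:
            raise ValueError("enzyme levels must be non-negative")


@dataclass
class DsbLevels:
    """Per-enzyme abundance levels for one condition."""

    condition_label: str = ""
    levels: dict[str, EnzymeLevel] = field(default_factory=dict)

    def __getitem__(self, enzyme: str) -> EnzymeLevel:
        return self.levels[enzyme]

    def __contains__(self, enzyme: str) -> bool:
        return enzyme in self.levels

    def copies(self, enzyme: str) -> float:
        return self.levels[enzyme].copies

    def ppm(self, enzyme: str) -> float:
        return self.levels[enzyme].ppm

    @property
    def missing(self) -> list[str]:
        return [e for e in DSB_UNIPROT if e not in self.levels]


def extract_dsb_levels(proteome: QuantitativeProteome) -> DsbLevels:
    """Read Dsb enzyme levels directly from a proteome by Uniprot ID.

    Enzymes absent from the proteome are simply left out of the result
    (``DsbLevels.missing`` lists them).
    """
    ppm = proteome.ppm()
    result = DsbLevels(proteome.condition_label)
    for enzyme, accession in DSB_UNIPROT.items():
        copies = proteome.copies(accession)
        if copies is None:
            continue
        result.levels[enzyme] = EnzymeLevel(float(ppm[accession]), copies, "measured")
    return result


def estimate_membrane_abundance(
    synthesis: Mapping[str, float],
    levels: DsbLevels,
    *,
    anchors: Sequence[str] = DEFAULT_ANCHORS,
    targets: Sequence[str] = MEMBRANE_ENZYMES,
    method: str = "mean",
    force: bool = False,
    variance_fold: float = 2.0,
) -> DsbLevels:
    """Estimate membrane-enzyme abundance via the anchor-protein ratio.

    ``synthesis`` maps enzyme name (or Uniprot ID) to a synthesis rate in
    arbitrary units.  The abundance/synthesis ratio of each anchor is
    aggregated (arithmetic mean by default, ``method="geometric"`` for the
    geometric mean) and multiplied onto each target's synthesis rate.
    Measured targets are only overwritten with ``force=True``.  Estimates are
    flagged high-variance when anchor ratios spread more than
    ``variance_fold``-fold.
    """

    def _rate(enzyme: str) -> float | None:
        if enzyme in synthesis:
            return float(synthesis[enzyme])
        accession = DSB_UNIPROT.get(enzyme)
        if accession is not None and accession in synthesis:
            return float(synthesis[accession])
        return None

    ratios = {}
    for anchor in anchors:
        rate = _rate(anchor)
        if anchor not in levels or rate is None or rate <= 0:
            logger.info("anchor %s unusable (missing abundance or synthesis rate)", anchor)
            continue
        ratios[anchor] = levels.copies(anchor) / rate
    if not ratios:
        raise ValueError(f"no usable anchor among {list(anchors)}")

    values = np.array(list(ratios.values()))
    if method == "mean":
        ratio = float(values.mean())
    elif method == "geometric":
        ratio = float(np.exp(np.log(values).mean()))
    else:
        raise ValueError("method must be 'mean' or 'geometric'")
    high_variance = len(values) > 1 and values.max() / values.min() > variance_fold

    ppm_per_copy = None
    measured = [lv for lv in levels.levels.values() if lv.copies > 0]
    if measured:
        ppm_per_copy = np.median([lv.ppm / lv.copies for lv in measured])

    result = DsbLevels(levels.condition_label, dict(levels.levels))
    for target in targets:
        if target in result.levels and result.levels[target].provenance == "measured" and not force:
            continue
        rate = _rate(target)
        if rate is None:
            logger.info("no synthesis rate for %s; cannot estimate", target)
            continue
        copies = ratio * rate
        ppm = copies * ppm_per_copy if ppm_per_copy is not None else 0.0
        result.levels[target] = EnzymeLevel(
            float(ppm),
            float(copies),
            "estimated",
            anchors=tuple(ratios),
            high_variance=high_variance,
        )
    return result


def summarize_levels(panels: Iterable[DsbLevels], unit: str = "ppm") -> pd.DataFrame:
    """Descriptive statistics per enzyme across a panel of conditions."""
    if unit not in ("ppm", "copies"):
        raise ValueError("unit must be 'ppm' or 'copies'")
    records: dict[str, list[float]] = {e: [] for e in DSB_UNIPROT}
    n = 0
    for panel in panels:
        n += 1
        for enzyme, level in panel.levels.items():
            records[enzyme].append(getattr(level, unit))
    if n == 0:
        raise ValueError("need at least one panel of enzyme levels")
    rows = []
    for enzyme, values in records.items():
        if not values:
            continue
        arr = np.array(values)
        rows.append(
            {
                "enzyme": enzyme,
                "n": len(arr),
                "mean": arr.mean(),
                "median": float(np.median(arr)),
                "min": arr.min(),
                "max": arr.max(),
            }
        )
    return pd.DataFrame(rows).set_index("enzyme")


def read_synthesis_rates(path: str | Path, sep: str | None = None) -> dict[str, float]:
    """Read a two-column (protein_id, synthesis_rate) table."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise ValueError("synthesis-rate table needs two columns")
    ids, rates = frame.columns[:2]
    out = dict(zip(frame[ids].astype(str), frame[rates].astype(float)))
    if any(v < 0 for v in out.values()):
        raise ValueError("synthesis rates must be non-negative")
    return out
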