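"""End-to-end orchestration: ingest -> annotate -> enzymes -> infer -> capacity.

A :class:`RunConfig` (YAML-loadable) names the inputs and thresholds; the
pipeline executes the stages in a fixed order, writes every stage output as
TSV into the output directory and records a run manifest with the resolved
configuration, package version and SHA-256 hash of every file it wrote, so
identical configs and inputs yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .capacity import ConditionModel, capacity_table
from .disulfides import (
    build_profiles,
    confidence_filter,
    folding_demand,
    merge_bond_sources,
    periplasmic_subset,
    write_category_summary,
)
from .enzymes import estimate_membrane_abundance, extract_dsb_levels, read_synthesis_rates
from .inference import (
    build_rate_table,
    enzyme_pools,
    infer_minimal_rates,
    pseudo_first_order,
    write_rate_table,
    FeasibilityCriteria,
)
from .proteome import (
    DEFAULT_PROTEIN_DENSITY,
    coverage_report,
    read_proteome_table,
    write_coverage_reports,
)
from .synthetic import SyntheticSpec, write_dataset

__all__ = ["RunConfig", "StageFailure", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one pipeline run (schema version 1)."""

    output_dir: str
    proteome: str | None = None
    bonds: dict[str, str] = field(default_factory=dict)  # source label -> path
    locations: str | None = None
    cysteines: str | None = None
    synthesis_rates: str | None = None
    synthetic_seed: int | None = None  # generate inputs instead of reading them
    density: float = DEFAULT_PROTEIN_DENSITY
    compartment_fraction: float = 0.2
    min_sources: int = 2
    accumulation_threshold: float = 0.005
    doubling_slack: float = 0.05
    f_futile: float = 1.0 / 3.0
    f_success: float = 1.0 / 3.0
    f_reduce: float = 1.0 / 3.0
    anchors: tuple[str, ...] = ("DsbA", "DsbG")
    capacity_categories: tuple[str, ...] = ("cat1", "cat2", "cat3")
    schema_version: int = 1

    def __post_init__(self) -> None:
        for name in ("accumulation_threshold", "doubling_slack"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        if self.proteome is None and self.synthetic_seed is None:
            raise ValueError("config needs either input paths or a synthetic_seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve_inputs(self) -> "RunConfig":
        """Materialise synthetic inputs, then check that all paths exist."""
        cfg = dataclasses.replace(self)
        if cfg.synthetic_seed is not None and cfg.proteome is None:
            outdir = Path(cfg.output_dir) / "synthetic_inputs"
            paths = write_dataset(SyntheticSpec(seed=cfg.synthetic_seed), outdir)
            cfg.proteome = paths["proteome"]
            cfg.bonds = {
                key[len("bonds_"):]: path
                for key, path in paths.items()
                if key.startswith("bonds_")
            }
            cfg.locations = paths["locations"]
            cfg.cysteines = paths["cysteines"]
            cfg.synthesis_rates = paths["synthesis"]
        for label, path in [("proteome", cfg.proteome), ("locations", cfg.locations),
                            ("cysteines", cfg.cysteines)] + list(cfg.bonds.items()):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} input not found: {path}")
        return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config = config.resolve_inputs()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("ingest")
        proteomes = read_proteome_table(config.proteome)
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise StageFailure("ingest", err) from err

    try:
        _stage("coverage")
        reports = [coverage_report(p, config.density) for p in proteomes]
        outputs["coverage"] = outdir / "coverage.tsv"
        write_coverage_reports(reports, outputs["coverage"])
        usable = [p for p, r in zip(proteomes, reports) if r.passes]
        if not usable:
            raise ValueError("no proteome passes the 50% coverage filter")
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure("coverage", err) from err

    try:
        _stage("annotate")
        tables = {
            source: pd.read_csv(path, sep="\t") for source, path in config.bonds.items()
        }
        records = merge_bond_sources(tables)
        records = confidence_filter(records, config.min_sources)
        cys = {}
        if config.cysteines:
            frame = pd.read_csv(config.cysteines, sep="\t")
            cys = {
                row.protein_id: tuple(int(x) for x in str(row.cysteines).split(","))
                for row in frame.itertuples()
            }
        locations = {}
        if config.locations:
            frame = pd.read_csv(config.locations, sep="\t")
            locations = dict(zip(frame.protein_id, frame.location))
        profiles = build_profiles(records, cys, locations)
        profiles = periplasmic_subset(profiles, locations)
        outputs["categories"] = outdir / "category_summary.tsv"
        write_category_summary(profiles, outputs["categories"], usable[0])
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure("annotate", err) from err

    try:
        _stage("enzymes")
        panels = {}
        for proteome in usable:
            levels = extract_dsb_levels(proteome)
            if config.synthesis_rates and levels.missing:
                rates = read_synthesis_rates(config.synthesis_rates)
                levels = estimate_membrane_abundance(
                    rates, levels, anchors=config.anchors
                )
            panels[proteome.condition_label] = levels
        enz_frame = pd.DataFrame(
            {
                label: {name: lv.ppm for name, lv in panel.levels.items()}
                for label, panel in panels.items()
            }
        )
        outputs["enzymes"] = outdir / "enzyme_levels_ppm.tsv"
        enz_frame.to_csv(outputs["enzymes"], sep="\t")
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure("enzymes", err) from err

    try:
        _stage("infer")
        criteria = FeasibilityCriteria(
            accumulation_threshold=config.accumulation_threshold,
            doubling_slack=config.doubling_slack,
        )
        rows, growth, conditions = {}, {}, []
        for proteome in usable:
            demand = folding_demand(profiles, proteome)
            pools = enzyme_pools(panels[proteome.condition_label])
            params = infer_minimal_rates(
                demand, pools, proteome.growth_rate,
                criteria=criteria,
                f_futile=config.f_futile, f_success=config.f_success,
                f_reduce=config.f_reduce,
            )
            rows[proteome.condition_label] = pseudo_first_order(params, pools)
            growth[proteome.condition_label] = proteome.growth_rate
            conditions.append(
                ConditionModel(
                    proteome.condition_label, params, pools,
                    proteome.growth_rate, proteome.total_copies,
                )
            )
        table = build_rate_table(rows, growth)
        outputs["rates"] = outdir / "rates.tsv"
        write_rate_table(table, outputs["rates"], summary=len(table) >= 2)
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure("infer", err) from err

    try:
        _stage("capacity")
        grid = capacity_table(
            conditions,
            config.capacity_categories,
            threshold=config.accumulation_threshold,
        )
        outputs["capacity"] = outdir / "capacity.tsv"
        grid.to_csv(outputs["capacity"], sep="\t", index=False)
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure("capacity", err) from err

    manifest = {
        "dsbfold_version": _version,
        "config": {
            key: (list(value) if isinstance(value, tuple) else value)
            for key, value in dataclasses.asdict(config).items()
        },
        "outputs": {name: str(path) for name, path in outputs.items()},
        "sha256": {name: _sha256(path) for name, path in outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
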