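"""End-to-end pipeline: filter -> annotate -> positional -> enrichment -> reports.

The pipeline is a thin orchestration over the library modules; every
output file is a pure view of the annotation table, so any stage can be
re-run in isolation.  Output files (TSV/JSON) are written with fixed column
orders and are byte-reproducible for identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as _annotate
from . import enrichment as _enrichment
from . import positional as _positional
from . import reports as _reports
from . import tags as _tags
from .genome import BiotypeTaxonomy, read_gtf

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    gtf: str
    tags: str
    outdir: str
    taxonomy_tsv: str | None = None
    enrichment_level: str = "major_class"
    enrichment_family: str = "global"
    fdr: float = 0.01
    strata: list[tuple[str, str]] = field(
        default_factory=lambda: [list(s) for s in _positional.DEFAULT_STRATA]
    )
    rounding: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise PipelineConfigError(f"fdr must lie in (0, 1), got {self.fdr}")
        if self.rounding < 0:
            raise PipelineConfigError("rounding must be >= 0")
        if self.enrichment_level not in ("major_class", "lnc_subclass"):
            raise PipelineConfigError(
                f"unknown enrichment level {self.enrichment_level!r}"
            )
        if self.enrichment_family not in ("global", "per_vector"):
            raise PipelineConfigError(
                f"unknown multiplicity family {self.enrichment_family!r}"
            )
        self.strata = [tuple(s) for s in self.strata]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns the paths of all written outputs.

    Raises :class:`PipelineConfigError` for configuration problems and
    propagates data errors from the stage modules.
    """
    for p in (config.gtf, config.tags):
        if not Path(p).exists():
            raise PipelineConfigError(f"input path does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxonomy = (
        BiotypeTaxonomy.from_tsv(config.taxonomy_tsv)
        if config.taxonomy_tsv
        else BiotypeTaxonomy()
    )
    annset = read_gtf(config.gtf, taxonomy=taxonomy)
    logger.info("annotation: %d genes on %d chromosomes", len(annset), len(annset.chromosomes))

    raw = _tags.read_tags(config.tags)
    integrations, report = _tags.filter_tags(raw)
    logger.info(
        "filter: n_input=%d n_retained=%d (+ discards unmapped=%d no_unique_hq=%d "
        "multi_hq=%d nonrepresentative=%d); n_input = n_retained + discards",
        report.n_input,
        report.n_retained,
        report.n_discarded_unmapped,
        report.n_discarded_no_unique_hq,
        report.n_discarded_multi_hq,
        report.n_discarded_nonrepresentative,
    )

    hits = _annotate.annotate_frame(integrations, annset)
    n_genic = int(hits.loc[hits["is_primary"]].shape[0])
    n_inter = int(hits["intergenic"].sum())
    logger.info("annotate: %d genic, %d intergenic integrations", n_genic, n_inter)

    profiles = _positional.positional_profiles(hits, strata=config.strata)
    enr = _enrichment.enrichment_matrix(
        hits,
        level=config.enrichment_level,
        fdr=config.fdr,
        family=config.enrichment_family,
    )
    census = _reports.census_report(hits, taxonomy, places=config.rounding)
    nc_table, nc_summary = _reports.ncrna_subclass_report(hits, places=config.rounding)
    spliced = _reports.spliced_report(hits, places=config.rounding)

    paths = {
        "integrations": outdir / "integrations.tsv",
        "filter_report": outdir / "filter_report.json",
        "annotation": outdir / "annotation.tsv",
        "bed": outdir / "integration_points.bed",
        "positional": outdir / "positional_profiles.tsv",
        "enrichment_cells": outdir / "enrichment_cells.tsv",
        "enrichment_matrix": outdir / "enrichment_matrix.tsv",
        "census": outdir / "biotype_census.tsv",
        "ncrna_subclasses": outdir / "ncrna_subclasses.tsv",
        "ncrna_summary": outdir / "ncrna_summary.json",
        "spliced": outdir / "spliced_report.tsv",
        "diagnostics": outdir / "taxonomy_diagnostics.tsv",
    }
    _tags.write_integrations(integrations, paths["integrations"])
    report.to_json(paths["filter_report"])
    _annotate.write_annotation(hits, paths["annotation"])
    _annotate.write_bed(integrations, paths["bed"])
    _positional.write_profiles(profiles, paths["positional"])
    _enrichment.write_enrichment(enr, paths["enrichment_cells"], paths["enrichment_matrix"])
    census.to_csv(paths["census"], sep="\t", index=False)
    if len(nc_table):
        nc_table.to_csv(paths["ncrna_subclasses"], sep="\t")
    else:
        paths["ncrna_subclasses"].write_text("")
    Path(paths["ncrna_summary"]).write_text(json.dumps(nc_summary, indent=2) + "\n")
    spliced.to_csv(paths["spliced"], sep="\t", index=False)
    annset.diagnostics().to_csv(paths["diagnostics"], sep="\t", index=False)
    logger.info("pipeline complete: %d output files in %s", len(paths), outdir)
    return paths
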