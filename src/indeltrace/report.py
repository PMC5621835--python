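"""Consolidated run report: pydantic models and JSON emission.

The report schema is published alongside every report as
``report.schema.json`` (generated from the models), so downstream tooling
can validate reports without importing this package.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field


class RegressionReport(BaseModel):
    r2: float
    slope: float
    intercept: float
    pvalue: float
    n: int


class AnimalReport(BaseModel):
    animal_id: str
    target: str
    n_alleles_primary: int
    mutation_rate_primary: float = Field(
        description="1 - intact RPM fraction in the primary limb")
    identity_change_primary_secondary: float | None = None
    identity_change_secondary_tertiary: float | None = None


class LostRecoveredReport(BaseModel):
    transition: str
    n_lost: int
    n_recovered: int
    mean_unrecovered_fraction_percent: float


class TissueReport(BaseModel):
    n_panel_alleles: int
    n_single_enriched: int
    n_double_enriched: int
    mean_tissues_detected_high: float | None = None
    mean_tissues_detected_low: float | None = None
    fisher_decreasing: dict[str, float] = Field(default_factory=dict)
    fisher_increasing: dict[str, float] = Field(default_factory=dict)
    r2_heatmap: dict[str, dict[str, float | None]] = Field(default_factory=dict)


class RunReport(BaseModel):
    seed: int
    thresholds: dict[str, float]
    n_animals: int
    n_targets: int
    mean_alleles_per_primary_limb: float
    sd_alleles_per_primary_limb: float
    mean_identity_change_primary_secondary: float | None = None
    sd_identity_change_primary_secondary: float | None = None
    mean_identity_change_secondary_tertiary: float | None = None
    sd_identity_change_secondary_tertiary: float | None = None
    regressions: dict[str, RegressionReport] = Field(default_factory=dict)
    frequency_bin_counts: dict[str, int] = Field(default_factory=dict)
    fold_change_category_counts_low: dict[str, int] = Field(default_factory=dict)
    median_rpm_low_frequency: float | None = None
    median_rpm_all: float | None = None
    allele_sharing_histogram: dict[str, int] = Field(default_factory=dict)
    lost_recovered: list[LostRecoveredReport] = Field(default_factory=list)
    animals: list[AnimalReport] = Field(default_factory=list)
    tissue: TissueReport | None = None
    read_accounting: dict[str, int] = Field(default_factory=dict)


def write_report(report: RunReport, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(report.model_dump_json(indent=1))
    (outdir / "report.schema.json").write_text(
        json.dumps(RunReport.model_json_schema(), indent=1))
    return path
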