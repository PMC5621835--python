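"""End-to-end orchestration: demultiplex → call → quantify → fidelity → tissue.

Each stage reads and writes the TSV interchange formats defined in
:mod:`indeltrace.amplicon_io`, so stages are independently runnable; this
module also provides the in-memory fast path used by the simulator round
trip (reads stay as per-sample sequence counters rather than FASTQ files).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fidelity, quantify, tissue as tissue_mod
from .amplicon_io import (SampleSpec, TISSUE_COMPARTMENTS, demultiplex_counts,
                          iter_reads, read_sample_sheet, write_count_table)
from .calling import INTACT, Allele, AlleleCaller, consolidate_alleles
from .quantify import control_map_from_sheet, filter_alleles, normalize_rpm, rpm_vector
from .report import (AnimalReport, LostRecoveredReport, RegressionReport,
                     RunReport, TissueReport, write_report)
from .simulate import LIMB_ORDER, Cohort, SimulationConfig, emit_reads, simulate_cohort
from .targets import AmpliconTarget, load_targets

log = logging.getLogger("indeltrace")


@dataclass
class AnalysisParams:
    """Thresholds and flags shared by the pipeline stages."""

    min_reads: int = quantify.MIN_READS
    control_fold: float = quantify.CONTROL_FOLD
    strict_fold: bool = False
    enrichment_fold: float = tissue_mod.ENRICHMENT_FOLD
    min_discovery_reads: int = 2
    include_intact: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"min_reads": float(self.min_reads),
                "control_fold": float(self.control_fold),
                "enrichment_fold": float(self.enrichment_fold),
                "min_discovery_reads": float(self.min_discovery_reads)}


@dataclass
class TargetAnalysis:
    """Per-target products of the call + quantify stages."""

    target: AmpliconTarget
    samples: list[SampleSpec]
    master_alleles: list[Allele]
    counts: pd.DataFrame
    rpm: pd.DataFrame
    audit: pd.DataFrame
    per_animal_alleles: dict[str, list[str]] = field(default_factory=dict)
    read_accounting: Counter = field(default_factory=Counter)


def call_target(sample_counters: dict[str, Counter], samples: list[SampleSpec],
                target: AmpliconTarget, params: AnalysisParams,
                ) -> tuple[pd.DataFrame, list[Allele], dict[str, list[str]], Counter]:
    """Discover alleles per sample, consolidate per target, assign reads.

    Returns the raw count table, the master allele list, per-animal
    discovered allele names, and pooled read accounting.
    """
    caller = AlleleCaller(target, min_discovery_reads=params.min_discovery_reads)
    per_sample_alleles: dict[str, list[Allele]] = {}
    for s in samples:
        reads = sample_counters.get(s.sample_id, Counter())
        per_sample_alleles[s.sample_id] = caller.discover(reads) if reads else []
    master = consolidate_alleles(per_sample_alleles.values()) \
        if any(per_sample_alleles.values()) else []
    per_animal: dict[str, list[str]] = {}
    for s in samples:
        if s.role != "mutant":
            continue
        per_animal.setdefault(s.animal_id, [])
        per_animal[s.animal_id] = sorted(
            set(per_animal[s.animal_id])
            | {a.name for a in per_sample_alleles[s.sample_id]})
    rows = []
    accounting: Counter = Counter()
    for s in samples:
        reads = sample_counters.get(s.sample_id, Counter())
        result = caller.assign(reads, master)
        accounting["assigned"] += result.n_assigned
        accounting["error"] += result.n_error
        accounting["unalignable"] += result.n_unalignable
        log.info("sample %s: %d assigned, %d error, %d unalignable",
                 s.sample_id, result.n_assigned, result.n_error, result.n_unalignable)
        for name, c in sorted(result.counts.items()):
            rows.append({"target": target.name, "sample": s.sample_id,
                         "allele_name": name, "raw_count": int(c)})
    counts = pd.DataFrame(rows, columns=["target", "sample", "allele_name", "raw_count"])
    return counts, master, per_animal, accounting


def analyze_target(sample_counters: dict[str, Counter], samples: list[SampleSpec],
                   target: AmpliconTarget, params: AnalysisParams) -> TargetAnalysis:
    """Run call + quantify for one target pool."""
    counts, master, per_animal, accounting = call_target(
        sample_counters, samples, target, params)
    control_map = control_map_from_sheet(samples, target.name)
    kept, audit = filter_alleles(counts, control_map, min_reads=params.min_reads,
                                 control_fold=params.control_fold,
                                 strict_fold=params.strict_fold)
    ntc_ids = {s.sample_id for s in samples if s.role == "no_template_control"}
    rpm = normalize_rpm(kept[~kept["sample"].isin(ntc_ids)])
    return TargetAnalysis(target=target, samples=samples, master_alleles=master,
                          counts=counts, rpm=rpm, audit=audit,
                          per_animal_alleles=per_animal,
                          read_accounting=accounting)


def _animal_compartments(analysis: TargetAnalysis) -> dict[str, dict[str, dict[str, float]]]:
    """animal -> compartment -> RPM vector, from one target's RPM table."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for s in analysis.samples:
        if s.role != "mutant":
            continue
        vec = rpm_vector(analysis.rpm, s.sample_id, analysis.target.name)
        if vec:
            out.setdefault(s.animal_id, {})[s.compartment] = vec
    return out


def summarize(analyses: list[TargetAnalysis], params: AnalysisParams,
              seed: int = 0) -> RunReport:
    """Pool fidelity and tissue statistics across targets into a report."""
    animals: list[AnimalReport] = []
    id_ps: list[float] = []
    id_st: list[float] = []
    pairs = {"primary_secondary": ([], []), "secondary_tertiary": ([], []),
             "primary_tertiary": ([], [])}
    fold_records_low: Counter = Counter()
    bin_counts: Counter = Counter()
    primary_allele_rpms: list[float] = []
    sharing: Counter = Counter()
    lost_frames: list[pd.DataFrame] = []
    unrecovered_ps: list[float] = []
    panels: list[dict[str, dict[str, float]]] = []
    fold_categories_ps: dict[str, str] = {}
    fold_categories_st: dict[str, str] = {}
    enriched_all: dict[str, set[str]] = {}
    accounting: Counter = Counter()

    for analysis in analyses:
        accounting.update(analysis.read_accounting)
        compartments = _animal_compartments(analysis)
        for animal_id, comps in sorted(compartments.items()):
            primary = comps.get("primary")
            secondary = comps.get("secondary")
            tertiary = comps.get("tertiary")
            n_primary = sum(1 for a, v in (primary or {}).items()
                            if a != INTACT and v > 0)
            mutation_rate = 1.0 - (primary or {}).get(INTACT, 0.0) / quantify.RPM_SCALE
            rec = AnimalReport(animal_id=animal_id, target=analysis.target.name,
                               n_alleles_primary=n_primary,
                               mutation_rate_primary=mutation_rate)
            if primary:
                for a, v in primary.items():
                    if a != INTACT and v > 0:
                        bin_counts[fidelity.frequency_bin(v)] += 1
                        primary_allele_rpms.append(v)
            if primary and secondary:
                rec.identity_change_primary_secondary = fidelity.identity_change(
                    primary, secondary, include_intact=params.include_intact)
                id_ps.append(rec.identity_change_primary_secondary)
                xb, xa, _ = fidelity.regression_pairs(primary, secondary)
                pairs["primary_secondary"][0].extend(xb)
                pairs["primary_secondary"][1].extend(xa)
                profile = fidelity.fold_change_profile(primary, secondary)
                for _, row in profile.iterrows():
                    key = f"{analysis.target.name}:{row['allele_name']}"
                    fold_categories_ps[key] = row["category"]
                    if row["rpm_before"] > 0 and row["frequency_bin"] == "low":
                        fold_records_low[row["category"]] += 1
            if secondary and tertiary:
                rec.identity_change_secondary_tertiary = fidelity.identity_change(
                    secondary, tertiary, include_intact=params.include_intact)
                id_st.append(rec.identity_change_secondary_tertiary)
                xb, xa, _ = fidelity.regression_pairs(secondary, tertiary)
                pairs["secondary_tertiary"][0].extend(xb)
                pairs["secondary_tertiary"][1].extend(xa)
                profile = fidelity.fold_change_profile(secondary, tertiary)
                for _, row in profile.iterrows():
                    key = f"{analysis.target.name}:{row['allele_name']}"
                    fold_categories_st[key] = row["category"]
            if primary and tertiary:
                xb, xa, _ = fidelity.regression_pairs(primary, tertiary)
                pairs["primary_tertiary"][0].extend(xb)
                pairs["primary_tertiary"][1].extend(xa)
            # loss/recovery is only informative for animals with compartments
            # beyond the transition in question (three or more limb stages)
            if sum(1 for c in LIMB_ORDER if c in comps) >= 3:
                acc = fidelity.lost_recovered_accounting(comps)
                if not acc.empty:
                    lost_frames.append(acc)
                unrecovered_ps.append(fidelity.unrecovered_fraction(
                    acc, "primary->secondary"))
            panel = {t: comps[t] for t in TISSUE_COMPARTMENTS if t in comps}
            if panel:
                if "quaternary_hand" in comps:
                    panel["quaternary_hand"] = comps["quaternary_hand"]
                panels.append(panel)
                for allele in tissue_mod.panel_alleles(panel):
                    call = tissue_mod.call_enriched(panel, allele,
                                                    fold=params.enrichment_fold)
                    enriched_all[f"{analysis.target.name}:{allele}"] = call
            animals.append(rec)
        if len(analysis.per_animal_alleles) >= 2:
            shared = fidelity.allele_sharing(analysis.per_animal_alleles)
            sharing.update(Counter(shared.values))

    n_alleles = [a.n_alleles_primary for a in animals]
    report = RunReport(
        seed=seed, thresholds=params.as_dict(),
        n_animals=len(animals), n_targets=len(analyses),
        mean_alleles_per_primary_limb=float(np.mean(n_alleles)) if n_alleles else 0.0,
        sd_alleles_per_primary_limb=float(np.std(n_alleles, ddof=1)) if len(n_alleles) > 1 else 0.0,
        animals=animals,
        read_accounting=dict(accounting),
    )
    if id_ps:
        report.mean_identity_change_primary_secondary = float(np.mean(id_ps))
        report.sd_identity_change_primary_secondary = (
            float(np.std(id_ps, ddof=1)) if len(id_ps) > 1 else 0.0)
    if id_st:
        report.mean_identity_change_secondary_tertiary = float(np.mean(id_st))
        report.sd_identity_change_secondary_tertiary = (
            float(np.std(id_st, ddof=1)) if len(id_st) > 1 else 0.0)
    for name, (xb, xa) in pairs.items():
        if len(xb) >= 3:
            fit = fidelity.pooled_regression(xb, xa)
            report.regressions[name] = RegressionReport(
                r2=fit.r2, slope=fit.slope, intercept=fit.intercept,
                pvalue=fit.pvalue, n=fit.n)
    report.frequency_bin_counts = dict(bin_counts)
    report.fold_change_category_counts_low = dict(fold_records_low)
    if primary_allele_rpms:
        arr = np.array(primary_allele_rpms)
        report.median_rpm_all = float(np.median(arr))
        low = arr[arr < fidelity.LOW_RPM]
        if low.size:
            report.median_rpm_low_frequency = float(np.median(low))
    report.allele_sharing_histogram = {str(k): int(v) for k, v in sorted(sharing.items())}
    if lost_frames:
        acc = pd.concat(lost_frames, ignore_index=True)
        for transition, group in acc.groupby("lost_after"):
            report.lost_recovered.append(LostRecoveredReport(
                transition=str(transition), n_lost=int(len(group)),
                n_recovered=int(group["recovered"].sum()),
                mean_unrecovered_fraction_percent=float(
                    100.0 * np.mean(unrecovered_ps)) if unrecovered_ps else 0.0))
    if panels:
        report.tissue = _tissue_report(panels, enriched_all, fold_categories_ps,
                                       fold_categories_st, params)
    return report


def _tissue_report(panels, enriched_all, categories_ps, categories_st,
                   params: AnalysisParams) -> TissueReport:
    n_single = sum(1 for s in enriched_all.values() if len(s) == 1)
    n_double = sum(1 for s in enriched_all.values() if len(s) == 2)
    presence_high: list[int] = []
    presence_low: list[int] = []
    for panel in panels:
        hand = panel.get("quaternary_hand", {})
        for allele in tissue_mod.panel_alleles(panel):
            n_tissues = tissue_mod.tissue_presence(panel, allele)
            hand_rpm = hand.get(allele, 0.0)
            if hand_rpm > fidelity.HIGH_RPM:
                presence_high.append(n_tissues)
            elif 0 < hand_rpm < fidelity.LOW_RPM:
                presence_low.append(n_tissues)
    fisher_dec = tissue_mod.enrichment_change_association(
        enriched_all, categories_ps, fidelity.CATEGORY_DECREASED)
    fisher_inc = tissue_mod.enrichment_change_association(
        enriched_all, categories_st, fidelity.CATEGORY_INCREASED)
    heatmap = tissue_mod.tissue_r2_heatmap(panels)
    heat_dict = {r: {c: (None if pd.isna(v) else float(v))
                     for c, v in row.items()}
                 for r, row in heatmap.iterrows()}
    n_alleles = sum(len(tissue_mod.panel_alleles(p)) for p in panels)
    return TissueReport(
        n_panel_alleles=n_alleles,
        n_single_enriched=n_single, n_double_enriched=n_double,
        mean_tissues_detected_high=(float(np.mean(presence_high))
                                    if presence_high else None),
        mean_tissues_detected_low=(float(np.mean(presence_low))
                                   if presence_low else None),
        fisher_decreasing=dict(zip(fisher_dec["tissue"], fisher_dec["pvalue"])),
        fisher_increasing=dict(zip(fisher_inc["tissue"], fisher_inc["pvalue"])),
        r2_heatmap=heat_dict)


# -- entry points -------------------------------------------------------

def analyze_cohort(cohort: Cohort, params: AnalysisParams | None = None,
                   through_demux: bool = True) -> tuple[list[TargetAnalysis], RunReport]:
    """Simulate-to-report round trip, streaming reads in memory.

    Emitted reads (tag + amplicon, with errors) are pushed through the exact
    demultiplexer and the full calling/quantification stack.
    """
    params = params or AnalysisParams()
    analyses = []
    for target in cohort.targets:
        pool = cohort.samples[target.name]
        counters: dict[str, Counter] = {s.sample_id: Counter() for s in pool}
        unassigned = 0
        for _sample, _truth_counts, reads in emit_reads(cohort.truths, target,
                                                        pool, cohort.config):
            if through_demux:
                demuxed, n_un = demultiplex_counts(reads, pool,
                                                   cohort.primers[target.name])
                unassigned += n_un
                for sid, counter in demuxed.items():
                    counters[sid].update(counter)
            else:
                for r in reads:
                    counters[_sample.sample_id][r.sequence] += 1
        analysis = analyze_target(counters, pool, target, params)
        analysis.read_accounting["unassigned"] = unassigned
        analyses.append(analysis)
    report = summarize(analyses, params, seed=cohort.config.seed)
    return analyses, report


def run_pipeline(outdir: str | Path,
                 config: SimulationConfig | None = None,
                 reads_by_target: dict[str, Path] | None = None,
                 sheets_by_target: dict[str, Path] | None = None,
                 targets_path: Path | None = None,
                 params: AnalysisParams | None = None) -> RunReport:
    """Run the full pipeline and write the report bundle.

    Either simulate a cohort (``config`` given) or analyze existing FASTQ
    pools (``reads_by_target``/``sheets_by_target``/``targets_path``).
    Writes report.json, its schema, and per-stage TSV tables under
    ``outdir``; deterministic given the seed.
    """
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    params = params or AnalysisParams()
    if config is not None:
        cohort = simulate_cohort(config)
        analyses, report = analyze_cohort(cohort, params)
    else:
        if not (reads_by_target and sheets_by_target and targets_path):
            raise ValueError("need reads, sample sheets and a target registry "
                             "when not simulating")
        registry = load_targets(targets_path)
        analyses = []
        for tname, fastq in reads_by_target.items():
            if tname not in registry:
                raise ValueError(f"target {tname!r} missing from registry")
            pool = read_sample_sheet(sheets_by_target[tname])
            primer = registry[tname].reference[:20]
            counters, unassigned = demultiplex_counts(iter_reads(fastq), pool, primer)
            analysis = analyze_target(counters, pool, registry[tname], params)
            analysis.read_accounting["unassigned"] = unassigned
            analyses.append(analysis)
        report = summarize(analyses, params)
    for analysis in analyses:
        write_count_table(analysis.counts,
                          outdir / "tables" / f"{analysis.target.name}.counts.tsv")
        write_count_table(analysis.rpm,
                          outdir / "tables" / f"{analysis.target.name}.rpm.tsv")
        analysis.audit.to_csv(outdir / "tables" / f"{analysis.target.name}.audit.tsv",
                              sep="\t", index=False)
    write_report(report, outdir)
    return report
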