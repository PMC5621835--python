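"""Synthetic mosaic-embryo cohorts with full ground truth.

The generator emulates the statistical structure the analysis assumes:

* each animal is edited at one gRNA target during early development,
  acquiring a skewed spectrum of indel alleles (few common, many rare) whose
  limb frequencies follow a sparse Dirichlet alongside an intact class;
* a fraction of editing events draw from a small per-target "hotspot" pool
  shared across animals, so high-frequency alleles recur between animals
  while rare alleles are mostly private;
* regeneration resamples lineage frequencies around the previous limb with
  a Dirichlet of high concentration (near-faithful), and independently drops
  rare lineages with a small probability;
* tissue compartments split each lineage across six tissues with a sparse
  Dirichlet, so some rare lineages are effectively single-tissue;
* reads are tag + amplicon with i.i.d. substitution errors, drawn
  multinomially from compartment composition.

All randomness flows from one seed via fixed-offset substreams, so a fixed
seed yields byte-identical output.  Read sampling for a compartment is keyed
on the compartment's composition (not its label): compartments with
identical true composition receive identical reads, which makes the
perfect-copy regeneration limit exact end to end.
"""

from __future__ import annotations

import itertools
import json
import zlib
from collections.abc import Iterator
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon_io import (ReadRecord, SampleSpec, TISSUE_COMPARTMENTS,
                          write_fastq, write_sample_sheet)
from .calling import (Allele, AlleleCaller, Indel, INTACT, apply_indel,
                      build_allele, classify_non_mutant, indel_qualifies,
                      left_align, name_allele)
from .targets import AmpliconTarget, DNA_ALPHABET, save_targets, synthetic_target

LIMB_ORDER = ("primary", "secondary", "tertiary", "quaternary_hand")


class SimulationConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the study conditions.

    19 animals across 6 gRNA targets (2–4 animals each), allele count per
    animal ~ round(N(27.3, 10.2)), 12 animals followed through a tertiary
    limb and 4 through quaternary tissue panels, 50,000 reads per sample
    with a 5e-4 per-base substitution error rate.
    """

    seed: int = 1
    n_animals: int = 19
    n_targets: int = 6
    n_tertiary: int = 12
    n_tissue: int = 4
    mean_alleles_per_animal: float = 27.3
    sd_alleles_per_animal: float = 10.2
    hotspot_fraction: float = 0.2
    hotspot_pool_size: int = 8
    intact_concentration: float = 3.0
    lineage_frequency_concentration: float = 0.3
    regeneration_concentration: float = 25.0
    copy_regeneration: bool = False
    rare_loss_probability: float = 0.1
    rare_threshold: float = 0.016
    tissue_concentration: float = 0.3
    intact_tissue_concentration: float = 5.0
    pure_insertion_fraction: float = 0.15
    mean_deletion_length: float = 6.0
    max_deletion_length: int = 40
    mean_insertion_length: float = 2.0
    read_depth: int = 50_000
    substitution_error_rate: float = 5e-4
    tag_length: int = 5

    def __post_init__(self) -> None:
        probs = {"hotspot_fraction": self.hotspot_fraction,
                 "rare_loss_probability": self.rare_loss_probability,
                 "rare_threshold": self.rare_threshold,
                 "pure_insertion_fraction": self.pure_insertion_fraction,
                 "substitution_error_rate": self.substitution_error_rate}
        for nm, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"{nm} must lie in [0, 1], got {p}")
        concs = {"intact_concentration": self.intact_concentration,
                 "lineage_frequency_concentration": self.lineage_frequency_concentration,
                 "regeneration_concentration": self.regeneration_concentration,
                 "tissue_concentration": self.tissue_concentration,
                 "intact_tissue_concentration": self.intact_tissue_concentration}
        for nm, c in concs.items():
            if not c > 0:
                raise SimulationConfigError(f"{nm} must be > 0, got {c}")
        if self.read_depth < 1:
            raise SimulationConfigError("read_depth must be >= 1")
        if not 4 <= self.tag_length <= 6:
            raise SimulationConfigError("tag_length must lie in [4, 6]")
        if self.mean_alleles_per_animal < 0 or self.sd_alleles_per_animal < 0:
            raise SimulationConfigError("allele count parameters must be non-negative")
        if self.n_animals < 1 or self.n_targets < 1 or self.hotspot_pool_size < 1:
            raise SimulationConfigError("counts must be >= 1")
        if not 0 <= self.n_tissue <= self.n_tertiary <= self.n_animals:
            raise SimulationConfigError(
                "need n_tissue <= n_tertiary <= n_animals (tissue panels follow tertiary limbs)")


def tvd_percent(a: dict[str, float], b: dict[str, float]) -> float:
    """Total-variation distance between two composition dicts, in percent."""
    classes = set(a) | set(b)
    return 50.0 * sum(abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in classes)


@dataclass
class SimulationTruth:
    """Ground truth for one animal: alleles, per-compartment compositions,
    and the true pairwise identity-change values."""

    animal_id: str
    target_name: str
    alleles: list[Allele]
    compartments: dict[str, dict[str, float]] = field(default_factory=dict)
    identity_change_true: dict[str, float] = field(default_factory=dict)

    def classes(self) -> list[str]:
        return [INTACT] + [a.name for a in self.alleles]


# -- substreams ---------------------------------------------------------

def _rng(seed: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *offsets]))


_OFF_TARGET, _OFF_HOTSPOT, _OFF_ANIMAL, _OFF_READS = 11, 13, 17, 19


def _composition_rng(seed: int, animal_id: str, classes: list[str],
                     freqs: np.ndarray) -> np.random.Generator:
    """Read-sampling stream keyed on composition, not compartment label."""
    payload = ";".join(classes).encode() + np.round(freqs, 12).tobytes()
    return _rng(seed, _OFF_READS, zlib.crc32(animal_id.encode()), zlib.crc32(payload))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=n))


# -- indel spectrum -----------------------------------------------------

def draw_indel(rng: np.random.Generator, target: AmpliconTarget,
               config: SimulationConfig, caller: AlleleCaller | None = None) -> Indel:
    """Sample one editing outcome overlapping the cut window.

    Deletion length ~ geometric (mean ``mean_deletion_length``, capped),
    positioned to overlap the cut window; insertion length ~ geometric
    (mean ``mean_insertion_length``, possibly 0); pure insertions at the cut
    site with probability ``pure_insertion_fraction``.  Candidates are
    rejected unless the left-aligned indel still qualifies, the mutant
    amplicon has lost its perfect protospacer+PAM match, and realigning the
    mutant amplicon recovers the same canonical allele name (equal-length
    del+ins events, which align as substitutions, are rejected here).
    """
    if caller is None:
        caller = AlleleCaller(target)
    ref = target.reference
    w_lo, w_hi = target.cut_window
    for _ in range(500):
        if rng.random() < config.pure_insertion_fraction:
            ins_len = int(rng.geometric(1.0 / max(config.mean_insertion_length, 1.0)))
            indel = Indel(insertion=_random_bases(rng, ins_len),
                          insertion_after=target.cut_after)
        else:
            del_len = min(int(rng.geometric(1.0 / config.mean_deletion_length)),
                          config.max_deletion_length)
            lo = max(2, w_lo - del_len + 1)
            hi = min(len(ref) - del_len, w_hi)
            if lo > hi:
                continue
            s = int(rng.integers(lo, hi + 1))
            ins_len = int(rng.geometric(1.0 / (config.mean_insertion_length + 1.0))) - 1
            if ins_len == del_len:
                continue
            indel = Indel(del_start=s, del_end=s + del_len - 1,
                          insertion=_random_bases(rng, ins_len))
        indel = left_align(indel, ref)
        if not indel_qualifies(indel, target):
            continue
        mutant = apply_indel(ref, indel)
        if classify_non_mutant(mutant, target):
            continue
        recovered = caller.qualifying_indel(mutant)
        if recovered is None or name_allele(recovered) != name_allele(indel):
            continue
        return indel
    raise SimulationConfigError("could not sample a valid indel for this target")


def hotspot_pool(target: AmpliconTarget, config: SimulationConfig,
                 target_index: int = 0) -> list[Indel]:
    """Per-target pool of recurrent ("hotspot") editing outcomes."""
    rng = _rng(config.seed, _OFF_HOTSPOT, target_index)
    caller = AlleleCaller(target)
    pool: list[Indel] = []
    names: set[str] = set()
    while len(pool) < config.hotspot_pool_size:
        indel = draw_indel(rng, target, config, caller)
        nm = name_allele(indel)
        if nm not in names:
            names.add(nm)
            pool.append(indel)
    return pool


# -- per-animal simulation ----------------------------------------------

def simulate_animal(config: SimulationConfig, target: AmpliconTarget,
                    animal_id: str = "animal_01", animal_index: int = 0,
                    pool: list[Indel] | None = None,
                    caller: AlleleCaller | None = None) -> SimulationTruth:
    """Simulate one mosaic animal's primary-limb composition."""
    rng = _rng(config.seed, _OFF_ANIMAL, animal_index)
    if caller is None:
        caller = AlleleCaller(target)
    if pool is None:
        pool = hotspot_pool(target, config)
    n_alleles = int(round(rng.normal(config.mean_alleles_per_animal,
                                     config.sd_alleles_per_animal)))
    n_alleles = int(np.clip(n_alleles, 0, 200))
    alleles: list[Allele] = []
    names: set[str] = set()
    reps: set[str] = set()
    attempts = 0
    while len(alleles) < n_alleles and attempts < 50 * max(n_alleles, 1):
        attempts += 1
        if rng.random() < config.hotspot_fraction:
            indel = pool[int(rng.integers(len(pool)))]
        else:
            indel = draw_indel(rng, target, config, caller)
        nm = name_allele(indel)
        if nm in names:
            continue
        allele = build_allele(indel, target)
        if allele.representative in reps:
            continue
        names.add(nm)
        reps.add(allele.representative)
        alleles.append(allele)
    truth = SimulationTruth(animal_id=animal_id, target_name=target.name,
                            alleles=alleles)
    k = len(alleles)
    if k == 0:
        freqs = np.array([1.0])
    else:
        alpha = np.array([config.intact_concentration]
                         + [config.lineage_frequency_concentration] * k)
        freqs = rng.dirichlet(alpha)
    truth.compartments["primary"] = dict(zip(truth.classes(), freqs.tolist()))
    return truth


def simulate_regeneration(truth: SimulationTruth, config: SimulationConfig,
                          source: str = "primary", dest: str = "secondary",
                          rng: np.random.Generator | None = None) -> SimulationTruth:
    """Resample a compartment's composition to model limb regeneration.

    ``dest`` is drawn from Dirichlet(prev * regeneration_concentration)
    (or copied exactly when ``copy_regeneration``), then each lineage below
    ``rare_threshold`` in the source is independently dropped with
    ``rare_loss_probability``.  The true identity change between the two
    compartments is recorded.
    """
    if source not in truth.compartments:
        raise SimulationConfigError(f"compartment {source!r} not simulated yet")
    if rng is None:
        rng = _rng(config.seed, _OFF_ANIMAL, zlib.crc32(truth.animal_id.encode()),
                   zlib.crc32(dest.encode()))
    classes = truth.classes()
    prev = np.array([truth.compartments[source].get(c, 0.0) for c in classes])
    if config.copy_regeneration:
        new = prev.copy()
    else:
        new = np.zeros_like(prev)
        mask = prev > 0
        new[mask] = rng.dirichlet(prev[mask] * config.regeneration_concentration)
    if config.rare_loss_probability > 0:
        for i, c in enumerate(classes):
            if c == INTACT or prev[i] <= 0 or new[i] <= 0:
                continue
            if prev[i] < config.rare_threshold and rng.random() < config.rare_loss_probability:
                new[i] = 0.0
        total = new.sum()
        if total <= 0:
            new[0] = 1.0
        else:
            new = new / total
    truth.compartments[dest] = dict(zip(classes, new.tolist()))
    truth.identity_change_true[f"{source}_{dest}"] = tvd_percent(
        truth.compartments[source], truth.compartments[dest])
    return truth


def simulate_tissues(truth: SimulationTruth, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulationTruth:
    """Split the quaternary-limb composition across six tissue compartments.

    Each allele lineage gets a sparse Dirichlet weight vector over tissues
    (so some lineages are effectively single-tissue); the intact class is
    spread with a high concentration (unedited cells occur everywhere).
    """
    if "quaternary_hand" not in truth.compartments:
        raise SimulationConfigError("simulate the quaternary_hand compartment first")
    if rng is None:
        rng = _rng(config.seed, _OFF_ANIMAL, zlib.crc32(truth.animal_id.encode()),
                   zlib.crc32(b"tissues"))
    classes = truth.classes()
    hand = np.array([truth.compartments["quaternary_hand"].get(c, 0.0) for c in classes])
    n_t = len(TISSUE_COMPARTMENTS)
    weights = np.zeros((len(classes), n_t))
    for i, c in enumerate(classes):
        conc = (config.intact_tissue_concentration if c == INTACT
                else config.tissue_concentration)
        weights[i] = rng.dirichlet(np.full(n_t, conc))
    raw = hand[:, None] * weights
    for j, tissue in enumerate(TISSUE_COMPARTMENTS):
        col = raw[:, j]
        total = col.sum()
        comp = col / total if total > 0 else np.eye(1, len(classes), 0).ravel()
        truth.compartments[tissue] = dict(zip(classes, comp.tolist()))
    return truth


# -- cohorts ------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated study: targets, per-animal truths, per-target sample pools."""

    config: SimulationConfig
    targets: list[AmpliconTarget]
    truths: dict[str, SimulationTruth]
    samples: dict[str, list[SampleSpec]]      # target name -> pool sheet
    primers: dict[str, str]                   # target name -> forward primer

    def animals_for(self, target_name: str) -> list[str]:
        return [a for a, t in self.truths.items() if t.target_name == target_name]


def _tag_series(n: int, length: int) -> list[str]:
    """Deterministic tags with pairwise Hamming distance >= 2, so a single
    substitution error cannot bleed a read into another sample."""
    tags: list[str] = []
    for combo in itertools.product(DNA_ALPHABET, repeat=length):
        tag = "".join(combo)
        if len(set(tag)) == 1:      # skip homopolymer tags
            continue
        if any(sum(a != b for a, b in zip(tag, t)) < 2 for t in tags):
            continue
        tags.append(tag)
        if len(tags) == n:
            return tags
    raise SimulationConfigError("tag space exhausted")


def simulate_cohort(config: SimulationConfig, primer_length: int = 20) -> Cohort:
    """Simulate the full study: animals, regenerations, tissues, sample sheets."""
    targets = [synthetic_target(seed=config.seed * 1000 + j, name=f"t{j + 1}")
               for j in range(config.n_targets)]
    callers = [AlleleCaller(t) for t in targets]
    pools = [hotspot_pool(t, config, j) for j, t in enumerate(targets)]
    truths: dict[str, SimulationTruth] = {}
    for i in range(config.n_animals):
        j = i % config.n_targets
        animal_id = f"animal_{i + 1:02d}"
        truth = simulate_animal(config, targets[j], animal_id, animal_index=i,
                                pool=pools[j], caller=callers[j])
        simulate_regeneration(truth, config, "primary", "secondary")
        if i < config.n_tertiary:
            simulate_regeneration(truth, config, "secondary", "tertiary")
        if i < config.n_tissue:
            simulate_regeneration(truth, config, "tertiary", "quaternary_hand")
            simulate_tissues(truth, config)
        truths[animal_id] = truth

    samples: dict[str, list[SampleSpec]] = {}
    primers: dict[str, str] = {}
    for j, target in enumerate(targets):
        primers[target.name] = target.reference[:primer_length]
        pool_samples: list[SampleSpec] = []
        animal_ids = [a for a, t in truths.items() if t.target_name == target.name]
        n_needed = sum(len(truths[a].compartments) for a in animal_ids) + 2
        tags = iter(_tag_series(n_needed, config.tag_length))
        for a in animal_ids:
            for comp in truths[a].compartments:
                pool_samples.append(SampleSpec(
                    sample_id=f"{a}_{comp}", animal_id=a, compartment=comp,
                    tag=next(tags), role="mutant"))
        pool_samples.append(SampleSpec(
            sample_id=f"{target.name}_control", animal_id=f"{target.name}_control",
            compartment="primary", tag=next(tags), role="non_mutant_control"))
        pool_samples.append(SampleSpec(
            sample_id=f"{target.name}_ntc", animal_id=f"{target.name}_ntc",
            compartment="primary", tag=next(tags), role="no_template_control"))
        samples[target.name] = pool_samples
    return Cohort(config=config, targets=targets, truths=truths,
                  samples=samples, primers=primers)


# -- read emission ------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, n_errors: int) -> str:
    chars = list(seq)
    for pos in rng.integers(0, len(chars), size=n_errors):
        old = chars[pos]
        choices = [b for b in DNA_ALPHABET if b != old]
        chars[pos] = choices[int(rng.integers(3))]
    return "".join(chars)


def emit_sample(truth: SimulationTruth | None, target: AmpliconTarget,
                sample: SampleSpec, config: SimulationConfig,
                with_reads: bool = True,
                ) -> tuple[dict[str, int], list[ReadRecord]]:
    """Emit one sample's reads and its true per-class counts.

    Mutant samples draw ``read_depth`` reads multinomially from the
    compartment composition; non-mutant controls contain only intact
    sequence (plus errors); no-template controls emit nothing.
    """
    if sample.role == "no_template_control":
        return {}, []
    if sample.role == "non_mutant_control":
        classes = [INTACT]
        probs = np.array([1.0])
        seq_of = {INTACT: target.reference}
    else:
        if truth is None or sample.compartment not in truth.compartments:
            raise SimulationConfigError(
                f"sample {sample.sample_id!r} references unknown compartment "
                f"{sample.compartment!r}")
        comp = truth.compartments[sample.compartment]
        classes = [INTACT] + sorted(c for c in comp if c != INTACT)
        probs = np.array([comp.get(c, 0.0) for c in classes])
        seq_of = {INTACT: target.reference}
        for a in truth.alleles:
            seq_of[a.name] = apply_indel(target.reference, a.indel)
    rng = _composition_rng(config.seed, sample.animal_id, classes, probs)
    counts = rng.multinomial(config.read_depth, probs)
    records: list[ReadRecord] = []
    truth_counts: dict[str, int] = {}
    i = 0
    for cls, n in zip(classes, counts):
        truth_counts[cls] = int(n)
        if n == 0 or not with_reads:
            continue
        base_seq = sample.tag + seq_of[cls]
        if config.substitution_error_rate > 0:
            n_err = rng.binomial(len(base_seq), config.substitution_error_rate, size=n)
        else:
            n_err = np.zeros(n, dtype=int)
        for k in range(int(n)):
            seq = base_seq if n_err[k] == 0 else _mutate(base_seq, rng, int(n_err[k]))
            records.append(ReadRecord(id=f"{sample.sample_id}:{i}", sequence=seq,
                                      quality="I" * len(seq)))
            i += 1
    return truth_counts, records


def emit_reads(truths: dict[str, SimulationTruth], target: AmpliconTarget,
               samples: list[SampleSpec], config: SimulationConfig,
               with_reads: bool = True,
               ) -> Iterator[tuple[SampleSpec, dict[str, int], list[ReadRecord]]]:
    """Yield (sample, truth counts, reads) for every sample of one pool."""
    for sample in samples:
        truth = truths.get(sample.animal_id)
        yield sample, *emit_sample(truth, target, sample, config, with_reads)


def truth_table(cohort: Cohort) -> pd.DataFrame:
    """True counts/frequencies for every sample, as a tidy table."""
    rows = []
    for target in cohort.targets:
        for sample, counts, _reads in emit_reads(cohort.truths, target,
                                                 cohort.samples[target.name],
                                                 cohort.config, with_reads=False):
            truth = cohort.truths.get(sample.animal_id)
            comp = (truth.compartments[sample.compartment]
                    if truth is not None else {INTACT: 1.0})
            for cls, n in counts.items():
                rows.append({"target": target.name, "sample": sample.sample_id,
                             "allele_name": cls, "true_count": n,
                             "true_frequency": comp.get(cls, 1.0 if cls == INTACT else 0.0)})
    return pd.DataFrame(rows, columns=["target", "sample", "allele_name",
                                       "true_count", "true_frequency"])


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write FASTQ, sample sheets, truth tables and the target registry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    save_targets(cohort.targets, outdir / "targets.json")
    paths["targets"] = outdir / "targets.json"
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=1)
    for target in cohort.targets:
        pool = cohort.samples[target.name]
        write_sample_sheet(pool, outdir / f"{target.name}.samples.tsv")

        def pool_records():
            for _sample, _counts, reads in emit_reads(cohort.truths, target,
                                                      pool, cohort.config):
                yield from reads

        write_fastq(pool_records(), outdir / f"{target.name}.reads.fastq")
        paths[target.name] = outdir / f"{target.name}.reads.fastq"
    truth_table(cohort).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    return paths
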