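"""Read/sample I/O: FASTQ/FASTA parsing, inline-tag demultiplexing, tables.

Pooled amplicon reads carry a 4–6 nt sample-identifier tag at the 5' end,
immediately followed by the forward primer.  Demultiplexing is by exact
prefix match only — no mismatch rescue — because the downstream fidelity
statistics are sensitive to tag bleed-through.  The tag is trimmed before
allele calling; the primer is retained (it is part of the reference
amplicon).
"""

from __future__ import annotations

import gzip
from collections import Counter
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .targets import DNA_ALPHABET

COMPARTMENTS = ("primary", "secondary", "tertiary", "quaternary_hand",
                "nerve", "vessel", "bone_cartilage", "skin", "muscle",
                "blood", "larva")
ROLES = ("mutant", "non_mutant_control", "no_template_control")
TISSUE_COMPARTMENTS = ("nerve", "vessel", "bone_cartilage", "skin", "muscle", "blood")

COUNT_COLUMNS = ["target", "sample", "allele_name", "raw_count"]
RPM_COLUMNS = ["target", "sample", "allele_name", "raw_count", "rpm"]
SHEET_COLUMNS = ["sample_id", "animal_id", "compartment", "tag", "role"]


class SampleSheetError(ValueError):
    """Raised for malformed sample sheets (duplicate/invalid tags, etc.)."""


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing sample: an animal compartment with its inline tag."""

    sample_id: str
    animal_id: str
    compartment: str
    tag: str
    role: str = "mutant"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise SampleSheetError(f"unknown compartment {self.compartment!r}")
        if self.role not in ROLES:
            raise SampleSheetError(f"unknown role {self.role!r}")
        if not 4 <= len(self.tag) <= 6 or any(b not in DNA_ALPHABET for b in self.tag):
            raise SampleSheetError(f"tag {self.tag!r} must be 4-6 nt of A/C/G/T")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str | None = None


# -- sequence files -----------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_reads(path: str | Path, fmt: str | None = None) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ or FASTA file (gzip-transparent)."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), quality=qual)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ records; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# -- demultiplexing -----------------------------------------------------

def _validate_tags(samples: list[SampleSpec]) -> None:
    tags = [s.tag for s in samples]
    if len(set(tags)) != len(tags):
        dupes = sorted({t for t in tags if tags.count(t) > 1})
        raise SampleSheetError(f"duplicate tags in pool: {dupes}")


def demultiplex(reads: Iterable[ReadRecord | str], samples: list[SampleSpec],
                forward_primer: str, trim_tag: bool = True,
                ) -> tuple[dict[str, list[str]], int]:
    """Assign pooled reads to samples by exact tag+primer prefix match.

    A read belongs to sample ``s`` iff it begins with ``s.tag`` immediately
    followed by ``forward_primer``, exactly; anything else is unassigned.
    Returns per-sample read-sequence lists (tag trimmed by default, primer
    retained) and the unassigned count.
    """
    if not samples:
        raise SampleSheetError("sample list is empty")
    _validate_tags(samples)
    prefixes: dict[str, tuple[str, int]] = {}
    for s in samples:
        prefix = s.tag + forward_primer
        if prefix in prefixes:
            raise SampleSheetError(f"ambiguous tag+primer prefix {prefix!r}")
        prefixes[prefix] = (s.sample_id, len(s.tag))
    for p in prefixes:
        for q in prefixes:
            if p != q and q.startswith(p):
                raise SampleSheetError("one tag+primer prefix is a prefix of another")
    lengths = sorted({len(s.tag) + len(forward_primer) for s in samples})
    out: dict[str, list[str]] = {s.sample_id: [] for s in samples}
    unassigned = 0
    for rec in reads:
        seq = rec if isinstance(rec, str) else rec.sequence
        for plen in lengths:
            hit = prefixes.get(seq[:plen])
            if hit is not None:
                sample_id, tag_len = hit
                out[sample_id].append(seq[tag_len:] if trim_tag else seq)
                break
        else:
            unassigned += 1
    return out, unassigned


def demultiplex_counts(reads: Iterable[ReadRecord | str], samples: list[SampleSpec],
                       forward_primer: str) -> tuple[dict[str, Counter], int]:
    """Memory-lean demultiplexing into per-sample unique-sequence counters."""
    assigned, unassigned = demultiplex(reads, samples, forward_primer)
    return {sid: Counter(seqs) for sid, seqs in assigned.items()}, unassigned


# -- tables -------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {sorted(missing)}")
    samples = [SampleSpec(**{k: row[k] for k in SHEET_COLUMNS})
               for _, row in df.iterrows()]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise SampleSheetError("duplicate sample_id in sheet")
    return samples


def write_sample_sheet(samples: list[SampleSpec], path: str | Path) -> None:
    pd.DataFrame([{k: getattr(s, k) for k in SHEET_COLUMNS} for s in samples]
                 ).to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"target": str, "sample": str,
                                            "allele_name": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise SampleSheetError(f"count table missing columns: {sorted(missing)}")
    if (df["raw_count"] < 0).any():
        raise SampleSheetError("negative raw_count in count table")
    return df[list(dict.fromkeys(COUNT_COLUMNS + list(df.columns)))]


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
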