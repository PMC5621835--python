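"""Allele identification from amplicon reads.

The calling procedure mirrors a manual contig-based workflow as an explicit
algorithm:

1. Reads containing a perfect protospacer+PAM match are counted as the
   non-mutant (INTACT) class, regardless of substitutions elsewhere.
2. Remaining reads are globally aligned to the reference amplicon with
   affine gap penalties (match +2, mismatch −3, gap open −8, extend −1),
   indels left-aligned to a canonical placement.
3. An alignment yields an allele only if its indel footprint touches the
   *cut window* (PAM + three PAM-proximal protospacer bases); indels
   elsewhere are set aside as putative PCR/sequencing error.
4. Alleles are named canonically from deletion span and inserted bases
   ("D28-30", "I30+TTA", "D29-33+G") and represented by a fixed-length
   junction sequence (flanks around the indel, trimmed to the target's
   representative length) so that every read can be assigned to at most one
   allele by exact substring match.
5. Discovery iterates: tally qualifying indels among unexplained reads,
   promote the best-supported one to an allele, remove all reads containing
   its representative, repeat until no indel has enough support.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from Bio import Align

from .targets import AmpliconTarget, TargetError

# Alignment scoring (recorded configuration: the reimplementation of the
# original interactive contig assembly).  A gap of length L scores
# -(GAP_OPEN + L * GAP_EXTEND).
MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_OPEN = 8
GAP_EXTEND = 1

DEFAULT_MIN_READ_LENGTH = 30
DEFAULT_MAX_GAP = 100
DEFAULT_MIN_DISCOVERY_READS = 2

INTACT = "INTACT"


class ReadTooShortError(ValueError):
    """Read shorter than the alignable minimum."""


class AlleleError(ValueError):
    """Raised for invalid indel/allele constructions."""


@dataclass(frozen=True)
class Indel:
    """A deletion span and/or insertion on the reference amplicon.

    Coordinates are 1-based inclusive.  A pure insertion is anchored by
    ``insertion_after`` (the reference base it follows; 0 = before base 1);
    a combined deletion+insertion places the insertion at the deletion
    junction, so ``insertion_after`` stays unset.
    """

    del_start: int | None = None
    del_end: int | None = None
    insertion: str = ""
    insertion_after: int | None = None

    def __post_init__(self) -> None:
        if self.del_start is None and not self.insertion:
            raise AlleleError("empty indel: no deletion and no insertion")
        if (self.del_start is None) != (self.del_end is None):
            raise AlleleError("del_start and del_end must be set together")
        if self.del_start is not None:
            if self.del_start < 1 or self.del_start > self.del_end:
                raise AlleleError("invalid deletion span")
            if self.insertion_after is not None:
                raise AlleleError("combined indels anchor the insertion at the deletion site")
        else:
            if self.insertion_after is None or self.insertion_after < 0:
                raise AlleleError("pure insertion requires insertion_after >= 0")

    @property
    def deletion_length(self) -> int:
        if self.del_start is None:
            return 0
        return self.del_end - self.del_start + 1

    @property
    def footprint(self) -> tuple[int, int]:
        """Inclusive reference span affected; an insertion touches the two
        bases flanking its junction."""
        if self.del_start is not None:
            return (self.del_start, self.del_end)
        return (self.insertion_after, self.insertion_after + 1)

    @property
    def footprint_size(self) -> int:
        return self.deletion_length + len(self.insertion)


@dataclass(frozen=True)
class Allele:
    """A named indel with its fixed-length representative junction sequence."""

    indel: Indel
    name: str
    representative: str
    target: str


def name_allele(indel: Indel) -> str:
    """Canonical allele name: deletion span then inserted bases."""
    if indel.del_start is not None and indel.insertion:
        return f"D{indel.del_start}-{indel.del_end}+{indel.insertion}"
    if indel.del_start is not None:
        return f"D{indel.del_start}-{indel.del_end}"
    return f"I{indel.insertion_after}+{indel.insertion}"


def apply_indel(reference: str, indel: Indel) -> str:
    """Mutant amplicon sequence produced by the indel."""
    if indel.del_start is not None:
        if indel.del_end > len(reference):
            raise AlleleError("deletion extends past reference end")
        return reference[:indel.del_start - 1] + indel.insertion + reference[indel.del_end:]
    p = indel.insertion_after
    if p > len(reference):
        raise AlleleError("insertion anchor past reference end")
    return reference[:p] + indel.insertion + reference[p:]


def left_align(indel: Indel, reference: str) -> Indel:
    """Shift an indel to its leftmost equivalent placement.

    Pure deletions slide left while the base preceding the span equals the
    last deleted base; pure insertions rotate left through repeats.
    Combined deletion+insertion events have no scoring-equivalent shifts
    under affine gaps and are returned unchanged.
    """
    if indel.del_start is not None and indel.insertion:
        return indel
    if indel.del_start is not None:
        s, e = indel.del_start, indel.del_end
        while s > 1 and reference[s - 2] == reference[e - 1]:
            s -= 1
            e -= 1
        if s == indel.del_start:
            return indel
        return Indel(del_start=s, del_end=e)
    p, ins = indel.insertion_after, indel.insertion
    while p >= 1 and reference[p - 1] == ins[-1]:
        ins = reference[p - 1] + ins[:-1]
        p -= 1
    if p == indel.insertion_after:
        return indel
    return Indel(insertion=ins, insertion_after=p)


def indel_qualifies(indel: Indel, target: AmpliconTarget) -> bool:
    """True iff the indel footprint intersects the target's cut window."""
    w_lo, w_hi = target.cut_window
    f_lo, f_hi = indel.footprint
    return max(f_lo, w_lo) <= min(f_hi, w_hi)


def make_representative(indel: Indel, target: AmpliconTarget) -> str:
    """Fixed-length junction sequence representing the allele.

    The insertion (if any) plus reference flanks on both sides of the indel
    footprint, trimmed to ``target.representative_length``; symmetric where
    possible, with flank deficit near the amplicon ends compensated on the
    other side.
    """
    ref = target.reference
    rep_len = target.representative_length
    ins = indel.insertion
    if len(ins) > rep_len - 2:
        raise AlleleError("insertion too long for representative length")
    if indel.del_start is not None:
        left_end = indel.del_start - 1        # last kept ref base on the left
        right_start = indel.del_end + 1       # first kept ref base on the right
    else:
        left_end = indel.insertion_after
        right_start = indel.insertion_after + 1
    left_avail = left_end
    right_avail = len(ref) - right_start + 1
    flank_total = rep_len - len(ins)
    if left_avail + right_avail < flank_total:
        raise AlleleError(
            f"amplicon too short to represent indel {name_allele(indel)} "
            f"at length {rep_len}")
    want_left = (flank_total + 1) // 2
    want_right = flank_total - want_left
    if want_left > left_avail:
        want_right += want_left - left_avail
        want_left = left_avail
    elif want_right > right_avail:
        want_left += want_right - right_avail
        want_right = right_avail
    left = ref[left_end - want_left: left_end]
    right = ref[right_start - 1: right_start - 1 + want_right]
    return left + ins + right


def build_allele(indel: Indel, target: AmpliconTarget) -> Allele:
    return Allele(indel=indel, name=name_allele(indel),
                  representative=make_representative(indel, target),
                  target=target.name)


def classify_non_mutant(read: str, target: AmpliconTarget) -> bool:
    """True iff the read contains a perfect protospacer+PAM match."""
    if not read:
        raise AlleleError("empty read")
    return target.site in read


def default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def align_read(read: str, target: AmpliconTarget,
               aligner: Align.PairwiseAligner | None = None,
               min_read_length: int = DEFAULT_MIN_READ_LENGTH) -> Align.Alignment:
    """Global affine alignment of a (non-intact) read to the reference."""
    if len(read) < min_read_length:
        raise ReadTooShortError(f"read of length {len(read)} < {min_read_length}")
    if aligner is None:
        aligner = default_aligner()
    return aligner.align(target.reference, read)[0]


def _alignment_indels(alignment: Align.Alignment, read: str, reference: str) -> list[Indel]:
    """Indel events from an alignment.

    The alignment is scanned column by column; every maximal run of
    non-match columns (gaps and mismatches together) that contains at least
    one gap column becomes a single event whose deletion span is the
    reference consumed by the run and whose insertion is the read sequence
    consumed.  Mismatches adjacent to a gap are thereby folded into a
    combined deletion+insertion — the natural reading of a replacement
    event — while runs of pure mismatches remain substitutions and yield no
    event.
    """
    ref_blocks, read_blocks = alignment.aligned
    if len(ref_blocks) == 0:
        return []
    runs: list[list[int | bool]] = []   # [ref_lo, ref_hi, q_lo, q_hi, has_gap]

    def add(r_lo: int, r_hi: int, q_lo: int, q_hi: int, is_gap: bool) -> None:
        if r_hi == r_lo and q_hi == q_lo:
            return
        if runs and runs[-1][1] == r_lo and runs[-1][3] == q_lo:
            runs[-1][1], runs[-1][3] = r_hi, q_hi
            runs[-1][4] = runs[-1][4] or is_gap
        else:
            runs.append([r_lo, r_hi, q_lo, q_hi, is_gap])

    prev_r, prev_q = 0, 0
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        rs, re, qs, qe = int(rs), int(re), int(qs), int(qe)
        add(prev_r, rs, prev_q, qs, True)
        i = 0
        while i < re - rs:
            if reference[rs + i] != read[qs + i]:
                j = i
                while j < re - rs and reference[rs + j] != read[qs + j]:
                    j += 1
                add(rs + i, rs + j, qs + i, qs + j, False)
                i = j
            else:
                i += 1
        prev_r, prev_q = re, qe
    add(prev_r, len(reference), prev_q, len(read), True)

    events: list[Indel] = []
    for r_lo, r_hi, q_lo, q_hi, has_gap in runs:
        if not has_gap:
            continue
        ins = read[q_lo:q_hi]
        if r_hi > r_lo:
            events.append(Indel(del_start=r_lo + 1, del_end=r_hi, insertion=ins))
        else:
            events.append(Indel(insertion=ins, insertion_after=r_lo))
    return events


def extract_indel(alignment: Align.Alignment, target: AmpliconTarget,
                  max_gap: int = DEFAULT_MAX_GAP) -> Indel | None:
    """Qualifying indel of an alignment, or None.

    Returns the left-aligned indel whose footprint touches the cut window
    (largest footprint wins if several qualify).  Substitution-only
    alignments and indels entirely outside the window return None — such
    reads are set aside as putative PCR/sequencing error.  Any single gap
    may span up to ``max_gap`` bases.
    """
    read = str(alignment.query if hasattr(alignment, "query") else alignment.sequences[1])
    events = _alignment_indels(alignment, read, target.reference)
    qualifying = []
    for ev in events:
        if ev.deletion_length > max_gap or len(ev.insertion) > max_gap:
            continue
        ev = left_align(ev, target.reference)
        if indel_qualifies(ev, target):
            qualifying.append(ev)
    if not qualifying:
        return None
    return max(qualifying, key=lambda e: (e.footprint_size, name_allele(e)))


@dataclass
class AssignmentResult:
    """Per-sample read accounting after assignment to a master allele list."""

    counts: Counter = field(default_factory=Counter)   # INTACT + allele names
    n_error: int = 0
    n_unalignable: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_error + self.n_unalignable


class AlleleCaller:
    """Stateful caller for one target: caches one alignment per unique read."""

    def __init__(self, target: AmpliconTarget,
                 min_discovery_reads: int = DEFAULT_MIN_DISCOVERY_READS,
                 min_read_length: int = DEFAULT_MIN_READ_LENGTH,
                 max_gap: int = DEFAULT_MAX_GAP) -> None:
        self.target = target
        self.min_discovery_reads = min_discovery_reads
        self.min_read_length = min_read_length
        self.max_gap = max_gap
        self.aligner = default_aligner()
        self._indel_cache: dict[str, Indel | None] = {}

    def qualifying_indel(self, read: str) -> Indel | None:
        """Left-aligned cut-window indel of a read (cached), or None."""
        cached = self._indel_cache.get(read, "MISS")
        if cached != "MISS":
            return cached
        alignment = align_read(read, self.target, self.aligner, self.min_read_length)
        indel = extract_indel(alignment, self.target, self.max_gap)
        self._indel_cache[read] = indel
        return indel

    # -- discovery ------------------------------------------------------
    def discover(self, reads: Iterable[str] | Mapping[str, int]) -> list[Allele]:
        """Iteratively extract alleles from one sample's read set.

        Aligns well-supported unique sequences first; reads explained by a
        discovered allele (containing its representative) are removed before
        the remaining, mostly-singleton error reads are examined.  An indel
        is promoted to an allele once its summed support reaches
        ``min_discovery_reads``.
        """
        counts = Counter(reads) if not isinstance(reads, Mapping) else Counter(reads)
        pending = {seq: c for seq, c in counts.items()
                   if not classify_non_mutant(seq, self.target)}
        alleles: list[Allele] = []
        seen_names: set[str] = set()

        def rounds(min_unique_count: int) -> None:
            nonlocal pending
            while True:
                tally: dict[str, list] = {}
                for seq, c in pending.items():
                    if c < min_unique_count or len(seq) < self.min_read_length:
                        continue
                    indel = self.qualifying_indel(seq)
                    if indel is None:
                        continue
                    nm = name_allele(indel)
                    if nm in seen_names:
                        continue
                    entry = tally.setdefault(nm, [0, indel])
                    entry[0] += c
                eligible = {nm: v for nm, v in tally.items()
                            if v[0] >= self.min_discovery_reads}
                if not eligible:
                    return
                top = max(v[0] for v in eligible.values())
                nm = min(n for n, v in eligible.items() if v[0] == top)
                seen_names.add(nm)
                try:
                    allele = build_allele(eligible[nm][1], self.target)
                except AlleleError:
                    continue  # unrepresentable (e.g. deletion too large); left as error reads
                alleles.append(allele)
                pending = {s: c for s, c in pending.items()
                           if allele.representative not in s}

        rounds(self.min_discovery_reads)
        rounds(1)
        return alleles

    # -- assignment -----------------------------------------------------
    def assign(self, reads: Iterable[str] | Mapping[str, int],
               alleles: list[Allele]) -> AssignmentResult:
        """Assign every read to exactly one class.

        INTACT beats everything; otherwise the read goes to the allele whose
        representative it contains, ties broken by largest indel footprint
        then lexicographically smallest name; leftovers are error reads,
        too-short reads unalignable.  Deterministic and idempotent.
        """
        counts = Counter(reads) if not isinstance(reads, Mapping) else reads
        order = sorted(alleles, key=lambda a: (-a.indel.footprint_size, a.name))
        result = AssignmentResult()
        result.counts[INTACT] = 0
        for a in order:
            result.counts[a.name] = 0
        for seq, c in counts.items():
            if len(seq) < self.min_read_length:
                result.n_unalignable += c
            elif classify_non_mutant(seq, self.target):
                result.counts[INTACT] += c
            else:
                for a in order:
                    if a.representative in seq:
                        result.counts[a.name] += c
                        break
                else:
                    result.n_error += c
        return result


def discover_alleles(reads: Iterable[str] | Mapping[str, int], target: AmpliconTarget,
                     min_discovery_reads: int = DEFAULT_MIN_DISCOVERY_READS,
                     ) -> tuple[list[Allele], AssignmentResult]:
    """Convenience wrapper: discover one sample's alleles and its raw counts."""
    caller = AlleleCaller(target, min_discovery_reads=min_discovery_reads)
    alleles = caller.discover(reads)
    return alleles, caller.assign(reads, alleles)


def consolidate_alleles(per_animal_alleles: Iterable[Iterable[Allele]],
                        ) -> list[Allele]:
    """Merge per-animal allele lists for one target into a master list.

    Deduplicates by canonical (left-aligned) name, then merges alleles whose
    representatives are identical (the same physical indel discovered at
    equivalent placements), keeping the leftmost-coordinate name.
    """
    by_name: dict[str, Allele] = {}
    rep_len: int | None = None
    for alleles in per_animal_alleles:
        for a in alleles:
            if rep_len is None:
                rep_len = len(a.representative)
            elif len(a.representative) != rep_len:
                raise TargetError("representative length mismatch across animals")
            by_name.setdefault(a.name, a)
    by_rep: dict[str, Allele] = {}
    for a in sorted(by_name.values(),
                    key=lambda a: (a.indel.footprint[0], a.name)):
        by_rep.setdefault(a.representative, a)
    return sorted(by_rep.values(), key=lambda a: (a.indel.footprint[0], a.name))


def assign_reads(reads: Iterable[str] | Mapping[str, int], alleles: list[Allele],
                 target: AmpliconTarget) -> AssignmentResult:
    """Assign a sample's reads against a consolidated master allele list."""
    return AlleleCaller(target).assign(reads, alleles)
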