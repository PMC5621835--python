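"""Amplicon target geometry: reference sequence, protospacer and PAM.

An :class:`AmpliconTarget` describes one PCR amplicon spanning a Cas9 target
site.  All coordinates are 1-based and inclusive on the reference amplicon.
The *cut window* — the PAM plus the three PAM-proximal protospacer bases —
defines which indels qualify as heritable lineage alleles: Cas9 cleaves
three bases upstream of the PAM, so repair-derived indels cluster there,
while mismatches or gaps elsewhere on the amplicon are treated as PCR or
sequencing artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

DNA_ALPHABET = "ACGT"


class TargetError(ValueError):
    """Raised when an amplicon target definition is inconsistent."""


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplicon with its protospacer/PAM geometry.

    Parameters
    ----------
    name : str
        Unique target (gRNA site) identifier.
    reference : str
        Expected PCR amplicon sequence (includes both primers).
    protospacer : str
        17–20 nt gRNA target sequence, as it appears in ``reference``.
    pam : str
        3 nt protospacer-adjacent motif immediately 3' of the protospacer.
    protospacer_start : int
        1-based position of the protospacer in ``reference``.
    representative_length : int
        Length (27–36 nt) to which every allele representative for this
        target is trimmed, so reads can be assigned by exact substring match.
    """

    name: str
    reference: str
    protospacer: str
    pam: str
    protospacer_start: int
    representative_length: int = 30
    flank_min: int = 13
    flank_max: int = 20
    pam_side: str = "three_prime"

    def __post_init__(self) -> None:
        for label, seq in (("reference", self.reference),
                           ("protospacer", self.protospacer),
                           ("pam", self.pam)):
            if not seq or any(b not in DNA_ALPHABET for b in seq):
                raise TargetError(f"{label} of target {self.name!r} must be non-empty A/C/G/T")
        if not 17 <= len(self.protospacer) <= 20:
            raise TargetError(f"protospacer of {self.name!r} must be 17-20 nt")
        if len(self.pam) != 3:
            raise TargetError(f"PAM of {self.name!r} must be 3 nt")
        if self.pam_side != "three_prime":
            raise TargetError("only 3' PAMs are supported")
        if not 27 <= self.representative_length <= 36:
            raise TargetError("representative_length must lie in [27, 36]")
        start = self.protospacer_start
        site = self.protospacer + self.pam
        if start < 1 or self.reference[start - 1:start - 1 + len(site)] != site:
            raise TargetError(
                f"protospacer+PAM not found at position {start} of target {self.name!r}")
        if len(self.reference) < self.representative_length:
            raise TargetError("reference amplicon shorter than representative_length")

    # -- geometry -------------------------------------------------------
    @property
    def protospacer_end(self) -> int:
        return self.protospacer_start + len(self.protospacer) - 1

    @property
    def pam_start(self) -> int:
        return self.protospacer_end + 1

    @property
    def pam_end(self) -> int:
        return self.pam_start + 2

    @property
    def site(self) -> str:
        """Protospacer plus PAM; a read containing this exact substring is non-mutant."""
        return self.protospacer + self.pam

    @property
    def cut_after(self) -> int:
        """Reference base after which Cas9 cleaves (3 bp upstream of the PAM)."""
        return self.protospacer_end - 3

    @property
    def cut_window(self) -> tuple[int, int]:
        """Inclusive span of positions an allele's indel must touch.

        The PAM plus the three protospacer bases adjacent to it.
        """
        return (self.protospacer_end - 2, self.pam_end)


def synthetic_target(seed: int = 0, name: str = "synthetic_t1",
                     amplicon_length: int = 160, protospacer_start: int = 61,
                     representative_length: int = 30) -> AmpliconTarget:
    """Build a random synthetic amplicon target for simulation and testing.

    The reference is a uniform-random amplicon carrying a 20 nt protospacer
    followed by an NGG PAM at ``protospacer_start``.  Deterministic in
    ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    bases = rng.integers(0, 4, size=amplicon_length)
    ref = list(DNA_ALPHABET[b] for b in bases)
    pam_start0 = protospacer_start - 1 + 20
    if pam_start0 + 3 > amplicon_length:
        raise TargetError("amplicon too short for protospacer+PAM at this position")
    ref[pam_start0 + 1] = "G"
    ref[pam_start0 + 2] = "G"
    reference = "".join(ref)
    protospacer = reference[protospacer_start - 1: protospacer_start - 1 + 20]
    pam = reference[pam_start0: pam_start0 + 3]
    return AmpliconTarget(name=name, reference=reference, protospacer=protospacer,
                          pam=pam, protospacer_start=protospacer_start,
                          representative_length=representative_length)


# -- registry I/O -------------------------------------------------------

def save_targets(targets: list[AmpliconTarget], path: str | Path) -> None:
    """Write a target registry as JSON (list of target records)."""
    with open(path, "w") as fh:
        json.dump([asdict(t) for t in targets], fh, indent=1)


def load_targets(path: str | Path) -> dict[str, AmpliconTarget]:
    """Load a JSON target registry into a name-keyed dict."""
    with open(path) as fh:
        records = json.load(fh)
    targets = {}
    for rec in records:
        t = AmpliconTarget(**rec)
        if t.name in targets:
            raise TargetError(f"duplicate target name {t.name!r} in registry")
        targets[t.name] = t
    return targets
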