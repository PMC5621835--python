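"""Shared fixtures: a hand-built toy amplicon with known geometry.

The toy reference is 60 nt with the protospacer at positions 11-30 and a
TGG PAM at 31-33, so the cut window is positions 28-33.  Positions 28-30
are "ATT" and position 34 onward starts with "CAG", giving a homopolymer
run (T T T across 29, 30 and the inserted base) for left-alignment tests
while keeping the D28-30 deletion placement unambiguous.
"""

import pytest

from indeltrace.targets import AmpliconTarget

TOY_PREFIX = "ACGTACGTCA"                       # 1-10
TOY_PROTOSPACER = "GCTGACTGACCTGGTACATT"        # 11-30
TOY_PAM = "TGG"                                 # 31-33
TOY_SUFFIX = "CAGTCCAGTACGGATCCAGTTACGCAT"      # 34-60
TOY_REFERENCE = TOY_PREFIX + TOY_PROTOSPACER + TOY_PAM + TOY_SUFFIX


@pytest.fixture(scope="session")
def toy_target() -> AmpliconTarget:
    return AmpliconTarget(name="toy", reference=TOY_REFERENCE,
                          protospacer=TOY_PROTOSPACER, pam=TOY_PAM,
                          protospacer_start=11, representative_length=30)
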