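"""Synthetic contaminant sequences for read simulation and screening.

Illumina runs of the era spiked phiX174 control DNA into every lane, and
libraries routinely pick up traces of human or bacterial DNA; unmapped-read
assemblies therefore need a contaminant screen.  Shipping real GenBank
records is unnecessary for that purpose, so this module generates two
clearly labelled *synthetic* stand-ins deterministically at import time:

``phiX_like``
    a random 5,386-base sequence (the length of the phiX174 genome) with
    phage-typical ~44% GC,
``foreign_like``
    a random 2,000-base high-GC sequence standing in for a fragment of a
    foreign (e.g. bacterial) gene.

Both are reproducible: they are derived from fixed internal seeds, never
from user-supplied ones, so the screen set is identical across runs.
"""

from __future__ import annotations

import numpy as np

from clonotyper.seqs import random_sequence

PHIX_LIKE_LENGTH = 5386
FOREIGN_LIKE_LENGTH = 2000

_PHIX_SEED = 174
_FOREIGN_SEED = 1759


def phix_like() -> str:
    """Synthetic 5,386-base phiX174-like control sequence."""
    return random_sequence(np.random.default_rng(_PHIX_SEED), PHIX_LIKE_LENGTH, gc=0.44)


def foreign_like() -> str:
    """Synthetic 2,000-base foreign-gene-like sequence."""
    return random_sequence(np.random.default_rng(_FOREIGN_SEED), FOREIGN_LIKE_LENGTH, gc=0.6)


def default_contaminants() -> dict[str, str]:
    """Named contaminant set used by the simulator and as default screen set."""
    return {"phiX_like": phix_like(), "foreign_like": foreign_like()}
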