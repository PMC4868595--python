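"""Detection of homopolymer runs and short tandem repeats (microsatellites).

Variants inside these contexts are prone to sequencing and alignment error,
so the SNP filter cascade needs a deterministic, purely sequence-based test
for "does position *p* sit in a repeat tract".  The simulator uses the same
predicates to keep planted true SNPs out of repeat contexts.
"""

from __future__ import annotations


def _run_bounds(seq: str, i: int) -> tuple[int, int]:
    """0-based inclusive bounds of the single-base run containing ``i``."""
    b = seq[i]
    lo, hi = i, i
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    while hi < len(seq) - 1 and seq[hi + 1] == b:
        hi += 1
    return lo, hi


def in_homopolymer(seq: str, pos: int, min_run: int, adjacent: bool = True) -> bool:
    """True if 1-based ``pos`` lies in (or immediately next to) a run >= min_run.

    ``adjacent=True`` also flags the two positions flanking a qualifying run,
    since a substitution bordering a long run is equally unreliable.
    """
    i = pos - 1
    if not 0 <= i < len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    lo, hi = _run_bounds(seq, i)
    if hi - lo + 1 >= min_run:
        return True
    if adjacent:
        for j in (i - 1, i + 1):
            if 0 <= j < len(seq) and seq[j] != seq[i]:
                lo, hi = _run_bounds(seq, j)
                if hi - lo + 1 >= min_run:
                    return True
    return False


def in_microsatellite(
    seq: str,
    pos: int,
    unit_max: int = 6,
    min_copies: int = 3,
    min_span: int = 8,
) -> bool:
    """True if 1-based ``pos`` lies within a tandem repeat.

    A tandem repeat of unit length ``u`` is a maximal interval over which
    ``seq[j] == seq[j + u]`` holds; it qualifies when it spans at least
    ``min_span`` bases comprising at least ``min_copies`` unit copies.
    """
    i = pos - 1
    n = len(seq)
    if not 0 <= i < n:
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    for u in range(1, unit_max + 1):
        # periodicity indices j such that seq[j] == seq[j+u]; a maximal run
        # [a, c] of such j's covers reference interval [a, c+u]
        j_lo = max(0, i - u)
        j_hi = min(i, n - 1 - u)
        j = j_lo
        while j <= j_hi:
            if seq[j] != seq[j + u]:
                j += 1
                continue
            a = j
            while a - 1 >= 0 and seq[a - 1] == seq[a - 1 + u]:
                a -= 1
            c = j
            while c + 1 <= n - 1 - u and seq[c + 1] == seq[c + 1 + u]:
                c += 1
            if a <= i <= c + u:
                span = c + u - a + 1
                if span >= min_span and span // u >= min_copies:
                    return True
            j = c + 1
    return False
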