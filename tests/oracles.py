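"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the library's vectorised code paths: plain
per-read, per-position Python loops, so that agreement with the package
is meaningful evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

from clonotyper.alignio import AlignmentRecord
from clonotyper.snpcall import CallerConfig


def brute_homopolymer(seq: str, pos: int, min_run: int, adjacent: bool = True) -> bool:
    """Position in (or next to) a run of >= min_run identical bases."""
    i = pos - 1
    runs = []
    s = 0
    for j in range(1, len(seq) + 1):
        if j == len(seq) or seq[j] != seq[s]:
            if j - s >= min_run:
                runs.append((s, j - 1))
            s = j
    for lo, hi in runs:
        if lo <= i <= hi:
            return True
        if adjacent and (i == lo - 1 or i == hi + 1):
            return True
    return False


def brute_microsatellite(seq: str, pos: int, unit_max: int = 6,
                         min_copies: int = 3, min_span: int = 8) -> bool:
    """Position inside any periodic interval meeting the span/copy rules.

    Checks every interval exhaustively; qualifying sub-intervals imply a
    qualifying maximal interval, so this is equivalent to a maximal scan.
    """
    i = pos - 1
    n = len(seq)
    for u in range(1, unit_max + 1):
        for a in range(n):
            for b in range(a + min_span - 1, n):
                if not (a <= i <= b):
                    continue
                span = b - a + 1
                if span // u < min_copies:
                    continue
                if all(seq[j] == seq[j - u] for j in range(a + u, b + 1)):
                    return True
    return False


def brute_cascade(records: list[AlignmentRecord], ref: str,
                  cfg: CallerConfig) -> list[tuple[int, str, str, int, frozenset]]:
    """Per-position call + triage from alignment records, all in plain loops.

    Returns (pos, ref_base, alt_base, alt_support, flags) for each call,
    sorted by position.
    """
    n = len(ref)
    counts = {b: [0] * n for b in "ACGT"}
    end_near = {b: [0] * n for b in "ACGT"}
    indel_open = [0] * n
    for rec in records:
        if not rec.mapped:
            continue
        qlen = len(rec.seq)
        r, q = rec.start - 1, 0
        for op, ln in rec.cigar:
            if op == "M":
                for t in range(ln):
                    b = rec.seq[q + t]
                    counts[b][r + t] += 1
                    offset = min(q + t, qlen - 1 - (q + t))
                    if offset < cfg.end_window:
                        end_near[b][r + t] += 1
                r += ln
                q += ln
            elif op == "D":
                indel_open[r] += 1
                r += ln
            elif op == "I":
                indel_open[r - 1] += 1
                q += ln
            elif op == "S":
                q += ln
    calls = []
    for i in range(n):
        ref_base = ref[i]
        alt, alt_count = None, -1
        for b in "ACGT":  # fixed order breaks ties deterministically
            if b != ref_base and counts[b][i] > alt_count:
                alt, alt_count = b, counts[b][i]
        if alt_count < cfg.min_mutant_reads:
            continue
        flags = set()
        if end_near[alt][i] / alt_count > cfg.max_end_fraction:
            flags.add("read_end")
        if brute_homopolymer(ref, i + 1, cfg.homopolymer_min):
            flags.add("homopolymer")
        if brute_microsatellite(ref, i + 1, cfg.microsat_unit_max,
                                cfg.microsat_min_copies, cfg.microsat_min_span):
            flags.add("microsatellite")
        lo, hi = max(0, i - cfg.indel_window), min(n, i + cfg.indel_window + 1)
        if sum(indel_open[lo:hi]) > cfg.max_indel_reads:
            flags.add("indel_shadow")
        calls.append((i + 1, ref_base, alt, alt_count, frozenset(flags)))
    return calls


def random_pileup_case(rng, max_columns: int = 30) -> tuple[list[AlignmentRecord], str]:
    """A random reference (<= max_columns bp) and random alignments over it.

    Mixes background reads (occasional substitutions, occasional 1 bp
    indels) with a deliberate alternate-allele stack at one position so a
    useful fraction of cases actually produce calls.
    """
    from clonotyper.seqs import random_sequence

    n = int(rng.integers(12, max_columns + 1))
    ref = random_sequence(rng, n)
    records: list[AlignmentRecord] = []
    rid = 0

    def add_read(start: int, seq: str, cigar) -> None:
        nonlocal rid
        records.append(AlignmentRecord(read_id=f"r{rid}", contig="c1",
                                       start=start, cigar=cigar, seq=seq))
        rid += 1

    for _ in range(int(rng.integers(5, 25))):
        start = int(rng.integers(1, n - 5))
        length = int(rng.integers(6, n - start + 2))
        bases = list(ref[start - 1 : start - 1 + length])
        for t in range(length):
            if rng.random() < 0.08:
                bases[t] = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.15 and length >= 8:
            # drop one reference base mid-read: M, D1, M
            cut = int(rng.integers(3, length - 3))
            seq = "".join(bases[:cut] + bases[cut + 1 :])
            add_read(start, seq, [("M", cut), ("D", 1), ("M", length - cut - 1)])
        else:
            add_read(start, "".join(bases), [("M", length)])

    # alternate-allele stack: k identical-substitution reads at one locus
    pos = int(rng.integers(1, n + 1))
    alt = "ACGT"[int(rng.integers(4))]
    for _ in range(int(rng.integers(0, 13))):
        start = int(rng.integers(max(1, pos - 8), pos + 1))
        end = int(rng.integers(pos, min(n, pos + 8) + 1))
        length = end - start + 1
        bases = list(ref[start - 1 : end])
        bases[pos - start] = alt
        add_read(start, "".join(bases), [("M", length)])
    return records, ref
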