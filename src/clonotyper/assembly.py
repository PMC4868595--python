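"""Compact de Bruijn assembly of unmapped reads and contig classification.

The genome-content cross-check for a near-clonal pair: reads that fail to
map to the reference are assembled into contigs, the other strain's
(unmapped) reads are mapped back onto them, and each contig is classified
as shared between the strains, strain-specific, or contaminant (by an
ungapped screen against known contaminant sequences such as the phiX
sequencing control).  The expected outcome for a genuinely clonal pair is
zero strain-specific non-contaminant contigs.

The assembler is deliberately small: canonical k-mers, an abundance floor,
maximal non-branching paths.  Determinism is favoured over assembly
quality — k-mers are traversed in sorted order and contigs are emitted in
canonical orientation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from clonotyper.alignio import AlignmentRecord
from clonotyper.seqs import canonical, revcomp


@dataclass
class AssemblyConfig:
    k: int = 21
    min_kmer_count: int = 2
    min_contig_length: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.k % 2 == 0 or not 11 <= self.k <= 63:
            raise ValueError("k must be odd and in [11, 63]")
        if self.min_kmer_count < 1 or self.min_contig_length < 1:
            raise ValueError("counts and lengths must be >= 1")


@dataclass
class ContigRecord:
    id: str
    sequence: str
    read_support: float  # mean k-mer multiplicity along the contig
    classification: str = "unassigned"  # shared | specific_to_A | specific_to_B | contaminant
    screen_hit: str | None = None


def collect_unmapped(alignments: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Exactly the unmapped records, sorted by read id (input-order independent)."""
    return sorted((a for a in alignments if not a.mapped), key=lambda a: a.read_id)


def _kmer_counts(seqs: list[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= set("ACGT"):
                counts[canonical(kmer)] += 1
    return counts


def _neighbours(kmer: str, kmers: set, direction: str) -> list[str]:
    """Oriented successors (direction 'out') or predecessors ('in')."""
    out = []
    for b in "ACGT":
        nxt = kmer[1:] + b if direction == "out" else b + kmer[:-1]
        if canonical(nxt) in kmers:
            out.append(nxt)
    return out


def assemble(reads: list[str] | list[AlignmentRecord], config: AssemblyConfig | None = None) -> list[ContigRecord]:
    """Assemble read sequences into maximal non-branching contigs.

    Accepts plain sequences or alignment records (their ``seq`` is used).
    Contigs shorter than ``min_contig_length`` are dropped; output is in
    canonical orientation, sorted by descending length then sequence.
    """
    config = config or AssemblyConfig()
    config.validate()
    seqs = [r.seq if isinstance(r, AlignmentRecord) else str(r) for r in reads]
    seqs = [s for s in seqs if s]
    if not seqs:
        return []
    if any(len(s) <= config.k for s in seqs):
        shortest = min(len(s) for s in seqs)
        if shortest <= config.k:
            raise ValueError(f"k={config.k} >= shortest read length {shortest}")
    counts = _kmer_counts(seqs, config.k)
    kmers = {km for km, c in counts.items() if c >= config.min_kmer_count}
    visited: set[str] = set()
    contigs: list[tuple[str, float]] = []

    def unambiguous_step(cur: str, direction: str) -> str | None:
        nbrs = _neighbours(cur, kmers, direction)
        if len(nbrs) != 1:
            return None
        nxt = nbrs[0]
        back = _neighbours(nxt, kmers, "in" if direction == "out" else "out")
        if len(back) != 1:
            return None
        return nxt

    for start in sorted(kmers):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        # extend forward then backward from the canonical seed orientation
        cur = start
        while True:
            nxt = unambiguous_step(cur, "out")
            if nxt is None or canonical(nxt) in visited:
                break
            path.append(nxt)
            visited.add(canonical(nxt))
            cur = nxt
        cur = start
        while True:
            prv = unambiguous_step(cur, "in")
            if prv is None or canonical(prv) in visited:
                break
            path.insert(0, prv)
            visited.add(canonical(prv))
            cur = prv
        seq = path[0] + "".join(p[-1] for p in path[1:])
        support = sum(counts[canonical(p)] for p in path) / len(path)
        contigs.append((canonical(seq), support))

    contigs = [(s, sup) for s, sup in contigs if len(s) >= config.min_contig_length]
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        ContigRecord(id=f"contig_{i + 1}", sequence=s, read_support=round(sup, 2))
        for i, (s, sup) in enumerate(contigs)
    ]


def cross_map(
    contigs: list[ContigRecord],
    other_reads: list[str] | list[AlignmentRecord],
    min_breadth: float = 0.9,
    k: int = 21,
    strain: str = "A",
) -> list[ContigRecord]:
    """Classify contigs as shared vs strain-specific by the other strain's reads.

    A contig whose positions are covered (via shared k-mers) by the other
    strain's reads over at least ``min_breadth`` of its length is
    ``shared``; otherwise it remains ``specific_to_<strain>`` pending the
    contaminant screen.  Already-classified contaminants are left alone.
    """
    seqs = [r.seq if isinstance(r, AlignmentRecord) else str(r) for r in other_reads]
    read_kmers = set(_kmer_counts(seqs, k)) if seqs else set()
    for contig in contigs:
        if contig.classification == "contaminant":
            continue
        s = contig.sequence
        covered = [False] * len(s)
        for i in range(len(s) - k + 1):
            if canonical(s[i : i + k]) in read_kmers:
                for j in range(i, i + k):
                    covered[j] = True
        breadth = sum(covered) / len(s) if s else 0.0
        contig.classification = "shared" if breadth >= min_breadth else f"specific_to_{strain}"
    return contigs


def _best_ungapped_match(contig: str, target: str, k: int) -> tuple[float, float]:
    """(identity, coverage_fraction) of the best offset-consistent ungapped match."""
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i : i + k], []).append(i)
    best = (0.0, 0.0)
    for query in (contig, revcomp(contig)):
        votes: Counter = Counter()
        for i in range(len(query) - k + 1):
            for j in index.get(query[i : i + k], ()):
                votes[j - i] += 1
        if not votes:
            continue
        offset, _ = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        # ungapped comparison of the overlapping region at this offset
        q_lo = max(0, -offset)
        q_hi = min(len(query), len(target) - offset)
        if q_hi <= q_lo:
            continue
        q_seg = query[q_lo:q_hi]
        t_seg = target[q_lo + offset : q_hi + offset]
        matches = sum(a == b for a, b in zip(q_seg, t_seg))
        identity = matches / len(q_seg)
        coverage = len(q_seg) / len(query)
        if (identity * coverage) > (best[0] * best[1]):
            best = (identity, coverage)
    return best


def screen_contaminants(
    contigs: list[ContigRecord],
    screen_set: dict[str, str],
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
    k: int = 21,
) -> list[ContigRecord]:
    """Mark contigs matching a screen sequence as contaminant.

    A contig is a contaminant when an ungapped offset-consistent match to
    any screen sequence reaches ``min_identity`` over at least
    ``min_coverage`` of the contig length.
    """
    if not screen_set:
        raise ValueError("screen set is empty")
    for contig in contigs:
        for name in sorted(screen_set):
            identity, coverage = _best_ungapped_match(contig.sequence, screen_set[name], k)
            if identity >= min_identity and coverage >= min_coverage:
                contig.classification = "contaminant"
                contig.screen_hit = name
                break
    return contigs


def classify_contigs(
    contigs: list[ContigRecord],
    other_reads,
    screen_set: dict[str, str],
    strain: str = "A",
    min_breadth: float = 0.9,
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
    k: int = 21,
) -> list[ContigRecord]:
    """Contaminant screen first, then shared/strain-specific cross-mapping."""
    screen_contaminants(contigs, screen_set, min_identity, min_coverage, k)
    cross_map(contigs, other_reads, min_breadth, k, strain)
    return contigs
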