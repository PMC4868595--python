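"""Per-position pileups, coverage breadth and divergence summaries.

The pileup is the substrate for the read-count SNP caller: for every
reference position it keeps per-nucleotide support counts, the number of
supporting reads whose base sits inside the terminal read window (where
base accuracy is lowest), and nearby insertion/deletion evidence.  Counting
is base-quality-blind and strand-blind; the caller works on read counts
alone.

Pileup semantics follow the usual conventions: deletions consume reference
positions but contribute no base support there; insertions attach to the
preceding reference position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonotyper.alignio import AlignmentRecord
from clonotyper.seqs import BASES, encode


@dataclass
class PileupColumn:
    """Read support at one reference position (1-based)."""

    contig: str
    pos: int
    ref_base: str
    base_support: dict[str, int]
    end_near: dict[str, int]  # supports with end_offset < the build end_window
    indel_evidence: int

    @property
    def depth(self) -> int:
        return sum(self.base_support.values())


class ContigPileup:
    """Dense per-contig arrays: 4xL base counts, 4xL near-end counts, L indel opens."""

    def __init__(self, length: int):
        self.length = length
        self.counts = np.zeros((4, length), dtype=np.int32)
        self.end_near = np.zeros((4, length), dtype=np.int32)
        self.indel_open = np.zeros(length, dtype=np.int32)

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def indel_evidence(self, window: int) -> np.ndarray:
        """Indel-open events within +/-window (inclusive) of each position."""
        if window == 0:
            return self.indel_open.copy()
        kernel = np.ones(2 * window + 1, dtype=np.int32)
        return np.convolve(self.indel_open, kernel, mode="same")


class Pileup:
    """Pileup over a reference genome.

    ``end_window`` is fixed at build time: the near-end counters record
    supports whose distance to the closest read end is strictly below it.
    """

    def __init__(self, reference: dict[str, str], end_window: int = 5):
        self.reference = reference
        self.end_window = end_window
        self.contigs = {name: ContigPileup(len(seq)) for name, seq in reference.items()}

    def column(self, contig: str, pos: int, indel_window: int = 5) -> PileupColumn:
        cp = self.contigs[contig]
        i = pos - 1
        lo, hi = max(0, i - indel_window), min(cp.length, i + indel_window + 1)
        return PileupColumn(
            contig=contig,
            pos=pos,
            ref_base=self.reference[contig][i],
            base_support={b: int(cp.counts[j, i]) for j, b in enumerate(BASES)},
            end_near={b: int(cp.end_near[j, i]) for j, b in enumerate(BASES)},
            indel_evidence=int(cp.indel_open[lo:hi].sum()),
        )

    def to_frame(self, min_depth: int = 1) -> pd.DataFrame:
        """Tabular view of covered positions, for inspection and TSV export."""
        rows = []
        for contig, cp in self.contigs.items():
            depth = cp.depth()
            for i in np.flatnonzero(depth >= min_depth):
                rows.append(
                    {
                        "contig": contig,
                        "pos": int(i) + 1,
                        "ref": self.reference[contig][i],
                        **{b: int(cp.counts[j, i]) for j, b in enumerate(BASES)},
                        "depth": int(depth[i]),
                        "indel_open": int(cp.indel_open[i]),
                    }
                )
        return pd.DataFrame(rows)


def build_pileup(
    alignments: list[AlignmentRecord],
    reference: dict[str, str],
    end_window: int = 5,
) -> Pileup:
    """Build a pileup from alignment records against ``reference``.

    Soft-clipped bases are skipped; unmapped records are ignored.  Raises
    on alignments that name an unknown contig or overrun its end.
    """
    pile = Pileup(reference, end_window=end_window)
    for rec in alignments:
        if not rec.mapped:
            continue
        if rec.contig not in pile.contigs:
            raise ValueError(f"alignment {rec.read_id} references unknown contig {rec.contig}")
        cp = pile.contigs[rec.contig]
        cigar = rec.cigar or [("M", len(rec.seq))]
        qlen = sum(n for op, n in cigar if op in ("M", "I", "S"))
        ref0 = rec.start - 1
        q0 = 0
        if ref0 + sum(n for op, n in cigar if op in ("M", "D")) > cp.length:
            raise ValueError(f"alignment {rec.read_id} overruns contig {rec.contig}")
        for op, n in cigar:
            if op == "M":
                qidx = np.arange(q0, q0 + n)
                ridx = np.arange(ref0, ref0 + n)
                bases = encode(rec.seq[q0 : q0 + n])
                np.add.at(cp.counts, (bases, ridx), 1)
                end_off = np.minimum(qidx, qlen - 1 - qidx)
                near = end_off < end_window
                if near.any():
                    np.add.at(cp.end_near, (bases[near], ridx[near]), 1)
                ref0 += n
                q0 += n
            elif op == "I":
                # insertion attaches to the preceding reference position
                if ref0 > 0:
                    cp.indel_open[ref0 - 1] += 1
                q0 += n
            elif op == "D":
                cp.indel_open[ref0] += 1
                ref0 += n
            elif op == "S":
                q0 += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
    return pile


@dataclass
class CoverageSummary:
    """Breadth at a depth threshold and mean depth over all reference positions."""

    breadth_at_k: float
    k: int
    mean_depth: float
    genome_length: int


def coverage_summary(pile: Pileup, k: int = 8) -> CoverageSummary:
    """Fraction of reference positions with depth >= k, and mean depth.

    Zero-depth positions count in both denominators.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = sum(cp.length for cp in pile.contigs.values())
    if total == 0:
        raise ValueError("empty reference genome")
    covered = sum(int((cp.depth() >= k).sum()) for cp in pile.contigs.values())
    bases = sum(int(cp.depth().sum()) for cp in pile.contigs.values())
    return CoverageSummary(
        breadth_at_k=covered / total, k=k, mean_depth=bases / total, genome_length=total
    )


@dataclass
class DivergenceResult:
    """Consensus divergence over callable (depth >= threshold) positions.

    ``rate`` is NaN when no position is callable — an undefined result is
    flagged rather than reported as zero divergence.
    """

    rate: float
    n_callable: int
    n_divergent: int

    @property
    def defined(self) -> bool:
        return self.n_callable > 0


def divergence_rate(pile: Pileup, min_depth: int = 8) -> DivergenceResult:
    """Fraction of callable positions whose consensus base differs from reference.

    Consensus is the best-supported base, ties broken in fixed A<C<G<T
    order; a tie that includes the reference resolves to the reference.
    """
    n_callable = 0
    n_div = 0
    for contig, cp in pile.contigs.items():
        depth = cp.depth()
        callable_mask = depth >= min_depth
        if not callable_mask.any():
            continue
        idx = np.flatnonzero(callable_mask)
        ref_codes = encode(pile.reference[contig])[idx]
        counts = cp.counts[:, idx]
        best = counts.argmax(axis=0)  # first max in A<C<G<T order
        ref_counts = counts[ref_codes, np.arange(len(idx))]
        best_counts = counts[best, np.arange(len(idx))]
        divergent = (best != ref_codes) & (best_counts > ref_counts)
        n_callable += len(idx)
        n_div += int(divergent.sum())
    rate = n_div / n_callable if n_callable else math.nan
    return DivergenceResult(rate=rate, n_callable=n_callable, n_divergent=n_div)
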