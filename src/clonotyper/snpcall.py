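"""Read-count SNP calling and artifact triage for near-clonal pairs.

The caller emits a putative SNP wherever a non-reference base is supported
by at least ``min_mutant_reads`` reads (default 8).  Because near-clonal
pairs yield almost no true variants, most putative calls are artifacts;
the cascade automates the three manual-inspection criteria used to reject
them:

``read_end``
    most alternate support sits within the terminal read window, where
    base accuracy is low;
``homopolymer`` / ``microsatellite``
    the position lies in a single-base run or short tandem repeat, where
    both sequencing and alignment are unreliable;
``indel_shadow``
    reads open an insertion or deletion near the position, the signature
    of misplaced gaps created by the mapper.

A putative SNP is *confirmed* only if it carries no flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clonotyper.pileup import Pileup
from clonotyper.repeats import in_homopolymer, in_microsatellite
from clonotyper.seqs import BASES, encode

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class CallerConfig:
    """Thresholds for calling and artifact triage.

    ``min_mutant_reads`` is the core read-count rule; the filter thresholds
    implement the qualitative rejection criteria with explicit defaults.
    """

    min_mutant_reads: int = 8
    end_window: int = 5
    max_end_fraction: float = 0.5
    homopolymer_min: int = 5
    microsat_unit_max: int = 6
    microsat_min_copies: int = 3
    microsat_min_span: int = 8
    indel_window: int = 5
    max_indel_reads: int = 0

    def validate(self) -> None:
        if self.min_mutant_reads < 1:
            raise ValueError("min_mutant_reads must be >= 1")
        if not 0.0 <= self.max_end_fraction <= 1.0:
            raise ValueError("max_end_fraction must lie in [0, 1]")


@dataclass
class PutativeSNP:
    """A candidate variant with its support evidence and artifact flags."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    alt_support: int
    total_depth: int
    alt_end_near: int = 0  # alt supports with end_offset < end_window
    flags: set[str] = field(default_factory=set)
    status: str = "putative"  # putative | confirmed | rejected


def call_putative(pile: Pileup, config: CallerConfig | None = None) -> list[PutativeSNP]:
    """Emit a putative SNP wherever some non-reference base reaches the threshold.

    The alternate allele is the best-supported non-reference base; ties are
    broken in fixed A<C<G<T order for determinism.
    """
    config = config or CallerConfig()
    config.validate()
    out: list[PutativeSNP] = []
    for contig in sorted(pile.contigs):
        cp = pile.contigs[contig]
        if cp.length == 0:
            continue
        ref_codes = encode(pile.reference[contig])
        counts = cp.counts.copy()
        cols = np.arange(cp.length)
        nonref = counts.copy()
        nonref[ref_codes, cols] = -1  # mask the reference base out
        best = nonref.argmax(axis=0)
        best_counts = nonref[best, cols]
        hits = np.flatnonzero(best_counts >= config.min_mutant_reads)
        depth = cp.depth()
        for i in hits:
            alt_code = int(best[i])
            out.append(
                PutativeSNP(
                    contig=contig,
                    pos=int(i) + 1,
                    ref_base=BASES[int(ref_codes[i])],
                    alt_base=BASES[alt_code],
                    alt_support=int(best_counts[i]),
                    total_depth=int(depth[i]),
                    alt_end_near=int(cp.end_near[alt_code, i]),
                )
            )
    return out


def flag_read_end(snp: PutativeSNP, pile: Pileup, config: CallerConfig) -> PutativeSNP:
    """Flag when the near-end fraction of alt support exceeds ``max_end_fraction``.

    The comparison is strict: a fraction exactly at the threshold passes.
    """
    if pile.end_window != config.end_window:
        raise ValueError(
            f"pileup was built with end_window={pile.end_window}, "
            f"caller expects {config.end_window}"
        )
    if snp.alt_support > 0:
        fraction = snp.alt_end_near / snp.alt_support
        if fraction > config.max_end_fraction:
            snp.flags.add("read_end")
    return snp


def flag_repeat_context(
    snp: PutativeSNP, reference: dict[str, str], config: CallerConfig
) -> PutativeSNP:
    """Flag positions inside (or, for runs, immediately adjacent to) repeats."""
    seq = reference[snp.contig]
    if not 1 <= snp.pos <= len(seq):
        raise IndexError(f"position {snp.pos} outside contig {snp.contig}")
    if in_homopolymer(seq, snp.pos, min_run=config.homopolymer_min):
        snp.flags.add("homopolymer")
    if in_microsatellite(
        seq,
        snp.pos,
        unit_max=config.microsat_unit_max,
        min_copies=config.microsat_min_copies,
        min_span=config.microsat_min_span,
    ):
        snp.flags.add("microsatellite")
    return snp


def flag_indel_shadow(snp: PutativeSNP, pile: Pileup, config: CallerConfig) -> PutativeSNP:
    """Flag when indel-open events within the (inclusive) window exceed the cap."""
    cp = pile.contigs[snp.contig]
    i = snp.pos - 1
    lo = max(0, i - config.indel_window)
    hi = min(cp.length, i + config.indel_window + 1)
    if int(cp.indel_open[lo:hi].sum()) > config.max_indel_reads:
        snp.flags.add("indel_shadow")
    return snp


def confirm(snps: list[PutativeSNP]) -> list[PutativeSNP]:
    """Set status confirmed/rejected by flag emptiness; return the confirmed subset."""
    confirmed = []
    for snp in snps:
        snp.status = "confirmed" if not snp.flags else "rejected"
        if snp.status == "confirmed":
            confirmed.append(snp)
    return confirmed


def run_filter_cascade(
    pile: Pileup,
    config: CallerConfig | None = None,
) -> tuple[list[PutativeSNP], list[PutativeSNP]]:
    """Call putative SNPs, apply all three filters, and confirm.

    Returns ``(all_putative, confirmed)``.
    """
    config = config or CallerConfig()
    snps = call_putative(pile, config)
    for snp in snps:
        flag_read_end(snp, pile, config)
        flag_repeat_context(snp, pile.reference, config)
        flag_indel_shadow(snp, pile, config)
    confirmed = confirm(snps)
    return snps, confirmed


def classify_titv(ref_base: str, alt_base: str) -> str:
    """Classify a substitution as ``transition`` or ``transversion``."""
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise ValueError("bases must be one of A, C, G, T")
    if ref_base == alt_base:
        raise ValueError("reference and alternate base are identical")
    same_class = (ref_base in PURINES) == (alt_base in PURINES)
    return "transition" if same_class else "transversion"


def write_vcf(snps: list[PutativeSNP], path: str, sample: str = "sample") -> None:
    """Write calls as a minimal VCF: FILTER carries flag names, INFO the counts."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=clonotyper ({sample})\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt read support">\n')
        for flt, desc in (
            ("read_end", "Alt support concentrated at read ends"),
            ("homopolymer", "Position in or adjacent to a homopolymer run"),
            ("microsatellite", "Position within a short tandem repeat"),
            ("indel_shadow", "Nearby insertion/deletion evidence"),
        ):
            fh.write(f'##FILTER=<ID={flt},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in sorted(snps, key=lambda s: (s.contig, s.pos)):
            filt = "PASS" if not snp.flags else ";".join(sorted(snp.flags))
            fh.write(
                f"{snp.contig}\t{snp.pos}\t.\t{snp.ref_base}\t{snp.alt_base}\t.\t"
                f"{filt}\tDP={snp.total_depth};AC={snp.alt_support}\n"
            )
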