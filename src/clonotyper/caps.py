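"""CAPS/RFLP marker design around a diagnostic SNP.

A CAPS (cleaved amplified polymorphic sequence) marker distinguishes two
alleles of a PCR amplicon by restriction digest: if the SNP creates or
destroys a recognition site, the two alleles yield different fragment
patterns on a gel.  This module scans degenerate (IUPAC) recognition
sites on both strands — including Type IIS enzymes such as HphI
(GGTGA, cutting 8 nucleotides downstream of the site) — predicts digest
fragment patterns, identifies diagnostic fragments, and ranks candidate
enzymes by gel distinguishability.

Sizing convention: each site contributes a single cut at the
recognition-strand top cut position projected onto reference coordinates.
The 1-nt stagger between the two duplex nicks (HphI 8/7) is ignored for
fragment sizing — a gel cannot resolve 1 nt — which makes digests exactly
reverse-complement symmetric.  Cuts whose offset runs past either end of a
linear amplicon produce no cut.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field

from clonotyper.seqs import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: degenerate recognition plus cut offsets.

    ``cut_offset_top`` is the number of bases downstream of the 3' end of
    the recognition sequence, on the recognition-bearing strand, at which
    the top strand is cut (0 = at the site boundary; negative = inside the
    site; HphI = 8).  ``cut_offset_bottom`` is carried as metadata only —
    fragment sizing uses the single-cut convention above.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int | None = None

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        for ch in self.recognition:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in recognition")
        if self.cut_offset_top < -len(self.recognition):
            raise ValueError("cut offset reaches upstream of the recognition site")


@dataclass
class SiteHit:
    """A recognition match: 1-based start on the + strand, strand, cut coordinate.

    The duplex is considered severed between ``cut_coordinate`` and
    ``cut_coordinate + 1``.
    """

    position: int
    strand: str
    cut_coordinate: int


@dataclass
class GelConfig:
    """What a 2% agarose gel can practically resolve."""

    min_detectable_length: int = 50
    min_relative_difference: float = 0.05


@dataclass
class DigestPattern:
    """Fragment-length multiset of a complete digest, descending."""

    fragment_lengths: list[int]

    @property
    def total(self) -> int:
        return sum(self.fragment_lengths)


@dataclass
class MarkerReport:
    """Per-enzyme comparison of two allele digests."""

    enzyme: Enzyme
    allele_labels: tuple[str, str]
    patterns: tuple[DigestPattern, DigestPattern]
    diagnostic_fragments: dict[str, list[int]]
    resolvable: bool
    score: float

    def to_dict(self) -> dict:
        a, b = self.allele_labels
        return {
            "enzyme": self.enzyme.name,
            "recognition": self.enzyme.recognition,
            "cut_offset_top": self.enzyme.cut_offset_top,
            "fragments": {a: self.patterns[0].fragment_lengths,
                          b: self.patterns[1].fragment_lengths},
            "diagnostic_fragments": self.diagnostic_fragments,
            "resolvable": self.resolvable,
            "score": self.score,
        }


def _pattern_regex(recognition: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[ch]}]" for ch in recognition))


def find_sites(seq: str, enzyme: Enzyme) -> list[SiteHit]:
    """All recognition matches on either strand, with projected cut coordinates.

    Overlapping and self-overlapping matches are all reported.  For a
    + strand match starting at ``p`` with recognition length ``m``, the cut
    falls after position ``p + m - 1 + offset``; for a − strand match
    (reverse complement of the recognition matching the + strand at ``p``),
    after position ``p - 1 - offset``.
    """
    seq = seq.upper()
    if not set(seq) <= set("ACGT"):
        raise ValueError("amplicon sequences must be plain ACGT")
    m = len(enzyme.recognition)
    off = enzyme.cut_offset_top
    hits: list[SiteHit] = []
    fwd = _pattern_regex(enzyme.recognition)
    for match in re.finditer(f"(?=({fwd.pattern}))", seq):
        p = match.start() + 1
        hits.append(SiteHit(position=p, strand="+", cut_coordinate=p + m - 1 + off))
    rev = _pattern_regex(revcomp(enzyme.recognition))
    if rev.pattern != fwd.pattern:
        for match in re.finditer(f"(?=({rev.pattern}))", seq):
            p = match.start() + 1
            hits.append(SiteHit(position=p, strand="-", cut_coordinate=p - 1 - off))
    # a palindromic recognition matches both strands at the same interval:
    # that is one site and, under the single-cut sizing convention, one cut
    # (the + orientation top-strand cut), so no extra hits are emitted
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def digest(seq: str, enzyme: Enzyme) -> DigestPattern:
    """Complete digest of a linear sequence: fragment lengths, descending.

    Cut coordinates outside the open interval (0, len) are discarded —
    an offset cutter whose cut runs off the amplicon end leaves no cut.
    """
    n = len(seq)
    cuts = sorted(
        {h.cut_coordinate for h in find_sites(seq, enzyme) if 0 < h.cut_coordinate < n}
    )
    bounds = [0] + cuts + [n]
    fragments = sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)
    return DigestPattern(fragment_lengths=fragments)


def compare_alleles(
    amplicon_a: str,
    amplicon_b: str,
    enzyme: Enzyme,
    gel: GelConfig | None = None,
    labels: tuple[str, str] = ("allele_A", "allele_B"),
) -> MarkerReport:
    """Digest both alleles and assess whether the enzyme distinguishes them.

    A fragment length is *diagnostic* when it appears in exactly one
    allele's pattern.  The marker is *resolvable* when some diagnostic
    fragment is at least ``min_detectable_length`` long and differs from
    every fragment of the other allele by at least
    ``min_relative_difference`` (relative to the larger of the pair).
    The score is the best such minimum relative difference.
    """
    gel = gel or GelConfig()
    pat_a = digest(amplicon_a, enzyme)
    pat_b = digest(amplicon_b, enzyme)
    set_a, set_b = set(pat_a.fragment_lengths), set(pat_b.fragment_lengths)
    diag = {
        labels[0]: sorted(set_a - set_b, reverse=True),
        labels[1]: sorted(set_b - set_a, reverse=True),
    }
    score = 0.0
    resolvable = False
    for own, other in ((labels[0], pat_b), (labels[1], pat_a)):
        for f in diag[own]:
            if f < gel.min_detectable_length:
                continue
            if other.fragment_lengths:
                min_rel = min(abs(f - g) / max(f, g) for g in other.fragment_lengths)
            else:
                min_rel = 1.0
            if min_rel >= gel.min_relative_difference:
                resolvable = True
                score = max(score, min_rel)
    return MarkerReport(
        enzyme=enzyme,
        allele_labels=labels,
        patterns=(pat_a, pat_b),
        diagnostic_fragments=diag,
        resolvable=resolvable,
        score=round(score, 4),
    )


def enumerate_enzymes(
    amplicon_a: str,
    amplicon_b: str,
    enzyme_library: list[Enzyme],
    gel: GelConfig | None = None,
    labels: tuple[str, str] = ("allele_A", "allele_B"),
) -> list[MarkerReport]:
    """Reports for every enzyme whose per-allele patterns differ, ranked.

    Ranking is by descending score, ties broken by enzyme name, and is
    invariant to library input order.
    """
    if not enzyme_library:
        raise ValueError("enzyme library is empty")
    reports = []
    for enz in enzyme_library:
        rep = compare_alleles(amplicon_a, amplicon_b, enz, gel, labels)
        if Counter(rep.patterns[0].fragment_lengths) != Counter(rep.patterns[1].fragment_lengths):
            reports.append(rep)
    reports.sort(key=lambda r: (-r.score, r.enzyme.name))
    return reports


_ENZYME_LINE = re.compile(r"^(\S+)\s+([A-Z]+)\((-?\d+)/(-?\d+)\)\s*$")


def parse_enzyme_library(text: str) -> list[Enzyme]:
    """Parse a REBASE-style two-column library: ``NAME  RECOG(top/bottom)``.

    Offsets are relative to the 3' end of the recognition sequence on the
    recognition-bearing strand; negative offsets cut within the site.
    Lines starting with ``#`` and blank lines are skipped.
    """
    enzymes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _ENZYME_LINE.match(line)
        if not m:
            raise ValueError(f"malformed enzyme library line {lineno}: {line!r}")
        name, recog, top, bottom = m.groups()
        enzymes.append(
            Enzyme(name=name, recognition=recog, cut_offset_top=int(top),
                   cut_offset_bottom=int(bottom))
        )
    return enzymes


def load_enzyme_library(path: str | None = None) -> list[Enzyme]:
    """Load an enzyme library file; default is the bundled mini-library."""
    if path is None:
        text = (
            importlib.resources.files("clonotyper") / "data" / "enzymes.txt"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return parse_enzyme_library(text)


def amplicon_window(genome: dict[str, str], contig: str, pos: int, length: int = 660) -> str:
    """Extract an amplicon-like window of ``length`` bases around a SNP.

    The window is centred on ``pos`` where possible and clipped at contig
    ends; mirrors a PCR product that encompasses the diagnostic SNP.
    """
    seq = genome[contig]
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside contig {contig}")
    half = length // 2
    start = max(0, min(pos - 1 - half, len(seq) - length))
    start = max(start, 0)
    return seq[start : start + length]


def render_gel(
    reports: list[MarkerReport],
    lane_order: list[str] | None = None,
    height: int = 18,
    include_undigested: bool = True,
) -> str:
    """Text rendering of the digest banding patterns.

    Lanes are one per allele per enzyme (plus undigested lanes); bands are
    positioned by log fragment length, largest at the top, as on a gel.
    """
    if not reports:
        raise ValueError("no marker reports to render")
    lanes: dict[str, list[int]] = {}
    for rep in reports:
        a, b = rep.allele_labels
        if include_undigested:
            lanes.setdefault(f"{a}:uncut", [rep.patterns[0].total])
            lanes.setdefault(f"{b}:uncut", [rep.patterns[1].total])
        lanes[f"{a}:{rep.enzyme.name}"] = rep.patterns[0].fragment_lengths
        lanes[f"{b}:{rep.enzyme.name}"] = rep.patterns[1].fragment_lengths
    if lane_order:
        lanes = {k: lanes[k] for k in lane_order}
    all_lengths = [f for frags in lanes.values() for f in frags if f > 0]
    lo, hi = math.log10(min(all_lengths)), math.log10(max(all_lengths))
    span = (hi - lo) or 1.0
    grid = {name: set() for name in lanes}
    for name, frags in lanes.items():
        for f in frags:
            if f <= 0:
                continue
            row = int(round((hi - math.log10(f)) / span * (height - 1)))
            grid[name].add(row)
    width = max(len(n) for n in lanes)
    lines = ["  ".join(n.ljust(width) for n in lanes)]
    for row in range(height):
        lines.append("  ".join(("=" * min(width, 6)).center(width) if row in grid[n] else " " * width for n in lanes))
    return "\n".join(lines)


def write_marker_reports(reports: list[MarkerReport], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
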