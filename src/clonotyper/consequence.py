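"""Codon-level consequence annotation of SNPs and protein motif scanning.

Gene models are CDS exon tables (1-based inclusive genomic intervals,
ordered 5'->3' on the coding strand); translation uses the standard
nuclear codon table via Biopython.  Both gene-relative and exon-relative
coordinates of a variant are reported, since published figures use either
numbering.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from clonotyper.seqs import revcomp

_AA = set("ACDEFGHIKLMNPQRSTVWY*")


@dataclass
class GeneModel:
    """A coding gene: ordered exon intervals on one strand of one contig."""

    gene_id: str
    contig: str
    strand: str  # + | -
    exons: list[tuple[int, int]]  # 1-based inclusive, ordered 5'->3' on coding strand

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        ivs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        genomic_order = [e[0] for e in self.exons]
        expect = sorted(genomic_order, reverse=self.strand == "-")
        if genomic_order != expect:
            raise ValueError("exons not ordered 5'->3' on the coding strand")

    def spliced_positions(self) -> list[int]:
        """Genomic positions of the spliced CDS in transcription order."""
        pos: list[int] = []
        for s, e in self.exons:
            rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
            pos.extend(rng)
        return pos

    def spliced_sequence(self, reference: dict[str, str]) -> str:
        seq = reference[self.contig]
        if self.strand == "+":
            return "".join(seq[s - 1 : e] for s, e in self.exons)
        return "".join(revcomp(seq[s - 1 : e]) for s, e in self.exons)


@dataclass
class Consequence:
    """Coding consequence of a single-base substitution."""

    gene_id: str
    gene_pos: int  # 1-based offset within the spliced CDS
    cds_pos: int
    codon_index: int  # 1-based codon number
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    aa_pos: int
    synonymous: bool
    exon_index: int  # 1-based, in coding order
    exon_offset: int  # 1-based offset within that exon (coding orientation)


@dataclass
class NonCoding:
    """Result for a variant outside the gene's exons (intronic or intergenic)."""

    gene_id: str
    reason: str = "non_coding"


def annotate_consequence(
    snp, gene: GeneModel, reference: dict[str, str]
) -> Consequence | NonCoding:
    """Annotate a substitution against a gene model.

    ``snp`` needs ``contig``, ``pos``, ``ref_base`` and ``alt_base``
    attributes.  Variants on minus-strand genes are complemented into
    coding orientation.  Returns :class:`NonCoding` for positions outside
    the exons rather than raising.
    """
    if snp.contig != gene.contig:
        return NonCoding(gene.gene_id, "different_contig")
    positions = gene.spliced_positions()
    try:
        idx = positions.index(snp.pos)
    except ValueError:
        return NonCoding(gene.gene_id)
    spliced = gene.spliced_sequence(reference)
    ref_base = snp.ref_base if gene.strand == "+" else revcomp(snp.ref_base)
    alt_base = snp.alt_base if gene.strand == "+" else revcomp(snp.alt_base)
    if spliced[idx] != ref_base:
        raise ValueError(
            f"reference mismatch at {gene.gene_id} position {idx + 1}: "
            f"spliced has {spliced[idx]}, variant claims {ref_base}"
        )
    gene_pos = idx + 1
    codon_index = idx // 3
    codon_start = codon_index * 3
    ref_codon = spliced[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return NonCoding(gene.gene_id, "incomplete_codon")
    alt_codon = ref_codon[: idx - codon_start] + alt_base + ref_codon[idx - codon_start + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    # exon-relative coordinate in coding orientation
    running = 0
    exon_index = exon_offset = 0
    for n, (s, e) in enumerate(gene.exons, start=1):
        length = e - s + 1
        if idx < running + length:
            exon_index = n
            exon_offset = idx - running + 1
            break
        running += length
    aa_pos = math.ceil(gene_pos / 3)
    return Consequence(
        gene_id=gene.gene_id,
        gene_pos=gene_pos,
        cds_pos=gene_pos,
        codon_index=codon_index + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        aa_pos=aa_pos,
        synonymous=ref_aa == alt_aa,
        exon_index=exon_index,
        exon_offset=exon_offset,
    )


def scan_motif(protein: str, pattern: str) -> list[int]:
    """All 1-based start positions where a wildcard motif matches exactly.

    The pattern uses one-letter amino-acid codes with ``x`` (or ``X``) as
    a single-residue wildcard, e.g. the MAP-kinase docking motif
    ``KKRxxKxxxxLxV``.  Overlapping matches are all reported.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    regex_parts = []
    for ch in pattern:
        up = ch.upper()
        if ch in "xX":
            regex_parts.append(".")
        elif up in _AA:
            regex_parts.append(re.escape(up))
        else:
            raise ValueError(f"invalid motif character {ch!r}")
    regex = re.compile(f"(?=({''.join(regex_parts)}))")
    return [m.start() + 1 for m in regex.finditer(protein.upper())]


def read_gene_models_tsv(path: str) -> list[GeneModel]:
    """Read gene models from an exon table TSV.

    Columns: gene_id, contig, strand, exon_start, exon_end; one row per
    exon, rows in 5'->3' coding order within a gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    models = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        contig = grp["contig"].iloc[0]
        strand = grp["strand"].iloc[0]
        exons = [(int(r.exon_start), int(r.exon_end)) for r in grp.itertuples()]
        models.append(GeneModel(gene_id=gene_id, contig=contig, strand=strand, exons=exons))
    return models


def read_gene_models_gff(path: str) -> list[GeneModel]:
    """Read CDS/exon features from a GFF3 subset, grouped by Parent/ID."""
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in ("CDS", "exon"):
                continue
            contig, _src, _type, start, end, _score, strand, _phase, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            gene_id = attr.get("Parent") or attr.get("ID") or "gene"
            rec = rows.setdefault(gene_id, {"contig": contig, "strand": strand, "exons": []})
            rec["exons"].append((int(start), int(end)))
    models = []
    for gene_id, rec in rows.items():
        exons = sorted(rec["exons"], reverse=rec["strand"] == "-")
        models.append(
            GeneModel(gene_id=gene_id, contig=rec["contig"], strand=rec["strand"], exons=exons)
        )
    return models
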