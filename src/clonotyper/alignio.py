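"""Alignment records and text-format I/O (SAM, FASTA, FASTQ, truth TSV).

The in-memory alignment container is deliberately minimal: contig, 1-based
leftmost coordinate, a CIGAR restricted to M/I/D/S, the reference-oriented
read sequence, strand and a mapped flag.  SAM round-trips go through pysam;
FASTA/FASTQ through Biopython.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_REF_CONSUMING = {"M", "D"}
_QUERY_CONSUMING = {"M", "I", "S"}


@dataclass
class AlignmentRecord:
    """One aligned (or unmapped) read.

    ``seq`` is stored in reference orientation (as in a SAM SEQ field);
    ``cigar`` is a list of ``(op, length)`` with op in M/I/D/S.
    """

    read_id: str
    contig: str | None
    start: int  # 1-based leftmost reference coordinate; 0 if unmapped
    cigar: list[tuple[str, int]] = field(default_factory=list)
    seq: str = ""
    strand: str = "+"
    mapped: bool = True

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_CONSUMING) or len(self.seq)


def cigar_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


_OP_CODES = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE_OPS = {v: k for k, v in _OP_CODES.items()}


def write_sam(records: list[AlignmentRecord], ref_lengths: dict[str, int], path: str) -> None:
    """Write records as plain-text SAM (unmapped reads get FLAG 4)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            if rec.mapped:
                a.reference_id = out.header.get_tid(rec.contig)
                a.reference_start = rec.start - 1
                a.cigartuples = [(_OP_CODES[op], n) for op, n in rec.cigar]
                a.flag = 16 if rec.strand == "-" else 0
                a.mapping_quality = 60
            else:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            out.write(a)


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read a text SAM file back into :class:`AlignmentRecord` objects."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=a.query_name,
                        contig=None,
                        start=0,
                        cigar=[],
                        seq=a.query_sequence or "",
                        mapped=False,
                    )
                )
                continue
            cigar = [(_CODE_OPS[code], n) for code, n in (a.cigartuples or [])]
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start + 1,
                    cigar=cigar,
                    seq=a.query_sequence or "",
                    strand="-" if a.is_reverse else "+",
                    mapped=True,
                )
            )
    return records


def write_fasta(sequences: dict[str, str], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()),
        path,
        "fasta",
    )


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads, path: str) -> None:
    """Write simulated reads (objects with id/sequence/qualities) as FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
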