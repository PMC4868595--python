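"""Shared fixtures and helpers for the test suite.

Pileup-construction helpers build alignment records directly so tests can
shape per-position support (depth, end offsets, indel evidence) exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from clonotyper.alignio import AlignmentRecord
from clonotyper.pileup import Pileup, build_pileup
from clonotyper.simulate import SimConfig


def make_alignments(reads: list[tuple[int, str]], contig: str = "c1") -> list[AlignmentRecord]:
    """Alignment records from (1-based start, sequence) pairs, all-match CIGARs."""
    return [
        AlignmentRecord(
            read_id=f"r{i}", contig=contig, start=start,
            cigar=[("M", len(seq))], seq=seq,
        )
        for i, (start, seq) in enumerate(reads)
    ]


def make_pileup(ref_seq: str, reads: list[tuple[int, str]], end_window: int = 5,
                contig: str = "c1") -> Pileup:
    return build_pileup(make_alignments(reads, contig), {contig: ref_seq}, end_window=end_window)


def column_reads(ref_seq: str, pos: int, alt: str, n_alt: int, n_ref: int,
                 read_len: int = 40) -> list[tuple[int, str]]:
    """Reads covering ``pos`` mid-read: ``n_alt`` carrying ``alt``, ``n_ref`` reference."""
    start = max(1, pos - read_len // 2)
    start = min(start, len(ref_seq) - read_len + 1)
    ref_read = ref_seq[start - 1 : start - 1 + read_len]
    i = pos - start
    alt_read = ref_read[:i] + alt + ref_read[i + 1 :]
    return [(start, alt_read)] * n_alt + [(start, ref_read)] * n_ref


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A fast, fully featured simulation: ~20 kb, reduced artifact counts."""
    return SimConfig(
        genome_length=20_000,
        n_homopolymers=5,
        n_microsatellites=5,
        artifacts_per_class=2,
        coverage_a=25.0,
        coverage_b=12.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
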