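"""Synthetic clonal-pair generator with a known truth table.

The module emulates the study design in which two nearly identical strain
genomes are compared against a common reference: a random reference genome
with planted homopolymer and microsatellite tracts, two strain genomes each
carrying one private transition SNP (C->T in strain A, A->G in strain B by
default), shotgun reads at ~35x / ~15x mean coverage with elevated error in
the terminal read window, engineered artifact loci for every false-positive
class the filter cascade must reject, and a contaminant read admixture.

Every planted difference — true SNP, artifact locus, contaminant source —
is recorded in a truth table so downstream calls can be scored exactly.
Artifact loci are engineered by construction rather than left to chance:
each receives a fixed number of dedicated reads carrying the artifact
pattern, so every class is guaranteed to be represented at callable support
under the default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from clonotyper.alignio import AlignmentRecord
from clonotyper.contaminants import default_contaminants
from clonotyper.repeats import in_homopolymer, in_microsatellite
from clonotyper.seqs import decode, encode, random_sequence, revcomp

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

ARTIFACT_CLASSES = (
    "artifact_read_end",
    "artifact_homopolymer",
    "artifact_microsatellite",
    "artifact_indel",
)

# sub-stream identifiers so each stage draws from an independent stream of
# the master seed
_STREAM_REF, _STREAM_DERIVE, _STREAM_ART, _STREAM_READS_A, _STREAM_READS_B = range(5)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic clonal pair.

    Coverage defaults (35x / 15x) and the single private transition SNP per
    strain mirror the sequencing depths and outcome of the motivating
    strain pair; repeat-tract and artifact counts are chosen so every
    false-positive class is represented several times in a 100 kb genome.
    """

    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_contigs: int = 2
    true_snps_per_strain: int = 1
    n_homopolymers: int = 6
    homopolymer_length: tuple[int, int] = (6, 12)
    n_microsatellites: int = 6
    microsat_unit_length: tuple[int, int] = (2, 4)
    microsat_copies: tuple[int, int] = (4, 8)
    coverage_a: float = 35.0
    coverage_b: float = 15.0
    read_length: int = 100
    base_error_rate: float = 0.001
    read_end_error_boost: float = 10.0
    end_window: int = 5
    contaminant_fraction: float = 0.02
    artifacts_per_class: int = 5
    artifact_read_count: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 0 or self.n_contigs < 1:
            raise ValueError("genome_length must be >= 0 and n_contigs >= 1")
        for name in ("gc_fraction", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.genome_length and self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        for name in (
            "true_snps_per_strain",
            "n_homopolymers",
            "n_microsatellites",
            "artifacts_per_class",
            "artifact_read_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coverage_a < 0 or self.coverage_b < 0:
            raise ValueError("coverages must be >= 0")
        if self.base_error_rate < 0 or self.base_error_rate > 1:
            raise ValueError("base_error_rate must lie in [0, 1]")


@dataclass
class SimRead:
    """A simulated read in instrument orientation.

    ``origin_pos`` is the 1-based leftmost reference coordinate of the
    alignment; ``cigar`` describes the true alignment (M/I/D runs) of the
    reference-oriented read.  Origin fields are ``None`` for contaminants.
    """

    id: str
    sequence: str
    qualities: str
    origin_contig: str | None = None
    origin_pos: int | None = None
    origin_strand: str | None = None
    cigar: list[tuple[str, int]] = field(default_factory=list)
    is_contaminant: bool = False


@dataclass
class SimResult:
    """Everything the simulator produced, with full truth."""

    config: SimConfig
    reference: dict[str, str]
    features: pd.DataFrame
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    truth: pd.DataFrame
    reads_a: list[SimRead]
    reads_b: list[SimRead]
    alignments_a: list[AlignmentRecord]
    alignments_b: list[AlignmentRecord]


def _contig_lengths(config: SimConfig) -> dict[str, int]:
    base = config.genome_length // config.n_contigs
    lengths = {}
    for i in range(config.n_contigs):
        extra = config.genome_length - base * config.n_contigs if i == 0 else 0
        lengths[f"contig_{i + 1}"] = base + extra
    return lengths


_EMPTY_FEATURES = ["contig", "start", "end", "kind", "unit"]
_TRUTH_COLS = ["contig", "pos", "ref", "alt", "strain", "klass"]


def generate_reference(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random reference genome plus a feature table of planted repeat tracts.

    Returns ``(genome, features)`` where features has columns
    contig/start/end/kind/unit (1-based inclusive coordinates).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_REF])
    if config.genome_length == 0:
        return {}, pd.DataFrame(columns=_EMPTY_FEATURES)
    genome = {
        name: encode(random_sequence(rng, length, config.gc_fraction))
        for name, length in _contig_lengths(config).items()
        if length > 0
    }
    features: list[dict] = []
    contigs = list(genome)

    # tracts stay clear of contig ends so artifact reads around them fit,
    # and clear of each other so repeat classes do not overlap
    margin = config.read_length + 50 if config.genome_length >= 4 * config.read_length else 25

    def place(kind: str, tract: str, unit: str) -> None:
        span = len(tract)
        for _attempt in range(2000):
            contig = contigs[rng.integers(len(contigs))]
            arr = genome[contig]
            if len(arr) < span + 2 * margin:
                continue
            start0 = int(rng.integers(margin, len(arr) - span - margin))
            clash = any(
                f["contig"] == contig
                and start0 + 1 <= f["end"] + 25
                and start0 + span >= f["start"] - 25
                for f in features
            )
            if clash:
                continue
            arr[start0 : start0 + span] = encode(tract)
            features.append(
                {"contig": contig, "start": start0 + 1, "end": start0 + span,
                 "kind": kind, "unit": unit}
            )
            return
        raise ValueError(f"could not place {kind} tract of length {span}")

    for _ in range(config.n_homopolymers):
        length = int(rng.integers(config.homopolymer_length[0], config.homopolymer_length[1] + 1))
        base = "ACGT"[rng.integers(4)]
        place("homopolymer", base * length, base)
    for _ in range(config.n_microsatellites):
        u = int(rng.integers(config.microsat_unit_length[0], config.microsat_unit_length[1] + 1))
        copies = int(rng.integers(config.microsat_copies[0], config.microsat_copies[1] + 1))
        # a unit that is itself a homopolymer would just extend a run
        while True:
            unit = decode(rng.integers(0, 4, size=u).astype(np.uint8))
            if len(set(unit)) > 1:
                break
        place("microsatellite", unit * copies, unit)

    out = {name: decode(arr) for name, arr in genome.items()}
    feat = pd.DataFrame(features, columns=_EMPTY_FEATURES)
    return out, feat


def _position_is_clean(seq: str, pos: int, config: SimConfig) -> bool:
    """Position suitable for a planted true SNP or read-engineered artifact."""
    margin = config.read_length + 10
    if not margin <= pos <= len(seq) - margin:
        return False
    if in_homopolymer(seq, pos, min_run=5):
        return False
    if in_microsatellite(seq, pos, unit_max=6, min_copies=3, min_span=8):
        return False
    return True


def _pick_clean_positions(
    reference: dict[str, str],
    rng: np.random.Generator,
    config: SimConfig,
    n: int,
    taken: list[tuple[str, int]],
    required_base: str | None = None,
    min_separation: int | None = None,
) -> list[tuple[str, int]]:
    sep = min_separation if min_separation is not None else 2 * config.read_length
    contigs = [c for c in reference if len(reference[c]) >= 2 * (config.read_length + 10)]
    if not contigs:
        raise ValueError("no contig long enough for planted positions")
    chosen: list[tuple[str, int]] = []
    for _ in range(n):
        for attempt in range(5000):
            contig = contigs[int(rng.integers(len(contigs)))]
            seq = reference[contig]
            pos = int(rng.integers(config.read_length + 10, len(seq) - config.read_length - 9))
            if required_base is not None and seq[pos - 1] != required_base:
                continue
            if not _position_is_clean(seq, pos, config):
                continue
            if any(c == contig and abs(p - pos) < sep for c, p in taken + chosen):
                continue
            chosen.append((contig, pos))
            break
        else:
            raise ValueError("not enough clean non-repeat positions for planted variants")
    return chosen


def derive_strain_genomes(
    reference: dict[str, str], config: SimConfig
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Derive strain genomes A and B, each with its private planted SNPs.

    The default configuration plants one transition per strain (C->T in A,
    A->G in B) at clean non-repeat positions.  Returns both genomes and the
    true-SNP truth table.
    """
    config.validate()
    if not reference:
        raise ValueError("reference genome is empty")
    rng = np.random.default_rng([config.seed, _STREAM_DERIVE])
    truth: list[dict] = []
    taken: list[tuple[str, int]] = []
    genomes = {"A": {c: list(s) for c, s in reference.items()},
               "B": {c: list(s) for c, s in reference.items()}}
    first_base = {"A": "C", "B": "A"}
    for strain in ("A", "B"):
        for i in range(config.true_snps_per_strain):
            base = first_base[strain] if i == 0 else None
            (contig, pos), = _pick_clean_positions(
                reference, rng, config, 1, taken, required_base=base
            )
            taken.append((contig, pos))
            ref_base = reference[contig][pos - 1]
            alt = TRANSITION[ref_base]
            genomes[strain][contig][pos - 1] = alt
            truth.append(
                {"contig": contig, "pos": pos, "ref": ref_base, "alt": alt,
                 "strain": strain, "klass": "true_snp"}
            )
    genome_a = {c: "".join(s) for c, s in genomes["A"].items()}
    genome_b = {c: "".join(s) for c, s in genomes["B"].items()}
    return genome_a, genome_b, pd.DataFrame(truth, columns=_TRUTH_COLS)


def plan_artifacts(
    reference: dict[str, str], features: pd.DataFrame, truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Choose the loci at which read-level artifacts will be engineered.

    Homopolymer/microsatellite artifacts sit inside planted repeat tracts;
    read-end and indel artifacts sit at clean positions.  Loci alternate
    between strains A and B so both read sets exercise the filters.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ART])
    rows: list[dict] = []
    taken = [(r.contig, int(r.pos)) for r in truth.itertuples()]

    def record(contig: str, pos: int, klass: str, strain: str) -> None:
        ref_base = reference[contig][pos - 1]
        rows.append(
            {"contig": contig, "pos": pos, "ref": ref_base,
             "alt": TRANSITION[ref_base], "strain": strain, "klass": klass}
        )
        taken.append((contig, pos))

    for kind, klass in (("homopolymer", "artifact_homopolymer"),
                        ("microsatellite", "artifact_microsatellite")):
        tracts = features[features["kind"] == kind]
        if config.artifacts_per_class > len(tracts):
            raise ValueError(f"not enough {kind} tracts for requested artifacts")
        idx = rng.choice(len(tracts), size=config.artifacts_per_class, replace=False)
        for j, i in enumerate(sorted(int(x) for x in idx)):
            t = tracts.iloc[i]
            pos = int((t.start + t.end) // 2)
            margin = config.read_length + 10
            pos = min(max(pos, margin), len(reference[t.contig]) - margin)
            record(t.contig, pos, klass, "A" if j % 2 == 0 else "B")

    for j_class, klass in enumerate(("artifact_read_end", "artifact_indel")):
        positions = _pick_clean_positions(
            reference, rng, config, config.artifacts_per_class, taken
        )
        for j, (contig, pos) in enumerate(positions):
            record(contig, pos, klass, "A" if (j + j_class) % 2 == 0 else "B")
    return pd.DataFrame(rows, columns=_TRUTH_COLS)


def _quality_string(read_length: int, end_window: int) -> str:
    # flat Q40 except the terminal windows (Q13): qualities are carried for
    # format fidelity only, counting downstream is quality-blind
    w = min(end_window, read_length // 2)
    return "." * w + "I" * (read_length - 2 * w) + "." * w


def simulate_reads(
    genome: dict[str, str],
    coverage: float,
    config: SimConfig,
    *,
    strain: str = "A",
    rng: np.random.Generator | None = None,
    artifacts: pd.DataFrame | None = None,
    contaminants: dict[str, str] | None = None,
) -> list[SimRead]:
    """Simulate shotgun reads from a strain genome.

    Background reads are uniform-start with per-base substitution errors,
    boosted ``read_end_error_boost``-fold inside the terminal
    ``end_window``; artifact loci (if given) receive
    ``artifact_read_count`` dedicated reads each; contaminant reads are
    drawn from the contaminant set at ``contaminant_fraction``.
    """
    config.validate()
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if rng is None:
        rng = np.random.default_rng(
            [config.seed, _STREAM_READS_A if strain == "A" else _STREAM_READS_B]
        )
    rl = config.read_length
    qual = _quality_string(rl, config.end_window)
    reads: list[SimRead] = []

    # per-offset error probability: boosted inside either terminal window
    rate = np.full(rl, config.base_error_rate)
    w = min(config.end_window, rl // 2)
    if w:
        rate[:w] *= config.read_end_error_boost
        rate[-w:] *= config.read_end_error_boost
    rate = np.clip(rate, 0.0, 1.0)

    n_background = 0
    for contig, seq in genome.items():
        L = len(seq)
        if L < rl:
            raise ValueError(f"read_length {rl} exceeds contig {contig} length {L}")
        n = int(rng.poisson(L * coverage / rl)) if coverage > 0 else 0
        if n == 0:
            continue
        n_background += n
        enc = encode(seq)
        starts = rng.integers(0, L - rl + 1, size=n)
        mat = enc[starts[:, None] + np.arange(rl)[None, :]]
        if config.base_error_rate > 0:
            err = rng.random((n, rl)) < rate[None, :]
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        strands = rng.integers(0, 2, size=n)
        for i in range(n):
            fwd = decode(mat[i])
            minus = bool(strands[i])
            reads.append(
                SimRead(
                    id=f"{strain}_{contig}_{i}",
                    sequence=revcomp(fwd) if minus else fwd,
                    qualities=qual,
                    origin_contig=contig,
                    origin_pos=int(starts[i]) + 1,
                    origin_strand="-" if minus else "+",
                    cigar=[("M", rl)],
                )
            )

    if artifacts is not None and len(artifacts):
        reads.extend(_artifact_reads(genome, artifacts, config, rng, strain, qual))

    if config.contaminant_fraction > 0 and n_background:
        pool = contaminants if contaminants is not None else default_contaminants()
        n_cont = int(rng.binomial(n_background, config.contaminant_fraction))
        names = list(pool)
        weights = np.array([len(pool[k]) for k in names], dtype=float)
        weights /= weights.sum()
        for i in range(n_cont):
            src = names[int(rng.choice(len(names), p=weights))]
            s = pool[src]
            start = int(rng.integers(0, len(s) - rl + 1))
            frag = s[start : start + rl]
            if rng.integers(2):
                frag = revcomp(frag)
            reads.append(
                SimRead(
                    id=f"{strain}_contam_{src}_{i}",
                    sequence=frag,
                    qualities=qual,
                    is_contaminant=True,
                )
            )
    return reads


def _artifact_reads(
    genome: dict[str, str],
    artifacts: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    strain: str,
    qual: str,
) -> list[SimRead]:
    rl = config.read_length
    out: list[SimRead] = []
    mine = artifacts[artifacts["strain"] == strain]
    for row in mine.itertuples():
        seq = genome[row.contig]
        pos, alt = int(row.pos), row.alt
        for i in range(config.artifact_read_count):
            if row.klass == "artifact_read_end":
                off = i % max(1, config.end_window)
                if i % 2 == 0:  # variant near read start
                    start = pos - off
                else:  # variant near read end
                    start = pos + off - rl + 1
                start = min(max(start, 1), len(seq) - rl + 1)
                frag = list(seq[start - 1 : start - 1 + rl])
                frag[pos - start] = alt
                out.append(
                    SimRead(
                        id=f"{strain}_art_read_end_{row.contig}_{pos}_{i}",
                        sequence="".join(frag),
                        qualities=qual,
                        origin_contig=row.contig,
                        origin_pos=start,
                        origin_strand="+",
                        cigar=[("M", rl)],
                    )
                )
            elif row.klass == "artifact_indel":
                jitter = int(rng.integers(-10, 11))
                start = min(max(pos - rl // 2 + jitter, 1), len(seq) - rl)
                d0 = pos + 1  # 0-based index of the deleted reference base (pos+2)
                m1 = d0 - (start - 1)
                frag = list(seq[start - 1 : d0] + seq[d0 + 1 : d0 + 1 + (rl - m1)])
                frag[pos - start] = alt
                out.append(
                    SimRead(
                        id=f"{strain}_art_indel_{row.contig}_{pos}_{i}",
                        sequence="".join(frag),
                        qualities=qual,
                        origin_contig=row.contig,
                        origin_pos=start,
                        origin_strand="+",
                        cigar=[("M", m1), ("D", 1), ("M", rl - m1)],
                    )
                )
            else:  # repeat-context artifacts: mid-read substitutions
                jitter = int(rng.integers(-10, 11))
                start = min(max(pos - rl // 2 + jitter, 1), len(seq) - rl + 1)
                frag = list(seq[start - 1 : start - 1 + rl])
                frag[pos - start] = alt
                out.append(
                    SimRead(
                        id=f"{strain}_art_{row.klass[9:]}_{row.contig}_{pos}_{i}",
                        sequence="".join(frag),
                        qualities=qual,
                        origin_contig=row.contig,
                        origin_pos=start,
                        origin_strand="+",
                        cigar=[("M", rl)],
                    )
                )
    return out


def emit_truth_alignments(reads: list[SimRead], genome: dict[str, str]) -> list[AlignmentRecord]:
    """Convert simulated reads into truth alignment records.

    Stands in for a read mapper: each non-contaminant read is placed at its
    known origin with the CIGAR of the injected edits; contaminant reads
    become unmapped records.
    """
    records: list[AlignmentRecord] = []
    for r in reads:
        if r.is_contaminant:
            records.append(
                AlignmentRecord(read_id=r.id, contig=None, start=0, cigar=[],
                                seq=r.sequence, mapped=False)
            )
            continue
        if r.origin_contig not in genome:
            raise ValueError(f"read {r.id} references unknown contig {r.origin_contig}")
        ref_oriented = revcomp(r.sequence) if r.origin_strand == "-" else r.sequence
        records.append(
            AlignmentRecord(
                read_id=r.id,
                contig=r.origin_contig,
                start=r.origin_pos,
                cigar=list(r.cigar),
                seq=ref_oriented,
                strand=r.origin_strand,
            )
        )
    return records


def simulate_clonal_pair(config: SimConfig | None = None, **overrides) -> SimResult:
    """Run the full generator: reference, strains, truth, reads, alignments."""
    config = replace(config or SimConfig(), **overrides)
    config.validate()
    reference, features = generate_reference(config)
    genome_a, genome_b, truth_snps = derive_strain_genomes(reference, config)
    if config.artifacts_per_class > 0:
        artifacts = plan_artifacts(reference, features, truth_snps, config)
    else:
        artifacts = pd.DataFrame(columns=_TRUTH_COLS)
    contaminants = default_contaminants()
    reads_a = simulate_reads(
        genome_a, config.coverage_a, config, strain="A",
        artifacts=artifacts, contaminants=contaminants,
    )
    reads_b = simulate_reads(
        genome_b, config.coverage_b, config, strain="B",
        artifacts=artifacts, contaminants=contaminants,
    )
    truth = pd.concat([truth_snps, artifacts], ignore_index=True)
    if config.contaminant_fraction > 0:
        contam_rows = pd.DataFrame(
            [{"contig": name, "pos": 0, "ref": ".", "alt": ".", "strain": "-",
              "klass": "contaminant"} for name in contaminants],
            columns=_TRUTH_COLS,
        )
        truth = pd.concat([truth, contam_rows], ignore_index=True)
    return SimResult(
        config=config,
        reference=reference,
        features=features,
        genome_a=genome_a,
        genome_b=genome_b,
        truth=truth,
        reads_a=reads_a,
        reads_b=reads_b,
        alignments_a=emit_truth_alignments(reads_a, genome_a),
        alignments_b=emit_truth_alignments(reads_b, genome_b),
    )
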