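"""End-to-end orchestration: simulate -> pileup -> call/filter -> assemble ->
marker design, with a machine-readable run report.

The pipeline mirrors the analysis order of a clonal-pair comparison:
generate (or load) the strain pair, build per-strain pileups against the
reference, call and triage SNPs, assemble unmapped reads and classify the
contigs, and design a CAPS marker around the first confirmed
strain-specific SNP.  The run report is deterministic JSON keyed by a
configuration hash, so identical configurations reproduce identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import yaml

from clonotyper import alignio, caps
from clonotyper.assembly import AssemblyConfig, assemble, classify_contigs, collect_unmapped
from clonotyper.caps import GelConfig, amplicon_window, enumerate_enzymes, load_enzyme_library
from clonotyper.contaminants import default_contaminants
from clonotyper.pileup import build_pileup, coverage_summary, divergence_rate
from clonotyper.simulate import SimConfig, simulate_clonal_pair
from clonotyper.snpcall import CallerConfig, classify_titv, run_filter_cascade, write_vcf

log = logging.getLogger("clonotyper")


@dataclass
class RunConfig:
    """Stage toggles and per-module configurations for one pipeline run."""

    outdir: str = "clonotyper_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    gel: GelConfig = field(default_factory=GelConfig)
    amplicon_length: int = 660
    stages: tuple[str, ...] = ("simulate", "pileup", "call", "assemble", "design")

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "caller": dataclasses.asdict(self.caller),
            "assembly": dataclasses.asdict(self.assembly),
            "gel": dataclasses.asdict(self.gel),
            "amplicon_length": self.amplicon_length,
            "stages": list(self.stages),
        }

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages in dependency order; return the run report.

    Artifacts (FASTA/FASTQ/SAM/VCF/TSV/JSON) are written under
    ``config.outdir``; the report is also written as ``report.json``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": _package_version(),
        },
        "stages": {},
    }
    stages = set(config.stages)
    sim = None
    piles = {}
    calls = {}

    if "simulate" in stages:
        try:
            sim = simulate_clonal_pair(config.sim)
            _write_sim(sim, config.outdir)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("simulate", exc) from exc
        report["stages"]["simulate"] = {
            "genome_length": sum(len(s) for s in sim.reference.values()),
            "n_contigs": len(sim.reference),
            "reads_a": len(sim.reads_a),
            "reads_b": len(sim.reads_b),
            "truth_counts": dict(Counter(sim.truth["klass"])),
        }
        log.info("[simulate] %s", report["stages"]["simulate"])

    if "pileup" in stages:
        if sim is None:
            raise StageError("pileup", ValueError("pileup requires the simulate stage"))
        try:
            out = {}
            for strain, aln in (("A", sim.alignments_a), ("B", sim.alignments_b)):
                pile = build_pileup(aln, sim.reference, end_window=config.caller.end_window)
                piles[strain] = pile
                cov = coverage_summary(pile, k=config.caller.min_mutant_reads)
                div = divergence_rate(pile, min_depth=config.caller.min_mutant_reads)
                out[strain] = {
                    "breadth_at_k": round(cov.breadth_at_k, 4),
                    "k": cov.k,
                    "mean_depth": round(cov.mean_depth, 2),
                    "divergence_rate": None if not div.defined else round(div.rate, 6),
                    "callable_positions": div.n_callable,
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("pileup", exc) from exc
        report["stages"]["pileup"] = out
        log.info("[pileup] %s", out)

    if "call" in stages:
        if not piles:
            raise StageError("call", ValueError("call requires the pileup stage"))
        try:
            out = {}
            for strain, pile in piles.items():
                putative, confirmed = run_filter_cascade(pile, config.caller)
                calls[strain] = (putative, confirmed)
                write_vcf(putative, os.path.join(config.outdir, f"snps_{strain}.vcf"),
                          sample=f"strain_{strain}")
                flag_counts = Counter(f for s in putative for f in s.flags)
                out[strain] = {
                    "putative": len(putative),
                    "confirmed": len(confirmed),
                    "rejected": len(putative) - len(confirmed),
                    "flags": dict(flag_counts),
                    "confirmed_snps": [
                        {
                            "contig": s.contig, "pos": s.pos, "ref": s.ref_base,
                            "alt": s.alt_base, "support": s.alt_support,
                            "titv": classify_titv(s.ref_base, s.alt_base),
                        }
                        for s in confirmed
                    ],
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("call", exc) from exc
        report["stages"]["call"] = out
        log.info("[call] %s", {k: {x: v[x] for x in ("putative", "confirmed")} for k, v in out.items()})

    if "assemble" in stages:
        if sim is None:
            raise StageError("assemble", ValueError("assemble requires the simulate stage"))
        try:
            out = {}
            screen = default_contaminants()
            unmapped = {s: collect_unmapped(a) for s, a in
                        (("A", sim.alignments_a), ("B", sim.alignments_b))}
            for strain, other in (("A", "B"), ("B", "A")):
                contigs = (
                    assemble(unmapped[strain], config.assembly) if unmapped[strain] else []
                )
                if contigs:
                    classify_contigs(contigs, unmapped[other], screen, strain=strain,
                                     k=config.assembly.k)
                alignio.write_fasta(
                    {c.id: c.sequence for c in contigs},
                    os.path.join(config.outdir, f"unmapped_contigs_{strain}.fasta"),
                )
                out[strain] = {
                    "contigs": len(contigs),
                    "classifications": dict(Counter(c.classification for c in contigs)),
                    "strain_specific_non_contaminant": sum(
                        c.classification.startswith("specific") for c in contigs
                    ),
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("assemble", exc) from exc
        report["stages"]["assemble"] = out
        log.info("[assemble] %s", out)

    if "design" in stages:
        if not calls or sim is None:
            raise StageError("design", ValueError("design requires the call stage"))
        try:
            confirmed_a = calls["A"][1]
            if not confirmed_a:
                report["stages"]["design"] = {"markers": [], "note": "no confirmed SNP in strain A"}
            else:
                snp = confirmed_a[0]
                amp_a = amplicon_window(sim.genome_a, snp.contig, snp.pos, config.amplicon_length)
                amp_b = amplicon_window(sim.genome_b, snp.contig, snp.pos, config.amplicon_length)
                reports = enumerate_enzymes(
                    amp_a, amp_b, load_enzyme_library(), config.gel,
                    labels=("strain_A", "strain_B"),
                )
                caps.write_marker_reports(
                    reports, os.path.join(config.outdir, "marker_reports.json")
                )
                report["stages"]["design"] = {
                    "snp": {"contig": snp.contig, "pos": snp.pos,
                            "ref": snp.ref_base, "alt": snp.alt_base},
                    "markers": [
                        {"enzyme": r.enzyme.name, "resolvable": r.resolvable,
                         "score": r.score}
                        for r in reports
                    ],
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("design", exc) from exc
        log.info("[design] %s", report["stages"]["design"])

    path = os.path.join(config.outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_sim(sim, outdir: str) -> None:
    alignio.write_fasta(sim.reference, os.path.join(outdir, "reference.fasta"))
    alignio.write_fasta(sim.genome_a, os.path.join(outdir, "strain_A.fasta"))
    alignio.write_fasta(sim.genome_b, os.path.join(outdir, "strain_B.fasta"))
    alignio.write_truth_table(sim.truth, os.path.join(outdir, "truth.tsv"))
    sim.features.to_csv(os.path.join(outdir, "repeat_features.tsv"), sep="\t", index=False)
    ref_lengths = {name: len(seq) for name, seq in sim.reference.items()}
    for strain, reads, aln in (("A", sim.reads_a, sim.alignments_a),
                               ("B", sim.reads_b, sim.alignments_b)):
        alignio.write_fastq(reads, os.path.join(outdir, f"reads_{strain}.fastq"))
        alignio.write_sam(aln, ref_lengths, os.path.join(outdir, f"alignments_{strain}.sam"))


def typing_assay(sample_amplicon: str | None, enzyme: caps.Enzyme, target_pattern: list[int]) -> str:
    """Type one sample amplicon against a designed marker.

    Returns ``marker-positive`` when the digest reproduces the target
    allele's fragment pattern, ``marker-negative`` when it does not, and
    ``no-amplification`` for an absent or empty amplicon (the outcome for
    strains whose locus does not amplify).
    """
    if not sample_amplicon:
        return "no-amplification"
    pattern = caps.digest(sample_amplicon, enzyme)
    if Counter(pattern.fragment_lengths) == Counter(target_pattern):
        return "marker-positive"
    return "marker-negative"


def _package_version() -> str:
    from clonotyper import __version__

    return __version__
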