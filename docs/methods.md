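# Methods

This document records the model behind each module, the defaults and why
they were chosen, and the numerical/representational conventions. All
quantitative claims below are either definitional or checked by the test
suite; nothing here reports an empirical result that the tests do not
compute.

## Synthetic clonal-pair model (`clonotyper.simulate`)

The simulator exists so that every downstream stage can be validated
against known ground truth. It emulates the *statistical shape* of a
near-clonal comparison, not any particular instrument:

* **Reference genome** — uniform random sequence at a configurable GC
  fraction (default 0.5), split over `n_contigs` (default 2) totalling
  `genome_length` bases (default 100 kb — large enough for thousands of
  artifact opportunities, small enough to simulate and call in seconds on
  one CPU). Homopolymer tracts (default 6 of length 6–12) and
  microsatellite tracts (default 6, unit 2–4 bp, 4–8 copies) are planted
  at recorded coordinates, kept clear of contig ends by at least
  `read_length + 50` bases so that engineered artifact reads always fit.
* **Strain genomes** — each strain receives `true_snps_per_strain`
  private substitutions (default 1) at positions outside repeat context
  and at least two read lengths apart. The first planted SNP per strain
  is forced to be a transition (C→T for strain A, A→G for strain B),
  matching the observation that strain-diagnostic differences in
  near-clonal pairs are typically transitions; additional SNPs use a
  fixed transition map.
* **Reads** — fixed-length (default 100 bp) uniformly placed reads at
  Poisson per-contig counts targeting `coverage_a`/`coverage_b`
  (defaults 35×/15×, an asymmetric pair representative of one deeply and
  one shallowly sequenced strain). Base errors are i.i.d. at
  `base_error_rate` (default 10⁻³), boosted 10-fold inside the terminal
  `end_window` (default 5 bp) to model degraded base quality at read
  ends.
* **Engineered artifact loci** — `artifacts_per_class` loci (default 5)
  for each of four classes. Artifacts are *engineered by construction*:
  each locus receives 12 dedicated reads carrying the artifact signature
  (read-end loci place the variant base inside the terminal window,
  repeat-class loci sit inside planted tracts, indel loci add a 1 bp
  deletion opening two bases downstream), guaranteeing deterministically
  that every artifact locus clears the 8-read calling threshold and
  carries its signature. This is a design decision: probabilistic
  artifact generation at realistic rates would make truth recovery a
  flaky property, whereas the cascade's job — reject a locus *given* its
  signature — is exactly testable with engineered support.
* **Contaminants** — a `contaminant_fraction` (default 2%) binomial
  admixture of reads drawn from bundled synthetic contaminant sequences
  (see below). Contaminant reads appear as unmapped records in the
  emitted alignments.
* **Truth table** — every planted locus (true SNP, artifact with its
  class, contaminant) with contig, position, ref/alt and strain.

Alignments are emitted from the simulator's own ground truth (position,
strand, CIGAR), i.e. a perfect mapper is assumed; mapping error is
represented only through its artifact signatures (indel shadows,
repeat-context mismatches), which is what the filter cascade actually
consumes.

**Determinism.** All randomness flows from
`numpy.random.default_rng([seed, stream])` with a fixed stream id per
stage, so the same seed reproduces the same genomes, reads and
alignments bit-for-bit regardless of which stages run.

## Pileup (`clonotyper.pileup`)

Dense per-contig arrays: a 4×L base-support matrix, a 4×L matrix counting
supports whose read-end offset (distance to the nearer read end) is
below `end_window`, and an L-vector of indel-open events (a deletion
counts at its first deleted position, an insertion at the preceding
reference position). Deletions consume reference without contributing
base support. Coverage breadth at depth k uses all reference positions
in the denominator (zero-depth positions count against breadth);
divergence rate is the fraction of positions at depth ≥ k whose
plurality base differs from the reference (ties including the reference
resolve to the reference), reported as undefined (NaN) when no position
is callable rather than as zero.

## Calling and artifact triage (`clonotyper.snpcall`)

A putative SNP is any position where some non-reference base has at
least `min_mutant_reads` supporting reads (default 8 — the read-count
rule this package is built around). The best-supported non-reference
base is the alternate; ties break in fixed A<C<G<T order for
determinism. Three filters then implement the manual triage criteria:

* `read_end` — flagged when the fraction of alternate support lying
  within the terminal `end_window` is *strictly greater* than
  `max_end_fraction` (default 0.5): a call exactly half-supported by
  read ends still passes.
* `homopolymer` / `microsatellite` — flagged when the position lies in a
  single-base run of ≥ 5 (including the two positions immediately
  adjacent to such a run, since a substitution bordering a long run is
  equally unreliable), or within a tandem repeat of unit ≤ 6 spanning
  ≥ 8 bases with ≥ 3 unit copies.
* `indel_shadow` — flagged when any read opens an insertion or deletion
  within ± 5 positions (inclusive) of the call.

A putative SNP is confirmed iff its flag set is empty. The cascade is
validated against an independent plain-loop re-implementation
(`tests/oracles.py`) on randomized pileups.

## Consequence annotation (`clonotyper.consequence`)

Gene models are ordered exon interval lists on one strand; the spliced
CDS is translated with the standard nuclear code (Biopython). Variants
on minus-strand genes are complemented into coding orientation; both
CDS-relative and exon-relative coordinates are reported because
published variant descriptions use either numbering. Intronic/intergenic
positions return a `NonCoding` result rather than raising. Motif
scanning compiles one-letter patterns with `x` wildcards to regex and
reports all (overlapping) 1-based match starts.

## Mini assembler and contaminant screen (`clonotyper.assembly`)

Canonical-k-mer de Bruijn assembly (default k = 21, abundance floor 2,
minimum contig 100 bp) emitting maximal non-branching paths. Determinism
is favoured over assembly quality: k-mers are traversed in sorted order
and contigs are emitted in canonical orientation, sorted by descending
length. Classification runs the contaminant screen first (best
offset-consistent ungapped match against the screen set; contaminant at
≥ 90 % identity over ≥ 80 % of the contig), then cross-maps the other
strain's unmapped reads (k-mer breadth ≥ 90 % → shared, else
strain-specific). For a genuinely clonal pair the expected outcome is
zero strain-specific non-contaminant contigs.

The bundled screen sequences (`clonotyper.contaminants`) are *synthetic
stand-ins*: random sequences of the approximate length and GC content of
a phiX-like sequencing control (5,386 bp, GC 0.44) and a generic
high-GC foreign sequence, generated from fixed internal seeds. They are
not the real phiX174 genome; shipping real reference records is outside
this package's text-only data budget, and the classification logic only
needs *a* known screen set.

## CAPS marker design (`clonotyper.caps`)

Recognition sites are degenerate IUPAC patterns matched on both strands
with overlap; Type IIS offsets are expressed relative to the 3′ end of
the recognition sequence on the recognition-bearing strand (HphI =
GGTGA(8/7); negative offsets cut inside the site, as for EcoRI = −5).

**Sizing convention.** Each site contributes a single cut at the
top-strand cut position of the recognition-bearing strand, projected
onto plus-strand coordinates (a plus-strand site at p with recognition
length m cuts after p + m − 1 + offset; a minus-strand site after
p − 1 − offset). The 1-nt stagger between the duplex nicks is ignored —
a gel cannot resolve 1 nt — which makes digests of non-palindromic
enzymes exactly reverse-complement symmetric (checked by test). A
palindromic recognition matching both strands at the same interval is
one site and one cut. Cuts projected outside the open interval (0, len)
of a linear amplicon are discarded: an offset cutter whose cut runs off
the end leaves no cut. Under this convention fragment multisets agree
exactly with Bio.Restriction for blunt/palindromic enzymes and for
offset cutters whose sites all lie on the plus strand (both used as
oracles in the tests); for minus-strand sites of staggered offset
cutters the two conventions differ by the 1-nt stagger.

An enzyme *resolves* two alleles when some diagnostic fragment (a length
present in exactly one allele's pattern) is at least
`min_detectable_length` (default 50 bp) and differs from every fragment
of the other allele by at least `min_relative_difference` (default 5 %,
relative to the larger) — a practical model of a 2 % agarose gel.
Enzyme ranking is by best such relative difference, ties by name, and is
input-order invariant.

## Phenotype analysis (`clonotyper.phenotype`)

* **QC** — readings strictly above `max_absorbance` (default 2.0, the
  usable ceiling of plate photometers) are excluded; a reading of
  exactly 2.0 is retained. Wells containing conidia are excluded by
  default because spore pigmentation contaminates absorbance.
* **Clustering** — strain × compound replicate-mean matrices (missing
  cells stay NaN, never zero) are clustered by UPGMA on distance
  1 − r (Pearson over shared compounds), clamped to [0, 1] so the
  reported similarity scale runs from 0 (complete dissimilarity,
  including perfect anti-correlation) to 1 (complete similarity). The
  correlation-based metric is a deliberate stand-in for any particular
  instrument vendor's proprietary similarity; only the scale convention
  is pinned.
* **LSD** — one-way ANOVA, then
  l.s.d. = t(1 − α/2, df_error) · √(2·MSE/n) with harmonic-mean n for
  unbalanced designs; compact letters from maximal runs of sorted means
  within one l.s.d.
* **ΔCq** — quantification cycle of target minus reference gene; lower
  ΔCq = higher relative expression. Rows with missing Cq are dropped
  with a warning, never imputed.
* **Conidiation** — integer scores 0–5 per well, averaged within
  replicate then across replicates.

## Pipeline (`clonotyper.pipeline`, `clonotyper.cli`)

`run_pipeline` chains simulate → pileup → call → assemble → design,
writing FASTA/FASTQ/SAM/VCF/TSV artifacts plus a JSON report keyed by a
SHA-256 hash of the full configuration; identical configurations produce
identical reports (tested). Marker design runs around the first
confirmed strain-A SNP on a centred amplicon window (default 660 bp). A
run may legitimately find no resolvable marker — whether any library
enzyme's site overlaps the SNP context depends on the sequence, exactly
as in real marker design. Stage failures raise `StageError` (CLI exit
code 2); input errors exit 1.

## Problem sizes

Defaults (100 kb genome, 35×/15× coverage, 5 artifact loci per class,
k = 21 assembly) are this package's own choice of a desk-scale regime:
large enough that artifact triage dominates true variation (the regime
of interest), small enough that the full pipeline plus test suite runs
in seconds on one CPU.
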