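# clonotyper

Genome comparison and marker design for near-clonal microbial strains.

## The problem

Two independently isolated strains of the same fungus or bacterium can be
near-clonal: their genomes differ at only a handful of positions. Proving
that such strains are genuinely distinct — and building a cheap routine
assay to tell them apart — runs into an unusual regime for variant
calling: almost every candidate SNP between the two genomes is a
sequencing or alignment artifact, because there are thousands of artifact
opportunities and only one or two real differences. The standard
practice is to call candidates with a simple read-count rule and then
manually triage them against a short list of known artifact signatures.

`clonotyper` packages that workflow end to end, with a synthetic data
generator so every step can be validated against known ground truth:

* **simulate** — generate a reference genome with planted homopolymer and
  microsatellite tracts, derive two near-clonal strain genomes (one
  private transition each by default), and simulate reads including
  engineered artifact loci of four classes (read-end errors, homopolymer,
  microsatellite, indel-shadow) plus a contaminant read admixture. A
  truth table records every planted locus.
* **pileup** — per-position base support with read-end offsets and
  indel-open evidence; coverage breadth and divergence-rate summaries.
* **snpcall** — the read-count caller (a putative SNP needs at least 8
  supporting mutant reads by default) followed by the artifact filter
  cascade; a putative SNP is *confirmed* only if it carries no artifact
  flag. Ti/Tv classification and minimal VCF output included.
* **consequence** — codon-level annotation of confirmed SNPs against exon
  gene models (synonymous vs non-synonymous, e.g. an alanine-to-valine
  substitution) and protein motif scanning with single-residue wildcards.
* **microasm** (`clonotyper.assembly`) — a small deterministic de Bruijn
  assembler for reads that fail to map, with contaminant screening and
  shared/strain-specific classification: the genome-content cross-check
  that a clonal pair has no strain-specific extra content.
* **capsdesign** (`clonotyper.caps`) — CAPS/RFLP marker design: find
  restriction sites (including Type IIS offset cutters such as HphI,
  GGTGA(8/7)) whose presence differs between the two alleles, predict
  digest fragment patterns, rank enzymes by gel distinguishability, and
  render a text gel.
* **phenotab** (`clonotyper.phenotype`) — phenotype-microarray support:
  absorbance QC (readings above 2.0 are excluded by default), UPGMA
  clustering of strain catabolic profiles on a [0, 1] similarity scale,
  Fisher's unprotected LSD with compact letters, delta-Cq relative
  expression, and conidiation score summaries.
* **pipeline / CLI** — `clonotyper run-all` chains
  simulate → pileup → call → assemble → design and writes a deterministic
  JSON run report keyed by a configuration hash.

## Worked example

Simulate a default clonal pair (100 kb, coverages 35×/15×, one private
transition per strain, five engineered artifact loci per class) and run
the caller on strain A:

```python
from clonotyper.simulate import SimConfig, simulate_clonal_pair
from clonotyper.pileup import build_pileup, coverage_summary
from clonotyper.snpcall import CallerConfig, run_filter_cascade

sim = simulate_clonal_pair(SimConfig(seed=7))
pile = build_pileup([a for a in sim.alignments_a if a.mapped], sim.reference)
cov = coverage_summary(pile, k=8)
print(f"breadth_at_8={cov.breadth_at_k:.4f} mean_depth={cov.mean_depth:.2f}")
putative, confirmed = run_filter_cascade(pile, CallerConfig())
print(f"putative={len(putative)} confirmed={len(confirmed)}")
for s in confirmed:
    print(f"confirmed SNP {s.contig}:{s.pos} {s.ref_base}->{s.alt_base} support={s.alt_support}")
```

Output:

```
breadth_at_8=0.9990 mean_depth=34.85
putative=12 confirmed=1
confirmed SNP contig_1:9523 C->T support=30
```

The 11 rejected putative SNPs are the strain's engineered artifact loci;
the one confirmed call matches the truth table's planted transition
exactly (`sim.truth` lists `contig_1:9523 C->T` for strain A).

Designing a CAPS marker for a C→T transition that creates an HphI site
(two 200 bp alleles that differ at one base):

```python
from clonotyper.caps import compare_alleles, load_enzyme_library

lib = {e.name: e for e in load_enzyme_library()}
site_allele    = "TAAAGGTGAAGGTAGAAGCGAAAAT" * 8
no_site_allele = "TAAAGGCGAAGGTAGAAGCGAAAAT" * 8
rep = compare_alleles(site_allele, no_site_allele, lib["HphI"])
print("fragments A:", rep.patterns[0].fragment_lengths)
print("fragments B:", rep.patterns[1].fragment_lengths)
print("diagnostic:", rep.diagnostic_fragments, "resolvable:", rep.resolvable)
```

Output:

```
fragments A: [25, 25, 25, 25, 25, 25, 25, 17, 8]
fragments B: [200]
diagnostic: {'allele_A': [25, 17, 8], 'allele_B': [200]} resolvable: True
```

The same steps are available from the command line; see
`clonotyper --help` (subcommands `simulate`, `pileup`, `call`,
`assemble`, `design`, `pheno`, `expr`, `run-all`, `type`).

## Layout

```
src/clonotyper/     library (simulate, pileup, snpcall, consequence,
                    assembly, caps, phenotype, pipeline, cli)
src/clonotyper/data enzyme mini-library (text)
tests/              pytest suite, including acceptance properties
scripts/            acceptance measurement script
docs/methods.md     model, conventions and numerical choices
```
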