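# bsamap

Mapping-by-sequencing (bulked segregant analysis, BSA-seq) of EMS-induced
mutations in diploid plants, as a tested, reusable Python pipeline — plus a
forward-genetics simulator that generates inputs with exactly the genetic
structure the analysis assumes, so every stage can be validated against a
known ground truth.

The package is aimed at forward-genetics groups mapping recessive EMS
mutants from two phenotype-selected DNA bulks: one pooled from wild-type
segregants and one from mutant segregants of a backcrossed, selfed pedigree
(e.g. BC₂S₁).

## What it computes

**Filter cascade.** For a recessive causal mutation m in a BC₂S₁
population, the mutant bulk (m/m plants) carries the alternate allele at
frequency AF = 1, while the phenotypically wild-type bulk (a mix of +/+ and
+/m plants) has AF well below ½ (¼ for a fixed 1:1 mix, ⅓ for a random 1:2
draw). Candidate SNPs are distilled from a two-bulk VCF in four conjunctive
stages, each with configurable thresholds:

1. **allele frequency** — AF_mut = 1 (optionally AF_mut ≥ 1 − tol to absorb
   sequencing error) and AF_wt ≤ 0.3, where AF = alt-AD / (ref-AD + alt-AD);
2. **EMS canonicality** — ref>alt is G>A or C>T as written on the reference
   strand (the transitions EMS induces);
3. **call quality** — GQ ≥ 90 and DP ≥ 10 in both bulks;
4. **impact** — the variant is protein-altering (HIGH or MODERATE impact
   from the built-in gene-model-aware annotator).

A blacklist VCF of variants shared across independently derived mutant
families (fixed line-vs-reference differences) can be subtracted first, and
a sliding-window scan of alternate AF along each chromosome locates the
linked peak region.

**Effect annotation.** Region classification (CDS > splice site > UTR >
intron > intergenic), codon/amino-acid change by splicing the CDS in
transcription order (minus-strand genes reverse-complemented), and an
impact class per standard annotator conventions.

**Simulator.** Toy genomes with translatable multi-exon gene models on both
strands, EMS mutagenesis (Binomial per G/C base), shared background
variants, Poisson-crossover meiosis, backcross/self pedigrees with carrier
selection, deterministic-recessive phenotypes with per-flower
andromonoecy-index (AI) scores, phenotype-selected bulks, and pooled
sequencing with Poisson depth, binomial read sampling, and a
likelihood-based diploid-pool genotype caller (GT/AD/DP/GQ).

**Phenotype statistics.** Plant/genotype AI, sex-class binning, χ²
segregation goodness-of-fit, genotype-phenotype co-segregation, and Livak
2^−ΔΔCt relative expression.

## Worked example

Simulate an experiment (BC₂S₁ pedigree, 300 plants, 30+30 bulks, one causal
CDS missense, 200 linked intergenic EMS passengers, 100 background
variants, depth 500×) and run the cascade:

```bash
$ bsamap simulate --outdir demo --seed 7 --mean-depth 500
wrote demo/genome.fasta, genes.gff3, bulks.vcf, truth.tsv
causal site: chr1:833 C>T

$ bsamap filter demo/bulks.vcf demo/genes.gff3 demo/genome.fasta --af-mut-tol 0.01
stage	count
total	301
allele_frequency	2
ems_canonical	2
quality	2
impact	1

chrom	pos	ref	alt	gene	effect	impact	annotation
chr1	833	C	T	gene1	P5L	MODERATE	simulated protein-coding gene 1
```

Reading the report: of 301 simulated SNPs, 2 satisfy the two-bulk allele
frequency signature (AF ≈ 1 in the mutant bulk, ≤ 0.3 in the WT bulk), both
are canonical EMS transitions with good calls, and exactly one is
protein-altering — a P5L missense (proline→leucine at residue 5), which is
the simulator's ground-truth causal site at chr1:833. The same steps are
available as library calls (`bsamap.pipeline.simulate_experiment`,
`bsamap.pipeline.run_bsa`).

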