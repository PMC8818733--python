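# Methods

This note documents the models implemented in `bsamap`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open.

## The mapping design being modelled

A recessive EMS mutant is backcrossed twice to its background genotype and
selfed (BC₂S₁ by default; the scheme is configuration, and BC₁S₁ or a plain
self are accepted). The selfed progeny of a heterozygous carrier segregates
1:2:1 at the causal locus, i.e. 3:1 phenotypically. Two 30-plant DNA bulks
are formed from the segregants: a mutant bulk of homozygous (1/1) plants —
causal-site allele frequency exactly 1 — and a phenotypically wild-type
bulk mixing 0/0 and 0/1 plants. Sequencing both bulks and filtering SNPs on
this AF signature, EMS canonicality, call quality and protein impact
isolates the causal candidate; co-segregation over the full population then
confirms it.

## Simulator

**Genomes.** Random A/C/G/T chromosomes with non-overlapping,
single-transcript gene models placed round-robin across chromosomes,
alternating strands. Every model is complete: ATG start, in-frame stop, no
internal stop, CDS length divisible by 3, ≥ 2 exons (intron lengths 30–120
bp, UTRs 5–30 bp). By default each gene carries a proline codon (CCA) at
residue 5, emulating the invariant N-terminal proline of plant ACO
(1-aminocyclopropane-1-carboxylate oxidase) enzymes; `make_causal_missense`
therefore prefers a P5L-style causal change (C>T or G>A on the reference
strand, canonical EMS either way). This is cosmetic — any EMS-compatible
missense position is accepted when the conserved codon is disabled.

**Mutations.** EMS mutagenesis flips each G/C base independently with the
given rate to the canonical transition (G>A, C>T as written on the
reference strand; reverse-strand events already appear in this form in VCF
coordinates, so no complementing is done anywhere). Background variants are
fixed line-vs-reference differences: homozygous in the founder *and* the
background parent, hence AF ≈ 1 in both bulks. They model the shared
variants that real pipelines remove by blacklisting across mutant families;
with a seeded generator, a sibling simulation reproduces the same set, which
is what makes blacklist subtraction exact.

**Founder zygosity.** The founder is an M1-like plant: heterozygous at
every EMS site and homozygous for background variants. This single choice
makes the Mendelian arithmetic exact — selfing gives 1:2:1 at every EMS
site, and an unlinked passenger survives two backcrosses heterozygous with
probability (1/2)². At each intermediate pedigree step a carrier
heterozygous at the causal site is selected to continue (marker-assisted
selection in miniature).

**Meiosis.** Poisson(crossover_rate) crossovers per chromosome (default
mean 1), breakpoints uniform, no interference, free recombination between
chromosomes. This is the simplest model that produces the linkage structure
the AF scan relies on; genetic map length is therefore ~50 cM per
chromosome regardless of physical size.

**Phenotype.** Deterministic recessive: mutant iff 1/1 at the causal site;
partial penetrance is deliberately not modelled (the analysis it feeds
assumes complete co-segregation). Mutant plants draw per-flower
stamen-development scores from a categorical distribution over {0,1,2,3}
(default (0.1, 0.1, 0.4, 0.4), chosen so the expected plant AI is 2.1);
wild-type plants score 0 on every flower.

**Bulks.** The mutant bulk is drawn from 1/1 plants, optionally ranked by
plant AI descending ("extreme-AI" selection; ties broken by a seeded
shuffle so selection is deterministic). The WT bulk is drawn from
phenotypic wild types; a random draw from the 1:2 mixture of 0/0 and 0/1
gives expected causal AF ⅓, while the explicit `composition=(15, 15)`
option pins the true AF at 0.25 — the designed condition used by the
end-to-end tests, reflecting a genotype-balanced bulk.

**Sequencing.** Per site and bulk: DP ~ Poisson(mean depth, default 45),
alt reads ~ Binomial(DP, p(1−e) + (1−p)e) with per-base error e (default
1e-3). GT is the maximum-likelihood diploid-pool call over expected alt
fractions {e, ½, 1−e} and GQ the phred-scaled gap to the second-best
likelihood, capped at 99 — monotone in evidence and cheap; real callers'
GQ models are more elaborate, but only ordering matters to the cascade.
Zero-coverage sites are emitted as `./.` with undefined AF. The emitted VCF
contains *all* simulated sites, including those lost from both bulks during
the pedigree (a real variant caller would simply not report these; they
carry near-zero AF and are inert in the cascade, but they do dilute
windowed AF means). Read-level simulation (FASTQ), alignment, indels, and
multi-allelic sites are out of scope.

## Filter cascade

Stages run in the fixed reporting order AF → EMS → quality → impact. The
set of survivors is a pure conjunction and thus order-independent; only the
per-stage counts depend on the order (a property the tests check against an
independent brute-force implementation).

Numerical choices:

- "AF = 1" in the mutant bulk defaults to strict equality, i.e. zero
  reference-supporting reads. With sequencing error e and depth D, a truly
  fixed site shows at least one error read with probability 1 − exp(−De)
  (≈ 39% at D = 500, e = 1e-3), so `recommended_filter_params` relaxes the
  test to AF ≥ 1 − tol with tol = min(0.02, 10e): an order of magnitude
  above the expected error-read fraction, generous to Poisson fluctuation,
  and exactly strict again for error-free data.
- The WT-side comparator defaults to ≤ 0.3 and the quality comparators to
  GQ ≥ 90, DP ≥ 10; strict (<, >) variants are a flag away, since published
  descriptions of such filters are not always consistent about boundaries.
- Quality thresholds apply to **both** bulks: a failed call in either bulk
  corrupts an AF test that is symmetric in the two bulks.
- Undefined AF (zero depth) fails the AF stage.

**AF scan.** Windows tile each chromosome (default window = chromosome
length / 50, step = window); per-window mean alternate AF per bulk, NaN
windows carry no sites. A window joins a peak when the mutant-bulk mean is
≥ 0.9 and the WT-bulk mean is ≤ 0.3 + 0.1; consecutive qualifying windows
merge. Thresholds are heuristics for the plateau a linked region produces
and are fully configurable; no smoothing (loess etc.) is applied.

## Effect annotation

Region precedence CDS > splice site > UTR > intron > intergenic; splice
sites are the 2 bp at each end of every intron (canonical donor/acceptor).
CDS variants are located in the spliced transcript, and reference and
mutant codons translated with the standard genetic code; start-loss,
stop-gain and stop-loss are detected explicitly. Amino-acid changes are
reported as refAA + residue + altAA (e.g. P5L). Overlapping gene models are
all annotated and the most severe call wins. One transcript per gene (the
first mRNA); non-ATG starts are rejected at GFF3 load. The impact taxonomy
is the standard one (missense = MODERATE); which classes count as mapping
candidates is a separate cascade parameter defaulting to {HIGH, MODERATE},
so a protein-altering missense is a candidate without corrupting the
taxonomy.

The annotator's correctness oracle is independent of its codon arithmetic:
tests mutate the chromosome sequence, re-splice and re-translate the whole
CDS, and diff the proteins, over ≥ 1000 randomized gene/variant cases on
both strands.

## Phenotype and expression statistics

AI is the arithmetic mean of per-flower scores; genotype-level AI is the
mean of plant means (not the pooled flower mean). Records with fewer than
10 flowers are accepted with a warning — the 10-flower minimum is protocol,
not a formula. Sex classes: AI = 0 monoecious, AI ≥ 2.5 andromonoecious,
otherwise partially andromonoecious; the 2.5 edge is a labelling
convenience and configurable. Segregation uses the one-df χ² goodness of
fit (scipy). Co-segregation scores phenotype against the recessive
prediction (mutant iff 1/1), lists discordant plants, and excludes
ungenotyped records with a warning. Relative expression follows Livak:
ΔCt = Ct_target − Ct_reference, ΔΔCt relative to the mean calibrator ΔCt
(multiple calibrators are averaged on the ΔCt scale, the standard
practice), fold = 2^−ΔΔCt.

## Problem sizes and determinism

The default simulated experiment uses 2 × 150 kb chromosomes, 6 genes,
300 BC₂S₁ plants, 30+30 bulks, 200 linked intergenic passengers and 100
background variants — small enough that a full simulate-and-map run takes
well under a second, while preserving every structural feature the analysis
depends on (linkage, phenotype selection, both bulk AF signatures). What
passing tests on these inputs does **not** show: behaviour under alignment
or calling artefacts, indels, structural variants, incomplete penetrance,
or population structure — none of which the generator emulates. Every
stochastic component takes an explicit integer seed and identical inputs
plus seed give byte-identical outputs, including written FASTA/GFF3/VCF.

## Known limitations

- Single-transcript gene models; no isoforms, no non-coding genes.
- The pooled genotype caller is intentionally minimal (three-point
  likelihood); GQ values are comparable within a run, not calibrated to any
  external caller.
- The AF scan's peak caller is threshold-based; on sparse windows it can
  fragment a plateau rather than bridging it.
- Chromosome-scale realism (hotspots, interference, centromeres) is absent.
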