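"""Gene-model-aware SNP effect annotation.

Classifies each variant by genic region (CDS > splice site > UTR > intron >
intergenic), computes codon and amino-acid changes for CDS variants by
splicing the CDS in transcription order (reverse-complementing minus-strand
genes), and assigns an impact class.

Impact taxonomy follows the usual annotator conventions (missense is
MODERATE, premature stops and splice-site hits are HIGH); which classes make
a variant a mapping candidate is a separate, configurable choice in the
filter cascade, where the default candidate set is {HIGH, MODERATE} so that
a protein-altering missense qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .simgenetics import (
    GeneModel,
    ToyGenome,
    VariantSite,
    complement_base,
    translate_codon,
)

REGIONS = ("intergenic", "intron", "five_prime_utr", "three_prime_utr",
           "splice_site", "cds")
IMPACTS = ("MODIFIER", "LOW", "MODERATE", "HIGH")

#: 2 bp on each side of every exon/intron junction (canonical donor and
#: acceptor dinucleotides) count as splice site.
SPLICE_SITE_WIDTH = 2

#: Region precedence for classification, most specific first.
_REGION_PRECEDENCE = ("cds", "splice_site", "five_prime_utr",
                      "three_prime_utr", "intron")

DEFAULT_IMPACT_POLICY: dict[str, str] = {
    "stop_gain": "HIGH",
    "stop_loss": "HIGH",
    "start_loss": "HIGH",
    "splice_site": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "intron": "MODIFIER",
    "five_prime_utr": "MODIFIER",
    "three_prime_utr": "MODIFIER",
    "intergenic": "MODIFIER",
}


@dataclass(frozen=True)
class EffectCall:
    """Predicted effect of a SNP on (at most) one gene model."""

    gene_id: str | None
    region: str
    codon_change: str | None = None
    aa_change: str | None = None
    impact: str = "MODIFIER"
    kind: str | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")
        if (self.aa_change is not None) != (self.region == "cds"):
            raise ValueError("aa_change is present iff the variant is in CDS")

    @property
    def severity(self) -> int:
        return IMPACTS.index(self.impact)


def classify_impact(kind_or_call, policy: Mapping[str, str] | None = None) -> str:
    """Impact class for an effect kind, region name, or EffectCall."""
    policy = dict(DEFAULT_IMPACT_POLICY, **(policy or {}))
    if isinstance(kind_or_call, EffectCall):
        key = kind_or_call.kind or kind_or_call.region
    else:
        key = kind_or_call
    try:
        return policy[key]
    except KeyError:
        raise ValueError(f"no impact defined for {key!r}") from None


def _region_in_gene(pos: int, gene: GeneModel) -> str | None:
    """Region of ``pos`` within one gene; None when outside the gene span."""
    s, e = gene.span
    if not s <= pos <= e:
        return None
    for cs, ce, _ in gene.cds:
        if cs <= pos <= ce:
            return "cds"
    for is_, ie in gene.introns():
        if is_ <= pos <= ie:
            if pos < is_ + SPLICE_SITE_WIDTH or pos > ie - SPLICE_SITE_WIDTH:
                return "splice_site"
            return "intron"
    # inside an exon but outside the CDS: a UTR
    if not gene.cds:
        return "intron"
    cds_start = min(c[0] for c in gene.cds)
    cds_end = max(c[1] for c in gene.cds)
    for xs, xe in gene.exons:
        if xs <= pos <= xe:
            if pos < cds_start:
                return "five_prime_utr" if gene.strand == "+" else "three_prime_utr"
            return "three_prime_utr" if gene.strand == "+" else "five_prime_utr"
    return "intron"


def classify_region(
    variant: VariantSite,
    genes: Sequence[GeneModel],
    *,
    chrom_names: Iterable[str] | None = None,
) -> tuple[str | None, str]:
    """(gene_id, region) under the stated precedence; (None, intergenic) outside."""
    if chrom_names is not None and variant.chrom not in set(chrom_names):
        raise KeyError(f"unknown chromosome: {variant.chrom}")
    best: tuple[str | None, str] | None = None
    best_rank = len(_REGION_PRECEDENCE)
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        region = _region_in_gene(variant.pos, gene)
        if region is None:
            continue
        rank = _REGION_PRECEDENCE.index(region)
        if rank < best_rank:
            best, best_rank = (gene.gene_id, region), rank
    return best if best is not None else (None, "intergenic")


def predict_protein_effect(
    variant: VariantSite,
    gene: GeneModel,
    genome: ToyGenome,
    policy: Mapping[str, str] | None = None,
) -> EffectCall:
    """Codon- and protein-level effect of a CDS SNP.

    Splices the CDS in transcription order, locates the variant's codon,
    and translates reference and mutant codons with the standard genetic
    code. Detects missense, synonymous, stop-gain, stop-loss and start-loss.
    """
    if gene.cds_length % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    seq = genome.sequence(gene.chrom)
    if seq[variant.pos - 1] != variant.ref:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: ref {variant.ref} does not match genome"
        )
    positions = gene.cds_genomic_positions()
    hits = np.nonzero(positions == variant.pos)[0]
    if hits.size == 0:
        raise ValueError(
            f"{variant.chrom}:{variant.pos} is not in the CDS of {gene.gene_id}"
        )
    i = int(hits[0])
    minus = gene.strand == "-"
    cds = gene.transcript_cds(seq)
    talt = complement_base(variant.alt) if minus else variant.alt
    ci, off = divmod(i, 3)
    ref_codon = cds[3 * ci : 3 * ci + 3]
    alt_codon = ref_codon[:off] + talt + ref_codon[off + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ci == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        kind = "start_loss"
    elif ref_aa == "*" and alt_aa != "*":
        kind = "stop_loss"
    elif alt_aa == "*" and ref_aa != "*":
        kind = "stop_gain"
    elif ref_aa == alt_aa:
        kind = "synonymous"
    else:
        kind = "missense"
    return EffectCall(
        gene_id=gene.gene_id,
        region="cds",
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{ci + 1}{alt_aa}",
        impact=classify_impact(kind, policy),
        kind=kind,
    )


def annotate_variant(
    variant: VariantSite,
    genome: ToyGenome,
    policy: Mapping[str, str] | None = None,
) -> EffectCall:
    """Most severe effect of a variant over all overlapping gene models."""
    if variant.chrom not in genome.chrom_lengths:
        raise KeyError(f"unknown chromosome: {variant.chrom}")
    calls: list[EffectCall] = []
    for gene in genome.genes_on(variant.chrom):
        region = _region_in_gene(variant.pos, gene)
        if region is None:
            continue
        if region == "cds":
            calls.append(predict_protein_effect(variant, gene, genome, policy))
        else:
            calls.append(
                EffectCall(gene_id=gene.gene_id, region=region,
                           impact=classify_impact(region, policy), kind=region)
            )
    if not calls:
        return EffectCall(gene_id=None, region="intergenic",
                          impact=classify_impact("intergenic", policy),
                          kind="intergenic")
    return max(calls, key=lambda c: c.severity)


def annotate_all(
    variants: Iterable[VariantSite],
    genome: ToyGenome,
    policy: Mapping[str, str] | None = None,
) -> dict[tuple, EffectCall]:
    """Effect call per variant key, for feeding the filter cascade."""
    return {v.key: annotate_variant(v, genome, policy) for v in variants}


def effects_to_frame(effects: Mapping[tuple, EffectCall]) -> pd.DataFrame:
    rows = []
    for (chrom, pos, ref, alt), call in effects.items():
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": call.gene_id or ".",
                "region": call.region,
                "codon_change": call.codon_change or ".",
                "aa_change": call.aa_change or ".",
                "impact": call.impact,
            }
        )
    return pd.DataFrame(rows)


def load_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> ToyGenome:
    """Load a reference genome and its gene models from FASTA + GFF3.

    One transcript per gene (the first mRNA); CDS phase column honoured;
    models whose CDS does not begin with ATG are rejected outright.
    """
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path), ":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        mrnas = list(db.children(feat, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else feat
        exons = tuple(
            (f.start, f.end)
            for f in db.children(parent, featuretype="exon", order_by="start")
        )
        cds = tuple(
            (f.start, f.end, int(f.frame) if f.frame != "." else 0)
            for f in db.children(parent, featuretype="CDS", order_by="start")
        )
        if not exons:
            exons = tuple((s, e) for s, e, _ in cds)
        desc = feat.attributes.get("description", [None])[0]
        gene = GeneModel(
            gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
            exons=exons, cds=cds, description=desc,
        )
        if gene.cds:
            if gene.chrom not in seqs:
                raise ValueError(f"gene {gene.gene_id}: no sequence for {gene.chrom}")
            start = gene.transcript_cds(seqs[gene.chrom])[:3]
            if start != "ATG":
                raise ValueError(
                    f"gene {gene.gene_id}: start codon is {start}, not ATG"
                )
        genes.append(gene)
    return ToyGenome(chromosomes=tuple(seqs.items()), genes=tuple(genes))
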