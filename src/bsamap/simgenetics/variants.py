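"""Mutation models: EMS transitions, shared background variants, causal pick.

EMS (ethyl methanesulfonate) alkylates guanine, producing almost exclusively
G>A and C>T transitions as written on the reference strand; the mutagenesis
model only ever touches G/C bases. Background variants represent fixed
differences between the mutant line's genetic background and the reference
assembly — they are homozygous in every founder and therefore show up at
allele frequency 1 in both bulks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import GeneModel, ToyGenome, complement_base, translate_codon

_EMS_ALT = {"G": "A", "C": "T"}


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic SNP with simulation ground truth attached.

    ``origin`` is ``"EMS"``, ``"background"`` or ``None`` (unknown, e.g. when
    read back from a VCF without a truth table).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str | None = None
    is_causal: bool = False

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: only SNVs are supported")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        if self.origin not in (None, "EMS", "background"):
            raise ValueError(f"unknown variant origin: {self.origin!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_ems_canonical(self) -> bool:
        return (self.ref, self.alt) in (("G", "A"), ("C", "T"))


def _eligible_gc_positions(
    genome: ToyGenome,
    chroms: Sequence[str] | None,
    intergenic_only: bool,
) -> list[tuple[str, np.ndarray]]:
    """Per chromosome, 0-based indices of G/C bases (optionally intergenic)."""
    out = []
    for name, seq in genome.chromosomes:
        if chroms is not None and name not in chroms:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        mask = (arr == ord("G")) | (arr == ord("C"))
        if intergenic_only:
            for gene in genome.genes_on(name):
                s, e = gene.span
                mask[s - 1 : e] = False
        out.append((name, mask))
    return out


def mutagenize_ems(
    genome: ToyGenome,
    rate: float,
    seed: int = 0,
    *,
    chroms: Sequence[str] | None = None,
    intergenic_only: bool = False,
) -> list[VariantSite]:
    """Induce canonical EMS transitions at the given per-eligible-base rate.

    Each G/C base mutates independently with probability ``rate``, so the
    total count is Binomial(#G + #C, rate).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites: list[VariantSite] = []
    for name, mask in _eligible_gc_positions(genome, chroms, intergenic_only):
        draws = rng.random(mask.size) < rate
        hits = np.nonzero(mask & draws)[0]
        seq = genome.sequence(name)
        for i in hits:
            ref = seq[i]
            sites.append(
                VariantSite(name, int(i) + 1, ref, _EMS_ALT[ref], origin="EMS")
            )
    return sites


def sample_ems_sites(
    genome: ToyGenome,
    n: int,
    seed: int = 0,
    *,
    chroms: Sequence[str] | None = None,
    intergenic_only: bool = False,
    exclude: Iterable[tuple[str, int]] = (),
) -> list[VariantSite]:
    """Draw exactly ``n`` distinct canonical EMS sites from eligible positions.

    Companion to :func:`mutagenize_ems` for experiment designs that fix the
    passenger count instead of the per-base rate.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    excluded = set(exclude)
    pool: list[tuple[str, int]] = []
    for name, mask in _eligible_gc_positions(genome, chroms, intergenic_only):
        positions = np.nonzero(mask)[0] + 1
        if excluded:
            keep = [p for p in positions.tolist() if (name, p) not in excluded]
        else:
            keep = positions.tolist()
        pool.extend((name, p) for p in keep)
    if n > len(pool):
        raise ValueError(f"requested {n} EMS sites but only {len(pool)} eligible")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), n, replace=False)
    sites = []
    for k in sorted(int(p) for p in picks):
        name, pos = pool[k]
        ref = genome.base_at(name, pos)
        sites.append(VariantSite(name, pos, ref, _EMS_ALT[ref], origin="EMS"))
    return sites


def add_background_variants(
    genome: ToyGenome,
    n: int,
    seed: int = 0,
    *,
    exclude: Iterable[tuple[str, int]] = (),
) -> list[VariantSite]:
    """Fixed line-vs-reference differences, homozygous in all founders.

    Any ref>alt substitution is allowed. These sites appear in both bulks at
    AF 1 and are removable with a blacklist built from any sibling simulation
    sharing the same genome and seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    excluded = set(exclude)
    offsets = []
    total = 0
    for name, seq in genome.chromosomes:
        offsets.append((name, total, len(seq)))
        total += len(seq)
    available = total - sum(
        1 for c, p in excluded if c in genome.chrom_lengths
    )
    if n > available:
        raise ValueError(f"requested {n} background variants but only "
                         f"{available} positions available")
    rng = np.random.default_rng(seed)
    chosen: dict[tuple[str, int], VariantSite] = {}
    while len(chosen) < n:
        batch = rng.integers(0, total, size=max(2 * (n - len(chosen)), 16))
        for g in batch:
            if len(chosen) >= n:
                break
            g = int(g)
            for name, off, ln in offsets:
                if off <= g < off + ln:
                    pos = g - off + 1
                    key = (name, pos)
                    if key in excluded or key in chosen:
                        break
                    ref = genome.base_at(name, pos)
                    alts = [b for b in "ACGT" if b != ref]
                    alt = alts[int(rng.integers(0, 3))]
                    chosen[key] = VariantSite(name, pos, ref, alt,
                                              origin="background")
                    break
    return sorted(chosen.values())


def make_causal_missense(genome: ToyGenome, gene: GeneModel | None = None) -> VariantSite:
    """Pick a canonical-EMS missense SNP inside a gene's CDS as the causal site.

    Prefers the conserved proline codon at residue 5 (giving a P5L change via
    a reference-strand C>T or G>A, depending on gene strand); otherwise the
    first EMS-compatible missense position in the CDS is used.
    """
    if gene is None:
        if not genome.genes:
            raise ValueError("genome has no genes")
        gene = genome.genes[0]
    seq = genome.sequence(gene.chrom)
    positions = gene.cds_genomic_positions()
    cds = gene.transcript_cds(seq)
    minus = gene.strand == "-"

    preferred = [13] if len(cds) >= 18 else []  # 2nd base of codon 5
    order = preferred + [
        i for i in range(3, len(cds) - 3) if i not in preferred
    ]
    for i in order:
        pos = int(positions[i])
        gref = seq[pos - 1]
        if gref not in _EMS_ALT:
            continue
        galt = _EMS_ALT[gref]
        talt = complement_base(galt) if minus else galt
        ci, off = divmod(i, 3)
        ref_codon = cds[3 * ci : 3 * ci + 3]
        alt_codon = ref_codon[:off] + talt + ref_codon[off + 1 :]
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        if ref_aa != alt_aa and "*" not in (ref_aa, alt_aa) and ci > 0:
            return VariantSite(gene.chrom, pos, gref, galt,
                               origin="EMS", is_causal=True)
    raise ValueError(f"gene {gene.gene_id}: no EMS-compatible missense position")
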