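"""Toy genomes and gene models for forward-genetics simulation.

The generator writes complete, translatable protein-coding genes into a
random nucleotide background, so every downstream stage (EMS mutagenesis,
pedigree simulation, pooled sequencing, effect annotation) can be exercised
against a known ground truth without any external reference genome.

Coordinates are 1-based inclusive throughout the public surface, matching
FASTA/GFF3/VCF conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Stop codons of the standard genetic code.
STOP_CODONS = tuple(standard_dna_table.stop_codons)

_NONSTOP_CODONS = tuple(sorted(standard_dna_table.forward_table))

_BASE_BYTES = b"ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for a stop codon."""
    codon = codon.upper()
    if codon in standard_dna_table.forward_table:
        return standard_dna_table.forward_table[codon]
    if codon in standard_dna_table.stop_codons:
        return "*"
    raise ValueError(f"not a DNA codon: {codon!r}")


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript protein-coding gene model.

    Intervals are 1-based inclusive. ``exons`` are sorted, non-overlapping;
    every CDS interval lies within an exon. Each CDS interval carries its
    GFF3 phase (bases to skip to reach the next codon boundary).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...]
    description: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(self, "cds", tuple(tuple(c) for c in self.cds))
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) inverted")
            if s <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = e
        for cs, ce, phase in self.cds:
            if phase not in (0, 1, 2):
                raise ValueError(f"gene {self.gene_id}: bad CDS phase {phase}")
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(
                    f"gene {self.gene_id}: CDS ({cs},{ce}) not contained in an exon"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals between consecutive exons."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 - e0 > 1:
                out.append((e0 + 1, s1 - 1))
        return tuple(out)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in transcription order.

        For minus-strand genes the array runs from the highest to the lowest
        coordinate, so index ``i`` is base ``i`` of the spliced CDS.
        """
        pieces = []
        if self.strand == "+":
            for s, e, _ in self.cds:
                pieces.append(np.arange(s, e + 1))
        else:
            for s, e, _ in reversed(self.cds):
                pieces.append(np.arange(e, s - 1, -1))
        if not pieces:
            return np.empty(0, dtype=int)
        return np.concatenate(pieces)

    def transcript_cds(self, chrom_seq: str) -> str:
        """Spliced CDS on the coding strand (starts with the start codon)."""
        bases = [chrom_seq[p - 1] for p in self.cds_genomic_positions()]
        seq = "".join(bases)
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)
        return seq


@dataclass
class ToyGenome:
    """In-memory reference genome: named chromosome sequences plus gene models."""

    chromosomes: tuple[tuple[str, str], ...]
    genes: tuple[GeneModel, ...] = ()
    _by_name: dict = field(init=False, repr=False, compare=False, default_factory=dict)
    _genes_by_chrom: dict = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.chromosomes = tuple((str(n), str(s)) for n, s in self.chromosomes)
        self.genes = tuple(self.genes)
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"chromosome {name}: sequence not over A/C/G/T")
        self._by_name = dict(self.chromosomes)
        self._genes_by_chrom = {}
        for gene in self.genes:
            if gene.chrom not in self._by_name:
                raise ValueError(
                    f"gene {gene.gene_id} placed on unknown chromosome {gene.chrom}"
                )
            s, e = gene.span
            if s < 1 or e > len(self._by_name[gene.chrom]):
                raise ValueError(
                    f"gene {gene.gene_id} interval ({s},{e}) outside chromosome"
                )
            self._genes_by_chrom.setdefault(gene.chrom, []).append(gene)

    def sequence(self, chrom: str) -> str:
        try:
            return self._by_name[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom}") from None

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def genes_on(self, chrom: str) -> tuple[GeneModel, ...]:
        return tuple(self._genes_by_chrom.get(chrom, ()))

    def base_at(self, chrom: str, pos: int) -> str:
        seq = self.sequence(chrom)
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {chrom} (1..{len(seq)})")
        return seq[pos - 1]

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for name, seq in self.chromosomes:
            lines.append(f"##sequence-region {name} 1 {len(seq)}")
        for gene in self.genes:
            s, e = gene.span
            attrs = f"ID={gene.gene_id}"
            if gene.description:
                attrs += f";description={gene.description}"
            mrna_id = f"{gene.gene_id}.1"
            lines.append(
                "\t".join(
                    [gene.chrom, "bsamap", "gene", str(s), str(e), ".",
                     gene.strand, ".", attrs]
                )
            )
            lines.append(
                "\t".join(
                    [gene.chrom, "bsamap", "mRNA", str(s), str(e), ".",
                     gene.strand, ".", f"ID={mrna_id};Parent={gene.gene_id}"]
                )
            )
            for xs, xe in gene.exons:
                lines.append(
                    "\t".join(
                        [gene.chrom, "bsamap", "exon", str(xs), str(xe), ".",
                         gene.strand, ".", f"Parent={mrna_id}"]
                    )
                )
            for cs, ce, phase in gene.cds:
                lines.append(
                    "\t".join(
                        [gene.chrom, "bsamap", "CDS", str(cs), str(ce), ".",
                         gene.strand, str(phase),
                         f"ID=cds-{gene.gene_id};Parent={mrna_id}"]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")


def _random_gene_locus(
    rng: np.random.Generator,
    *,
    min_codons: int,
    max_codons: int,
    conserved_pro5: bool,
    intron_range: tuple[int, int],
    utr_range: tuple[int, int],
    min_exons: int = 2,
    max_exons: int = 4,
):
    """Build a gene locus on the coding strand.

    Returns (locus string including introns and UTRs, exon intervals,
    CDS intervals with phase) — intervals local, 0-based inclusive, in
    transcription order.
    """
    n_codons = int(rng.integers(min_codons, max_codons + 1))
    interior = [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)
    ]
    if conserved_pro5 and len(interior) >= 4:
        # conserved proline at residue 5, mirroring the invariant DIOX_N
        # proline of plant ACO proteins
        interior[3] = "CCA"
    stop = STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))]
    coding = "ATG" + "".join(interior) + stop

    n_exons = int(rng.integers(min_exons, max_exons + 1))
    n_exons = min(n_exons, len(coding) - 1)
    cuts = np.sort(rng.choice(np.arange(1, len(coding)), n_exons - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(coding)]
    cds_pieces = [coding[a:b] for a, b in zip(bounds, bounds[1:])]
    intron_lens = rng.integers(intron_range[0], intron_range[1] + 1, n_exons - 1)
    u5_len = int(rng.integers(utr_range[0], utr_range[1] + 1))
    u3_len = int(rng.integers(utr_range[0], utr_range[1] + 1))

    def rand_seq(n: int) -> str:
        idx = rng.integers(0, 4, n)
        return bytes(_BASE_BYTES[i] for i in idx).decode()

    locus_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int, int]] = []
    cursor = 0
    cum_cds = 0
    for j, piece in enumerate(cds_pieces):
        if j == 0:
            exon_start = cursor
            u5 = rand_seq(u5_len)
            locus_parts.append(u5)
            cursor += u5_len
        else:
            exon_start = cursor
        cds_start = cursor
        locus_parts.append(piece)
        cursor += len(piece)
        phase = (3 - cum_cds % 3) % 3
        cds.append((cds_start, cursor - 1, phase))
        cum_cds += len(piece)
        if j == len(cds_pieces) - 1:
            u3 = rand_seq(u3_len)
            locus_parts.append(u3)
            cursor += u3_len
            exons.append((exon_start, cursor - 1))
        else:
            exons.append((exon_start, cursor - 1))
            ilen = int(intron_lens[j])
            locus_parts.append(rand_seq(ilen))
            cursor += ilen
    return "".join(locus_parts), exons, cds


def make_toy_genome(
    n_chrom: int = 1,
    chrom_length: int = 100_000,
    n_genes: int = 2,
    seed: int = 0,
    *,
    min_codons: int = 40,
    max_codons: int = 80,
    conserved_pro5: bool = True,
    min_spacing: int = 200,
    max_spacing: int = 1000,
    intron_range: tuple[int, int] = (30, 120),
    utr_range: tuple[int, int] = (5, 30),
) -> ToyGenome:
    """Generate a reproducible random genome with packed gene models.

    Genes are distributed round-robin over chromosomes, alternate strands,
    have >=2 exons, complete ATG..stop CDS with length divisible by 3, and
    no internal stop codon. Raises ``ValueError`` when the requested genes
    cannot be packed.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be at least 10 kb")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    lut = np.frombuffer(_BASE_BYTES, dtype=np.uint8)
    seqs = [
        bytearray(lut[rng.integers(0, 4, chrom_length)].tobytes())
        for _ in range(n_chrom)
    ]

    cursors = [0] * n_chrom
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        ci = gi % n_chrom
        strand = "+" if gi % 2 == 0 else "-"
        locus, exons_local, cds_local = _random_gene_locus(
            rng,
            min_codons=min_codons,
            max_codons=max_codons,
            conserved_pro5=conserved_pro5,
            intron_range=intron_range,
            utr_range=utr_range,
        )
        gap = int(rng.integers(min_spacing, max_spacing + 1))
        start0 = cursors[ci] + gap
        lg = len(locus)
        end0 = start0 + lg - 1
        if end0 >= chrom_length - min_spacing:
            raise ValueError(
                f"cannot pack {n_genes} genes into {n_chrom} chromosome(s) of "
                f"{chrom_length} bp: gene {gi + 1} does not fit"
            )
        if strand == "+":
            seqs[ci][start0 : start0 + lg] = locus.encode()
            exons = [(start0 + a + 1, start0 + b + 1) for a, b in exons_local]
            cds = [(start0 + a + 1, start0 + b + 1, ph) for a, b, ph in cds_local]
        else:
            seqs[ci][start0 : start0 + lg] = reverse_complement(locus).encode()
            exons = sorted(
                (start0 + lg - b, start0 + lg - a) for a, b in exons_local
            )
            cds = sorted(
                (start0 + lg - b, start0 + lg - a, ph) for a, b, ph in cds_local
            )
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1}",
                chrom=names[ci],
                strand=strand,
                exons=tuple(exons),
                cds=tuple(cds),
                description=f"simulated protein-coding gene {gi + 1}",
            )
        )
        cursors[ci] = end0
    return ToyGenome(
        chromosomes=tuple((n, bytes(s).decode()) for n, s in zip(names, seqs)),
        genes=tuple(genes),
    )
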