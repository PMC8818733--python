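"""Diploid pedigree simulation: meiosis, crosses, phenotypes, bulks.

The meiosis model draws Poisson(crossover_rate) crossovers per chromosome
with uniform breakpoints and no interference; a gamete then copies each
variant allele from whichever parental haplotype the breakpoint pattern
selects. The founder of a mutant line is an M1 plant: heterozygous at every
EMS-induced site and homozygous for the line's background variants, which
reproduces the expected Mendelian arithmetic (1:2:1 on selfing, (1/2)^k
passenger retention through k backcrosses).

Phenotype is deterministic recessive: a plant is mutant iff it is 1/1 at the
causal site. Mutant plants draw per-flower stamen-development scores (0-3)
from a categorical distribution; wild-type plants score 0 on every flower.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import ToyGenome
from .variants import VariantSite

#: Per-flower score distribution for homozygous mutants over scores 0..3.
#: Calibrated so the expected plant-level andromonoecy index is 2.1.
DEFAULT_FLOWER_SCORE_DIST = (0.1, 0.1, 0.4, 0.4)

GENOTYPES = ("0/0", "0/1", "1/1")


class SiteIndex:
    """Ordered universe of segregating sites shared by a whole simulation.

    Haplotypes are boolean arrays over this index, which keeps meiosis and
    bulk allele counting vectorised.
    """

    def __init__(self, genome: ToyGenome, sites: Sequence[VariantSite]):
        ordered = sorted(sites)
        keys = [s.key for s in ordered]
        if len(set((s.chrom, s.pos) for s in ordered)) != len(ordered):
            raise ValueError("duplicate (chrom, pos) in site list")
        for s in ordered:
            if genome.base_at(s.chrom, s.pos) != s.ref:
                raise ValueError(
                    f"{s.chrom}:{s.pos}: ref {s.ref} does not match genome"
                )
        self.genome = genome
        self.sites: tuple[VariantSite, ...] = tuple(ordered)
        self.index: dict[tuple, int] = {k: i for i, k in enumerate(keys)}
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in genome.chrom_lengths:
            idxs = np.array(
                [i for i, s in enumerate(self.sites) if s.chrom == chrom],
                dtype=int,
            )
            pos = np.array([self.sites[i].pos for i in idxs], dtype=float)
            if idxs.size:
                self.by_chrom[chrom] = (pos, idxs)
        causal = [s for s in self.sites if s.is_causal]
        if len(causal) > 1:
            raise ValueError("at most one causal site per simulation")
        self.causal: VariantSite | None = causal[0] if causal else None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def origin_mask(self, origin: str) -> np.ndarray:
        return np.array([s.origin == origin for s in self.sites])


class Individual:
    """Diploid plant: two haplotypes of alternate alleles plus phenotype."""

    __slots__ = ("index", "hap0", "hap1", "phenotype", "flower_scores")

    def __init__(
        self,
        index: SiteIndex,
        hap0: np.ndarray,
        hap1: np.ndarray,
        phenotype: str | None = None,
        flower_scores: tuple[int, ...] = (),
    ):
        self.index = index
        self.hap0 = np.asarray(hap0, dtype=bool)
        self.hap1 = np.asarray(hap1, dtype=bool)
        if self.hap0.shape != (index.n_sites,) or self.hap1.shape != (index.n_sites,):
            raise ValueError("haplotype length does not match site index")
        if phenotype not in (None, "WT", "mutant"):
            raise ValueError(f"unknown phenotype: {phenotype!r}")
        scores = tuple(int(s) for s in flower_scores)
        if phenotype == "WT" and any(scores):
            raise ValueError("wild-type plants must score 0 on every flower")
        self.phenotype = phenotype
        self.flower_scores = scores

    def allele_count(self, site: VariantSite) -> int:
        i = self.index.index[site.key]
        return int(self.hap0[i]) + int(self.hap1[i])

    def genotype_at(self, site: VariantSite) -> str:
        return GENOTYPES[self.allele_count(site)]

    @property
    def plant_ai(self) -> float:
        if not self.flower_scores:
            raise ValueError("no flower scores assigned")
        return float(np.mean(self.flower_scores))


def founders(index: SiteIndex) -> tuple[Individual, Individual]:
    """(M1 mutant founder, background parent) for a simulated line.

    The founder is heterozygous at every EMS site and homozygous for the
    background variants; the background parent carries only the latter.
    """
    ems = index.origin_mask("EMS")
    bg = index.origin_mask("background")
    founder = Individual(index, ems | bg, bg.copy())
    background = Individual(index, bg.copy(), bg.copy())
    return founder, background


def _gamete(
    parent: Individual, rng: np.random.Generator, crossover_rate: float
) -> np.ndarray:
    index = parent.index
    g = np.zeros(index.n_sites, dtype=bool)
    for chrom, (pos, idxs) in index.by_chrom.items():
        length = index.genome.chrom_lengths[chrom]
        k = int(rng.poisson(crossover_rate))
        breaks = np.sort(rng.uniform(1.0, length + 1.0, k)) if k else np.empty(0)
        start = int(rng.integers(0, 2))
        seg = np.searchsorted(breaks, pos)
        use_hap0 = (start + seg) % 2 == 0
        g[idxs] = np.where(use_hap0, parent.hap0[idxs], parent.hap1[idxs])
    return g


def cross(
    parent_a: Individual,
    parent_b: Individual,
    n_offspring: int,
    crossover_rate: float = 1.0,
    seed: int = 0,
) -> list[Individual]:
    """Cross two plants; each offspring gets one recombinant gamete per parent."""
    if parent_a.index is not parent_b.index:
        raise ValueError("parents must share the same ToyGenome / site index")
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    rng = np.random.default_rng(seed)
    return [
        Individual(
            parent_a.index,
            _gamete(parent_a, rng, crossover_rate),
            _gamete(parent_b, rng, crossover_rate),
        )
        for _ in range(n_offspring)
    ]


def parse_scheme(scheme) -> tuple[str, ...]:
    """Normalise a cross scheme to a tuple of 'backcross'/'self' steps.

    Accepts strings like ``"BC2S1"``, ``"BC1S1"``, ``"S1"`` or ``"M2"``
    (a single self), or an explicit sequence of step names.
    """
    if isinstance(scheme, str):
        s = scheme.strip().upper()
        if s == "M2":
            return ("self",)
        m = re.fullmatch(r"(?:BC(\d+))?(?:S(\d+))?", s)
        if not m or (m.group(1) is None and m.group(2) is None):
            raise ValueError(f"cannot parse pedigree scheme {scheme!r}")
        steps = ["backcross"] * int(m.group(1) or 0) + ["self"] * int(m.group(2) or 0)
    else:
        steps = list(scheme)
        if any(st not in ("backcross", "self") for st in steps):
            raise ValueError(f"unknown pedigree step in {scheme!r}")
    if not steps:
        raise ValueError("empty pedigree scheme")
    return tuple(steps)


@dataclass
class PedigreeResult:
    final: list[Individual]
    carrier: Individual
    founder: Individual
    background: Individual


def run_pedigree(
    scheme="BC2S1",
    n_final: int = 300,
    seed: int = 0,
    *,
    index: SiteIndex,
    crossover_rate: float = 1.0,
    carrier_pool: int = 40,
) -> PedigreeResult:
    """Breed a segregating population through a backcross/self scheme.

    After every intermediate step a carrier heterozygous at the causal site
    is selected to continue the pedigree (mirroring marker- or
    phenotype-assisted selection); the last step produces ``n_final``
    offspring. ``result.carrier`` is the parent of the final generation.
    """
    steps = parse_scheme(scheme)
    if index.causal is None:
        raise ValueError("site index has no causal site")
    founder, background = founders(index)
    rng = np.random.default_rng(seed)
    carrier = founder
    for step in steps[:-1]:
        mate = background if step == "backcross" else carrier
        carrier = _select_het_carrier(carrier, mate, index.causal,
                                      carrier_pool, crossover_rate, rng)
    last = steps[-1]
    mate = background if last == "backcross" else carrier
    final = cross(carrier, mate, n_final, crossover_rate,
                  seed=int(rng.integers(0, 2**31 - 1)))
    return PedigreeResult(final=final, carrier=carrier, founder=founder,
                          background=background)


def _select_het_carrier(parent_a, parent_b, causal, pool, crossover_rate, rng):
    for _ in range(8):
        pool_seed = int(rng.integers(0, 2**31 - 1))
        offspring = cross(parent_a, parent_b, pool, crossover_rate, seed=pool_seed)
        for ind in offspring:
            if ind.genotype_at(causal) == "0/1":
                return ind
    raise RuntimeError("could not find a heterozygous carrier")  # pragma: no cover


def _draw_scores(rng, dist, n_flowers):
    return tuple(int(x) for x in rng.choice(4, size=n_flowers, p=dist))


def assign_phenotype(
    ind: Individual,
    causal: VariantSite,
    flower_score_dist: Sequence[float] = DEFAULT_FLOWER_SCORE_DIST,
    n_flowers: int = 10,
    seed: int = 0,
) -> Individual:
    """Deterministic recessive phenotype plus per-flower scores.

    0/0 and 0/1 plants are wild type with all-zero scores; 1/1 plants are
    mutant with scores drawn i.i.d. from ``flower_score_dist``.
    """
    dist = np.asarray(flower_score_dist, dtype=float)
    if dist.shape != (4,) or not np.isclose(dist.sum(), 1.0):
        raise ValueError("flower score distribution must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    return _assign(ind, causal, dist, n_flowers, rng)


def _assign(ind, causal, dist, n_flowers, rng):
    if ind.genotype_at(causal) == "1/1":
        return Individual(ind.index, ind.hap0, ind.hap1, "mutant",
                          _draw_scores(rng, dist, n_flowers))
    return Individual(ind.index, ind.hap0, ind.hap1, "WT", (0,) * n_flowers)


def assign_phenotypes(
    population: Sequence[Individual],
    causal: VariantSite,
    flower_score_dist: Sequence[float] = DEFAULT_FLOWER_SCORE_DIST,
    n_flowers: int = 10,
    seed: int = 0,
) -> list[Individual]:
    dist = np.asarray(flower_score_dist, dtype=float)
    if dist.shape != (4,) or not np.isclose(dist.sum(), 1.0):
        raise ValueError("flower score distribution must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    return [_assign(ind, causal, dist, n_flowers, rng) for ind in population]


@dataclass(frozen=True)
class Bulk:
    """Pool of same-phenotype plants whose DNA is sequenced together."""

    members: tuple[Individual, ...]
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("WT", "mutant"):
            raise ValueError("bulk label must be 'WT' or 'mutant'")
        object.__setattr__(self, "members", tuple(self.members))
        if any(m.phenotype != self.label for m in self.members):
            raise ValueError("all bulk members must share the bulk's phenotype")

    @property
    def size(self) -> int:
        return len(self.members)

    def true_allele_count(self, site: VariantSite) -> int:
        return sum(m.allele_count(site) for m in self.members)

    def true_af(self, site: VariantSite) -> float:
        return self.true_allele_count(site) / (2 * self.size)

    def true_af_array(self) -> np.ndarray:
        """True alternate AF at every indexed site, in site-index order."""
        if not self.members:
            raise ValueError("empty bulk")
        counts = np.zeros(self.members[0].index.n_sites, dtype=int)
        for m in self.members:
            counts += m.hap0.astype(int) + m.hap1.astype(int)
        return counts / (2 * self.size)


def build_bulk(
    population: Sequence[Individual],
    label: str,
    size: int,
    selection: str = "random",
    seed: int = 0,
    *,
    causal: VariantSite | None = None,
    composition: tuple[int, int] | None = None,
) -> Bulk:
    """Select a phenotype-defined bulk from a segregating population.

    ``selection="extreme-AI"`` ranks mutant plants by plant-level
    andromonoecy index, descending, with a seeded shuffle breaking ties
    deterministically. ``composition=(n_homref, n_het)`` pins the WT bulk's
    causal-site genotype mix (e.g. ``(15, 15)`` gives true AF 0.25).
    """
    if label not in ("WT", "mutant"):
        raise ValueError("bulk label must be 'WT' or 'mutant'")
    if selection not in ("random", "extreme-AI"):
        raise ValueError("selection must be 'random' or 'extreme-AI'")
    pool = [p for p in population if p.phenotype == label]
    if len(pool) < size:
        raise ValueError(
            f"requested a {label} bulk of {size} but only {len(pool)} "
            f"{label} plants are available"
        )
    rng = np.random.default_rng(seed)
    if composition is not None:
        if label != "WT":
            raise ValueError("composition applies to the WT bulk only")
        n00, n01 = composition
        if n00 + n01 != size:
            raise ValueError("composition must sum to the bulk size")
        if causal is None:
            causal = population[0].index.causal
        if causal is None:
            raise ValueError("composition requires a causal site")
        groups = {"0/0": [], "0/1": []}
        for p in pool:
            gt = p.genotype_at(causal)
            if gt in groups:
                groups[gt].append(p)
        for gt, need in (("0/0", n00), ("0/1", n01)):
            if len(groups[gt]) < need:
                raise ValueError(
                    f"requested {need} {gt} plants for the WT bulk but only "
                    f"{len(groups[gt])} are available"
                )
        chosen = [groups["0/0"][i] for i in rng.choice(len(groups["0/0"]), n00,
                                                       replace=False)]
        chosen += [groups["0/1"][i] for i in rng.choice(len(groups["0/1"]), n01,
                                                        replace=False)]
        return Bulk(tuple(chosen), label)
    if selection == "extreme-AI":
        order = rng.permutation(len(pool))
        shuffled = [pool[i] for i in order]
        ranked = sorted(shuffled, key=lambda p: -p.plant_ai)
        return Bulk(tuple(ranked[:size]), label)
    picks = rng.choice(len(pool), size, replace=False)
    return Bulk(tuple(pool[i] for i in picks), label)
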