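"""End-to-end simulated mapping-by-sequencing experiments.

``simulate_experiment`` wires the simulator stages together with the genetic
structure the analysis assumes: an EMS line carrying one causal recessive
CDS missense plus linked intergenic passenger mutations, shared background
variants, a backcross/self pedigree (BC2S1 by default), phenotype-selected
30-plant bulks, and pooled sequencing. ``run_bsa`` then runs the blacklist
subtraction, effect annotation and the filter cascade over the result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .bsafilter import FilterCascadeResult, FilterParams, apply_cascade, subtract_common
from .effectannot import annotate_all
from .simgenetics import (
    Bulk,
    DEFAULT_FLOWER_SCORE_DIST,
    Individual,
    SequencingResult,
    SiteIndex,
    SiteObservation,
    ToyGenome,
    VariantSite,
    add_background_variants,
    assign_phenotypes,
    build_bulk,
    make_causal_missense,
    make_toy_genome,
    run_pedigree,
    sample_ems_sites,
    sequence_bulks,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated bulked-segregant experiment.

    Defaults mirror the analysed cross: BC2S1 pedigree of ~300 plants,
    two 30-plant bulks (mutant bulk selected for extreme AI, WT bulk with a
    fixed 15 homozygous + 15 heterozygous mix, true causal AF 0.25), 200
    intergenic EMS passengers linked to the causal gene, 100 shared
    background variants, mean depth 45 and per-base error 1e-3.
    """

    n_chrom: int = 2
    chrom_length: int = 150_000
    n_genes: int = 6
    scheme: str = "BC2S1"
    n_population: int = 300
    bulk_size: int = 30
    wt_bulk_composition: tuple[int, int] | None = (15, 15)
    mutant_selection: str = "extreme-AI"
    n_linked_passengers: int = 200
    n_background: int = 100
    mean_depth: float = 45.0
    error_rate: float = 1e-3
    crossover_rate: float = 1.0
    n_flowers: int = 10
    flower_score_dist: tuple[float, ...] = DEFAULT_FLOWER_SCORE_DIST


@dataclass
class SimulationResult:
    genome: ToyGenome
    index: SiteIndex
    causal: VariantSite
    background_sites: list[VariantSite]
    population: list[Individual]
    wt_bulk: Bulk
    mut_bulk: Bulk
    sequencing: SequencingResult
    config: SimulationConfig

    @property
    def observations(self) -> list[SiteObservation]:
        return self.sequencing.observations


def simulate_experiment(
    config: SimulationConfig | None = None, seed: int = 0, **overrides
) -> SimulationResult:
    """Run one full simulated experiment with known ground truth."""
    config = replace(config or SimulationConfig(), **overrides)
    master = np.random.default_rng(seed)
    sub = [int(s) for s in master.integers(0, 2**31 - 1, size=8)]

    genome = make_toy_genome(
        config.n_chrom, config.chrom_length, config.n_genes, seed=sub[0]
    )
    causal = make_causal_missense(genome)
    passengers = sample_ems_sites(
        genome,
        config.n_linked_passengers,
        seed=sub[1],
        chroms=[causal.chrom],
        intergenic_only=True,
        exclude={(causal.chrom, causal.pos)},
    )
    taken = {(s.chrom, s.pos) for s in passengers} | {(causal.chrom, causal.pos)}
    background = add_background_variants(
        genome, config.n_background, seed=sub[2], exclude=taken
    )
    index = SiteIndex(genome, [causal, *passengers, *background])
    causal = index.causal  # canonical instance

    ped = run_pedigree(
        config.scheme,
        config.n_population,
        seed=sub[3],
        index=index,
        crossover_rate=config.crossover_rate,
    )
    population = assign_phenotypes(
        ped.final, causal, config.flower_score_dist, config.n_flowers, seed=sub[4]
    )
    mut_bulk = build_bulk(
        population, "mutant", config.bulk_size, config.mutant_selection, seed=sub[5]
    )
    wt_bulk = build_bulk(
        population, "WT", config.bulk_size, seed=sub[6],
        causal=causal, composition=config.wt_bulk_composition,
    )
    sequencing = sequence_bulks(
        wt_bulk, mut_bulk, index.sites,
        mean_depth=config.mean_depth, error_rate=config.error_rate, seed=sub[7],
    )
    return SimulationResult(
        genome=genome, index=index, causal=causal,
        background_sites=list(background), population=population,
        wt_bulk=wt_bulk, mut_bulk=mut_bulk, sequencing=sequencing,
        config=config,
    )


def recommended_filter_params(
    mean_depth: float, error_rate: float, **overrides
) -> FilterParams:
    """Cascade thresholds adapted to the sequencing error model.

    With a symmetric per-base error rate e, a truly fixed site is expected
    to show a fraction e of reference-looking reads, so the mutant-bulk
    "AF = 1" test is relaxed to AF >= 1 - tol with tol = 10e (an order of
    magnitude above the expectation, generous to Poisson fluctuation),
    capped at 0.02. Error-free data keeps the strict equality.
    """
    tol = min(0.02, 10.0 * error_rate)
    return FilterParams(af_mut_tol=tol, **overrides)


def run_bsa(
    observations: Sequence[SiteObservation],
    genome: ToyGenome,
    params: FilterParams | None = None,
    blacklist: Sequence = (),
) -> FilterCascadeResult:
    """Blacklist subtraction, effect annotation and the filter cascade."""
    records = subtract_common(observations, blacklist)
    effects = annotate_all([r.site for r in records], genome)
    return apply_cascade(records, effects, params)
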