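"""Pooled short-read sequencing model for two phenotype bulks.

Per site and bulk: depth DP ~ Poisson(mean_depth); alternate reads
~ Binomial(DP, p) with p the true bulk allele frequency adjusted for a
symmetric per-base error rate, p' = p(1-e) + (1-p)e. The genotype call is
the maximum-likelihood diploid-pool genotype among 0/0, 0/1 and 1/1
(expected alternate fractions e, 1/2 and 1-e) and GQ is the phred-scaled
gap between the best and second-best likelihood, capped at 99.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Bulk
from .variants import VariantSite

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class BulkCall:
    """Observed read support and genotype call for one bulk at one site."""

    dp: int
    ref_reads: int
    alt_reads: int
    gt: str
    gq: int

    def __post_init__(self) -> None:
        if self.dp < 0 or self.gq < 0:
            raise ValueError("DP and GQ must be non-negative")
        if self.ref_reads + self.alt_reads != self.dp:
            raise ValueError("ref + alt reads must equal DP")

    @property
    def af(self) -> float | None:
        """Alternate allele frequency; None when the site has no coverage."""
        if self.dp == 0:
            return None
        return self.alt_reads / self.dp


@dataclass(frozen=True)
class SiteObservation:
    """One variant site with its per-bulk sequencing observations."""

    site: VariantSite
    wt: BulkCall
    mut: BulkCall


@dataclass
class SequencingResult:
    """Observations plus the simulation truth table and contig sizes."""

    observations: list[SiteObservation]
    truth: pd.DataFrame
    contig_lengths: dict[str, int]

    def write_vcf(self, path: str | Path) -> None:
        from ..io import write_bulk_vcf

        write_bulk_vcf(self.observations, path, contig_lengths=self.contig_lengths)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _call_genotype(dp: int, alt: int, error_rate: float) -> tuple[str, int]:
    if dp == 0:
        return "./.", 0
    e = min(max(error_rate, 1e-10), 0.499)
    probs = np.array([e, 0.5, 1.0 - e])
    loglik = alt * np.log(probs) + (dp - alt) * np.log1p(-probs)
    order = np.argsort(loglik)[::-1]
    best, second = order[0], order[1]
    gq = int(min(99, round(10.0 * (loglik[best] - loglik[second]) / _LN10)))
    return ("0/0", "0/1", "1/1")[best], max(gq, 0)


def sequence_bulks(
    wt: Bulk,
    mut: Bulk,
    sites: Sequence[VariantSite],
    mean_depth: float = 45.0,
    error_rate: float = 1e-3,
    seed: int = 0,
) -> SequencingResult:
    """Simulate pooled sequencing of the two bulks over the given sites.

    Observations come back in (chrom, pos) order — the order of the emitted
    VCF. The truth table records each site's origin, causal flag and true
    per-bulk allele frequencies.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if wt.label != "WT" or mut.label != "mutant":
        raise ValueError("expected a WT bulk and a mutant bulk, in that order")
    ordered = sorted(sites)
    index = wt.members[0].index
    contigs = dict(index.genome.chrom_lengths)
    if not ordered:
        return SequencingResult([], _truth_frame([], [], []), contigs)

    af_all = {"wt": wt.true_af_array(), "mut": mut.true_af_array()}
    idxs = np.array([index.index[s.key] for s in ordered])
    rng = np.random.default_rng(seed)
    observations = []
    true_wt, true_mut = [], []
    p0 = np.vstack([af_all["wt"][idxs], af_all["mut"][idxs]])
    p = p0 * (1.0 - error_rate) + (1.0 - p0) * error_rate
    dp = rng.poisson(mean_depth, size=p.shape)
    alt = rng.binomial(dp, p)
    for j, site in enumerate(ordered):
        calls = []
        for b in (0, 1):
            gt, gq = _call_genotype(int(dp[b, j]), int(alt[b, j]), error_rate)
            calls.append(
                BulkCall(
                    dp=int(dp[b, j]),
                    ref_reads=int(dp[b, j] - alt[b, j]),
                    alt_reads=int(alt[b, j]),
                    gt=gt,
                    gq=gq,
                )
            )
        observations.append(SiteObservation(site, wt=calls[0], mut=calls[1]))
        true_wt.append(float(p0[0, j]))
        true_mut.append(float(p0[1, j]))
    truth = _truth_frame(ordered, true_wt, true_mut)
    return SequencingResult(observations, truth, contigs)


def _truth_frame(sites, true_wt, true_mut) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "origin": [s.origin for s in sites],
            "is_causal": [s.is_causal for s in sites],
            "true_af_wt": true_wt,
            "true_af_mut": true_mut,
        }
    )
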