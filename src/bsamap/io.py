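"""Plain-text readers and writers for the pipeline's file formats.

The two-sample VCF (v4.2, FORMAT ``GT:AD:DP:GQ``, samples ``WT_BULK`` and
``MUT_BULK``) is the hand-off between the simulator and the filter cascade.
Writers are deterministic: no timestamps, fixed field order, so re-running
with the same seed produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simgenetics import BulkCall, SiteObservation, VariantSite

WT_SAMPLE = "WT_BULK"
MUT_SAMPLE = "MUT_BULK"


class VcfParseError(ValueError):
    """Raised when a bulk VCF cannot be interpreted."""


def write_bulk_vcf(
    observations: Sequence[SiteObservation],
    path: str | Path,
    *,
    contig_lengths: Mapping[str, int] | None = None,
    wt_sample: str = WT_SAMPLE,
    mut_sample: str = MUT_SAMPLE,
) -> None:
    """Write observations as a two-sample VCF v4.2 (WT bulk first)."""
    if contig_lengths is None:
        contig_lengths = {}
        for obs in observations:
            c = obs.site.chrom
            contig_lengths[c] = max(contig_lengths.get(c, 0), obs.site.pos)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bsamap",
    ]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{wt_sample}\t{mut_sample}",
    ]
    for obs in sorted(observations, key=lambda o: (o.site.chrom, o.site.pos)):
        site = obs.site
        cells = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".",
                 "PASS", ".", "GT:AD:DP:GQ"]
        for call in (obs.wt, obs.mut):
            cells.append(
                f"{call.gt}:{call.ref_reads},{call.alt_reads}:{call.dp}:{call.gq}"
            )
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _sample_call(variant, i: int) -> BulkCall:
    ad = variant.format("AD")
    if ad is None:
        raise VcfParseError(
            f"{variant.CHROM}:{variant.POS}: missing AD field"
        )
    ref_reads, alt_reads = (int(x) for x in np.atleast_2d(ad)[i][:2])
    if ref_reads < 0 or alt_reads < 0:
        raise VcfParseError(
            f"{variant.CHROM}:{variant.POS}: malformed AD for sample {i}"
        )
    dp_field = variant.format("DP")
    dp = int(np.ravel(dp_field)[i]) if dp_field is not None else ref_reads + alt_reads
    gq_field = variant.format("GQ")
    gq = int(round(float(np.ravel(gq_field)[i]))) if gq_field is not None else 0
    a, b = variant.genotypes[i][:2]
    gt = "./." if a < 0 or b < 0 else f"{min(a, b)}/{max(a, b)}"
    return BulkCall(dp=dp, ref_reads=ref_reads, alt_reads=alt_reads,
                    gt=gt, gq=max(gq, 0))


def read_bulk_vcf(
    path: str | Path,
    *,
    wt_sample: str = WT_SAMPLE,
    mut_sample: str = MUT_SAMPLE,
) -> list[SiteObservation]:
    """Read a two-bulk VCF into site observations (origin unknown).

    Per-bulk AF is later computed as alt-AD / (ref-AD + alt-AD); a record
    with zero depth in a bulk is retained but has undefined AF there.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for wanted in (wt_sample, mut_sample):
        if wanted not in samples:
            raise VcfParseError(
                f"{path}: sample {wanted!r} not found (has {samples})"
            )
    wt_i, mut_i = samples.index(wt_sample), samples.index(mut_sample)
    out: list[SiteObservation] = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise VcfParseError(
                f"{v.CHROM}:{v.POS}: only biallelic SNVs are supported"
            )
        site = VariantSite(v.CHROM, v.POS, v.REF, v.ALT[0])
        out.append(
            SiteObservation(site, wt=_sample_call(v, wt_i),
                            mut=_sample_call(v, mut_i))
        )
    return out


def read_variant_keys(path: str | Path) -> list[tuple[str, int, str, str]]:
    """(chrom, pos, ref, alt) keys from any VCF — e.g. a blacklist file."""
    out = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            out.append((v.CHROM, v.POS, v.REF, alt))
    return out


def read_truth_table(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "origin", "is_causal"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return truth


def attach_truth(
    observations: Iterable[SiteObservation], truth: pd.DataFrame
) -> list[SiteObservation]:
    """Re-attach simulation origin/causality to observations read from VCF."""
    lookup = {
        (r.chrom, int(r.pos), r.ref, r.alt): (r.origin, bool(r.is_causal))
        for r in truth.itertuples()
    }
    out = []
    for obs in observations:
        origin, causal = lookup.get(obs.site.key, (obs.site.origin,
                                                   obs.site.is_causal))
        site = VariantSite(obs.site.chrom, obs.site.pos, obs.site.ref,
                           obs.site.alt, origin=origin, is_causal=causal)
        out.append(SiteObservation(site, wt=obs.wt, mut=obs.mut))
    return out
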