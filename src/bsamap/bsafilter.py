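"""Allele-frequency filter cascade and chromosome-wide AF scan.

The cascade distils a two-bulk SNP list down to causal-mutation candidates
in four stages, applied as a pure conjunction in a fixed reporting order:

1. allele frequency — AF = 1 in the mutant bulk (optionally within a small
   tolerance for sequencing error) and AF at most ~0.3 in the WT bulk;
2. EMS canonicality — the ref>alt pair, as written on the reference strand,
   is G>A or C>T;
3. call quality — GQ and DP thresholds, enforced in both bulks;
4. impact — the variant's effect class is in the candidate set
   (protein-altering by default: HIGH + MODERATE).

Because the stages are conjunctive, the surviving set is order-independent;
only the per-stage counts depend on the reporting order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effectannot import EffectCall, IMPACTS
from .io import read_bulk_vcf, read_variant_keys, VcfParseError  # noqa: F401
from .simgenetics import SiteObservation, VariantSite

_EMS_PAIRS = (("G", "A"), ("C", "T"))


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the candidate-SNP filter cascade.

    ``af_mut_tol`` relaxes the mutant-bulk "AF = 1" test to
    ``AF >= 1 - af_mut_tol``; the default 0 keeps strict equality
    (zero reference-supporting reads). ``*_inclusive`` toggles choose
    between >=/<= (default) and strict >/< comparators.
    """

    af_wt_max: float = 0.3
    af_wt_inclusive: bool = True
    af_mut: float = 1.0
    af_mut_tol: float = 0.0
    gq_min: float = 90.0
    gq_inclusive: bool = True
    dp_min: float = 10.0
    dp_inclusive: bool = True
    ems_only: bool = True
    candidate_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_wt_max <= 1.0:
            raise ValueError("af_wt_max must be in [0, 1]")
        if not 0.0 <= self.af_mut_tol <= 1.0:
            raise ValueError("af_mut_tol must be in [0, 1]")
        if self.gq_min < 0 or self.dp_min < 0:
            raise ValueError("thresholds must be non-negative")
        bad = set(self.candidate_impacts) - set(IMPACTS)
        if bad:
            raise ValueError(f"unknown impact classes: {sorted(bad)}")
        object.__setattr__(self, "candidate_impacts",
                           frozenset(self.candidate_impacts))


def passes_af(obs: SiteObservation, params: FilterParams) -> bool:
    af_wt, af_mut = obs.wt.af, obs.mut.af
    if af_wt is None or af_mut is None:
        return False
    if af_mut < params.af_mut - params.af_mut_tol:
        return False
    if params.af_wt_inclusive:
        return af_wt <= params.af_wt_max
    return af_wt < params.af_wt_max


def passes_ems(obs: SiteObservation) -> bool:
    return (obs.site.ref, obs.site.alt) in _EMS_PAIRS


def passes_quality(obs: SiteObservation, params: FilterParams) -> bool:
    for call in (obs.wt, obs.mut):
        if params.gq_inclusive:
            if call.gq < params.gq_min:
                return False
        elif call.gq <= params.gq_min:
            return False
        if params.dp_inclusive:
            if call.dp < params.dp_min:
                return False
        elif call.dp <= params.dp_min:
            return False
    return True


def passes_impact(effect: EffectCall, params: FilterParams) -> bool:
    return effect.impact in params.candidate_impacts


@dataclass
class FilterCascadeResult:
    """Ordered per-stage survivors and the final candidate list."""

    stages: tuple[tuple[str, tuple[SiteObservation, ...]], ...]
    candidates: tuple[tuple[SiteObservation, EffectCall], ...]

    @property
    def counts(self) -> list[tuple[str, int]]:
        return [(name, len(records)) for name, records in self.stages]

    def stage(self, name: str) -> tuple[SiteObservation, ...]:
        for stage_name, records in self.stages:
            if stage_name == name:
                return records
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=["stage", "count"])


def subtract_common(
    records: Sequence[SiteObservation],
    blacklist: Iterable,
) -> list[SiteObservation]:
    """Drop records whose (chrom, pos, ref, alt) key is blacklisted.

    The blacklist holds variants shared across independently derived mutant
    families — fixed line-vs-reference differences rather than induced
    mutations. Accepts VariantSite objects or raw key tuples; order is
    preserved.
    """
    keys = set()
    for item in blacklist:
        keys.add(item.key if isinstance(item, VariantSite) else tuple(item))
    return [r for r in records if r.site.key not in keys]


def apply_cascade(
    records: Sequence[SiteObservation],
    effects: Mapping[tuple, EffectCall],
    params: FilterParams | None = None,
) -> FilterCascadeResult:
    """Run the four-stage candidate filter and record per-stage counts.

    ``effects`` must cover every record (intergenic calls included).
    """
    params = params or FilterParams()
    for r in records:
        if r.site.key not in effects:
            raise KeyError(
                f"no effect call for {r.site.chrom}:{r.site.pos} "
                f"{r.site.ref}>{r.site.alt}"
            )
    stages: list[tuple[str, tuple[SiteObservation, ...]]] = [
        ("total", tuple(records))
    ]
    surviving = list(records)
    surviving = [r for r in surviving if passes_af(r, params)]
    stages.append(("allele_frequency", tuple(surviving)))
    if params.ems_only:
        surviving = [r for r in surviving if passes_ems(r)]
        stages.append(("ems_canonical", tuple(surviving)))
    surviving = [r for r in surviving if passes_quality(r, params)]
    stages.append(("quality", tuple(surviving)))
    surviving = [r for r in surviving if passes_impact(effects[r.site.key], params)]
    stages.append(("impact", tuple(surviving)))
    candidates = tuple((r, effects[r.site.key]) for r in surviving)
    return FilterCascadeResult(stages=tuple(stages), candidates=candidates)


@dataclass
class AFProfile:
    """Windowed alternate-AF means per bulk, with called peak regions.

    ``table`` columns: chrom, start, end (1-based inclusive), n_sites,
    af_wt, af_mut. ``peaks`` are merged runs of windows where the mutant
    bulk's mean AF stays high while the WT bulk's stays moderate.
    """

    table: pd.DataFrame
    peaks: tuple[tuple[str, int, int], ...]

    @property
    def peak(self) -> tuple[str, int, int] | None:
        """Widest peak region, or None."""
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p[2] - p[1])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def peaks_to_bed(self, path: str | Path) -> None:
        lines = [f"{c}\t{s - 1}\t{e}\tpeak{i + 1}"
                 for i, (c, s, e) in enumerate(self.peaks)]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def scan_af_profile(
    records: Sequence[SiteObservation],
    window: int | None = None,
    step: int | None = None,
    *,
    chrom_lengths: Mapping[str, int] | None = None,
    peak_mut_min: float = 0.9,
    wt_max: float = 0.3,
    wt_margin: float = 0.1,
) -> AFProfile:
    """Windowed mean alternate AF along each chromosome, plus peak calling.

    Defaults: window = chromosome length / 50, step = window (tiling).
    A window joins a peak when its mutant-bulk mean AF is at least
    ``peak_mut_min`` and its WT-bulk mean is at most ``wt_max + wt_margin``.
    Chromosomes with no sites emit no windows.
    """
    if window is not None and step is not None and not window >= step > 0:
        raise ValueError("need window >= step > 0")
    by_chrom: dict[str, list[SiteObservation]] = {}
    for r in records:
        by_chrom.setdefault(r.site.chrom, []).append(r)
    lengths = dict(chrom_lengths or {})
    for chrom, recs in by_chrom.items():
        lengths.setdefault(chrom, max(r.site.pos for r in recs))

    rows = []
    peaks: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        length = lengths[chrom]
        win = window if window is not None else max(1, int(np.ceil(length / 50)))
        stp = step if step is not None else win
        pos = np.array([r.site.pos for r in recs])
        af_wt = np.array([np.nan if r.wt.af is None else r.wt.af for r in recs])
        af_mut = np.array([np.nan if r.mut.af is None else r.mut.af for r in recs])
        starts = np.arange(1, length + 1, stp)
        run: list[int] = []
        chrom_rows = []
        for wi, s in enumerate(starts):
            e = min(int(s) + win - 1, length)
            in_win = (pos >= s) & (pos <= e)
            n = int(in_win.sum())
            with np.errstate(invalid="ignore"):
                mean_wt = float(np.nanmean(af_wt[in_win])) if n else np.nan
                mean_mut = float(np.nanmean(af_mut[in_win])) if n else np.nan
            chrom_rows.append((chrom, int(s), e, n, mean_wt, mean_mut))
            is_peak = (
                n > 0
                and not np.isnan(mean_mut)
                and mean_mut >= peak_mut_min
                and not np.isnan(mean_wt)
                and mean_wt <= wt_max + wt_margin
            )
            if is_peak:
                run.append(wi)
            if run and (not is_peak or wi == len(starts) - 1):
                first, last = run[0], run[-1]
                peaks.append(
                    (chrom, int(starts[first]),
                     min(int(starts[last]) + win - 1, length))
                )
                run = []
        rows.extend(chrom_rows)
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "af_wt", "af_mut"]
    )
    return AFProfile(table=table, peaks=tuple(peaks))


def report_cascade(
    result: FilterCascadeResult,
    fmt: str = "tsv",
    *,
    gene_descriptions: Mapping[str, str] | None = None,
) -> str:
    """Render the stage table plus candidate lines as TSV or JSON."""
    gene_descriptions = gene_descriptions or {}
    cand_rows = []
    for obs, eff in result.candidates:
        s = obs.site
        cand_rows.append(
            {
                "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                "gene": eff.gene_id or ".",
                "effect": eff.aa_change or eff.region,
                "impact": eff.impact,
                "annotation": gene_descriptions.get(eff.gene_id, "."),
            }
        )
    if fmt == "json":
        return json.dumps(
            {
                "stages": [{"stage": n, "count": c} for n, c in result.counts],
                "candidates": cand_rows,
            },
            indent=2,
        )
    if fmt != "tsv":
        raise ValueError("format must be 'tsv' or 'json'")
    lines = ["stage\tcount"]
    lines += [f"{n}\t{c}" for n, c in result.counts]
    lines.append("")
    lines.append("chrom\tpos\tref\talt\tgene\teffect\timpact\tannotation")
    for row in cand_rows:
        lines.append("\t".join(str(row[k]) for k in
                               ("chrom", "pos", "ref", "alt", "gene",
                                "effect", "impact", "annotation")))
    return "\n".join(lines) + "\n"
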