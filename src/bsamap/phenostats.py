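"""Phenotype and expression statistics for segregating populations.

Covers the andromonoecy index (AI: per-flower stamen-development score 0-3,
averaged per plant and per genotype), sex-phenotype classification,
chi-square segregation goodness-of-fit, genotype-phenotype co-segregation,
and Livak 2^-ddCt relative expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Protocol minimum flowers scored per plant; fewer triggers a warning.
MIN_FLOWERS = 10

SEX_CLASSES = ("monoecious", "partially_andromonoecious", "andromonoecious")


def andromonoecy_index(scores: Sequence[int]) -> float:
    """Plant-level AI: arithmetic mean of per-flower scores in {0,1,2,3}."""
    if len(scores) == 0:
        raise ValueError("no flower scores given")
    arr = np.asarray(scores)
    if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0 or arr.max() > 3:
        raise ValueError("flower scores must be integers in {0, 1, 2, 3}")
    return float(arr.mean())


def genotype_ai(plant_ais: Sequence[float]) -> float:
    """Genotype-level AI: mean of plant-level AIs (not the pooled flower mean)."""
    if len(plant_ais) == 0:
        raise ValueError("no plant AI values given")
    return float(np.mean(plant_ais))


def classify_sex_phenotype(plant_ai: float, *, andro_min: float = 2.5) -> str:
    """Bin a plant AI into a sex-expression class.

    AI = 0 is monoecious (all-female pistillate flowers); AI >= ``andro_min``
    is andromonoecious; anything between is partially andromonoecious. The
    2.5 cut is a classification convenience, not a biological constant.
    """
    if not 0.0 <= plant_ai <= 3.0:
        raise ValueError("plant AI must be in [0, 3]")
    if plant_ai == 0:
        return "monoecious"
    if plant_ai >= andro_min:
        return "andromonoecious"
    return "partially_andromonoecious"


@dataclass(frozen=True)
class AIRecord:
    """One phenotyped (and possibly genotyped) plant."""

    plant_id: str
    flower_scores: tuple[int, ...]
    genotype: str | None = None  # "0/0", "0/1", "1/1" or None
    phenotype: str | None = None  # "WT"/"mutant"; inferred from AI when None

    def __post_init__(self) -> None:
        if self.genotype not in (None, "0/0", "0/1", "1/1"):
            raise ValueError(f"plant {self.plant_id}: bad genotype {self.genotype!r}")
        if self.phenotype not in (None, "WT", "mutant"):
            raise ValueError(f"plant {self.plant_id}: bad phenotype {self.phenotype!r}")
        object.__setattr__(self, "flower_scores",
                           tuple(int(s) for s in self.flower_scores))
        if len(self.flower_scores) < MIN_FLOWERS:
            warnings.warn(
                f"plant {self.plant_id}: only {len(self.flower_scores)} flowers "
                f"scored; protocol expects at least {MIN_FLOWERS}",
                stacklevel=2,
            )

    @property
    def plant_ai(self) -> float:
        return andromonoecy_index(self.flower_scores)

    @property
    def observed_phenotype(self) -> str:
        if self.phenotype is not None:
            return self.phenotype
        return "mutant" if self.plant_ai > 0 else "WT"


def segregation_test(
    n_wt: int, n_mut: int, expected_ratio: tuple[float, float] = (3.0, 1.0)
) -> tuple[float, float]:
    """One-df chi-square goodness of fit of WT:mutant counts to a ratio."""
    total = n_wt + n_mut
    if total <= 0:
        raise ValueError("need at least one plant")
    a, b = expected_ratio
    expected = np.array([a, b]) / (a + b) * total
    chi2, p = stats.chisquare([n_wt, n_mut], f_exp=expected)
    return float(chi2), float(p)


@dataclass
class CosegregationResult:
    percent: float
    n: int
    discordant: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def cosegregation(records: Iterable[AIRecord]) -> CosegregationResult:
    """Percent concordance of phenotype with the recessive genotype prediction.

    A plant is predicted mutant iff its genotype at the candidate site is
    1/1. Records lacking a genotype are excluded with a warning; discordant
    plants are listed by id.
    """
    records = list(records)
    scored: list[AIRecord] = []
    excluded: list[str] = []
    for rec in records:
        if rec.genotype is None:
            excluded.append(rec.plant_id)
        else:
            scored.append(rec)
    if excluded:
        warnings.warn(
            f"{len(excluded)} plant(s) without genotype excluded from "
            f"co-segregation: {excluded[:5]}...",
            stacklevel=2,
        )
    if not scored:
        raise ValueError("no genotyped plants to score")
    discordant = [
        rec.plant_id
        for rec in scored
        if rec.observed_phenotype != ("mutant" if rec.genotype == "1/1" else "WT")
    ]
    n = len(scored)
    return CosegregationResult(
        percent=100.0 * (n - len(discordant)) / n,
        n=n,
        discordant=discordant,
        excluded=excluded,
    )


@dataclass(frozen=True)
class ExpressionSample:
    """One qPCR sample: target and reference-gene cycle thresholds."""

    sample_id: str
    ct_target: float
    ct_reference: float
    group: str  # "calibrator" or "test"

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target),
                        ("ct_reference", self.ct_reference)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"sample {self.sample_id}: {name} must be positive and finite"
                )
        if self.group not in ("calibrator", "test"):
            raise ValueError(f"sample {self.sample_id}: bad group {self.group!r}")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression_ddct(samples: Sequence[ExpressionSample]) -> pd.DataFrame:
    """Livak relative expression: fold = 2^-(dCt - mean calibrator dCt).

    Multiple calibrators are averaged on the dCt scale. Returns a frame with
    columns sample_id, group, dct, ddct, fold for every sample.
    """
    cal = [s.dct for s in samples if s.group == "calibrator"]
    if not cal:
        raise ValueError("at least one calibrator sample is required")
    cal_mean = float(np.mean(cal))
    rows = []
    for s in samples:
        ddct = s.dct - cal_mean
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "dct": s.dct,
                "ddct": ddct,
                "fold": float(2.0 ** (-ddct)),
            }
        )
    return pd.DataFrame(rows)
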