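"""Divergence-based insertion dating under the Jukes-Cantor model.

A copy's percent divergence D from its subfamily consensus is corrected
for multiple hits with the one-parameter Jukes-Cantor formula

    K = -(300/4) * ln(1 - D * 4/300)      (K, D both in percent)

and dated as t = K / (2 r) with K converted to a per-site fraction and a
substitution rate r (default 2.2e-9 substitutions/site/year, the mammalian
rate assumed for the pig lineage).  Amplification waves are summarized as
the percent of the genome in each age bin per family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from mobiloscope.formats_io import TEAnnotation

#: Divergence (%) above which the JC correction is undefined.
JC_SATURATION_PCT = 75.0


class SaturationError(ValueError):
    """Divergence at or beyond the JC saturation limit (D >= 75%)."""


@dataclass(frozen=True)
class AgeModelConfig:
    """Dating parameters.

    r: substitution rate in substitutions/site/year.
    bin_width_mya / max_age_mya: histogram binning (half-open [lo, hi) bins);
    ages >= max_age_mya and saturated copies accumulate in an overflow bin.
    """

    r: float = 2.2e-9
    bin_width_mya: float = 1.0
    max_age_mya: float = 100.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("substitution rate r must be positive")
        if self.bin_width_mya <= 0:
            raise ValueError("bin_width_mya must be positive")


@dataclass(frozen=True)
class AgeEstimate:
    """(D, K, t) for one copy: divergence %, corrected substitutions %, age in years."""

    D: float
    K: float
    t: float


def jc_correct(D: float) -> float:
    """Jukes-Cantor multiple-hit correction, percent in, percent out.

    K = -75 * ln(1 - 4D/300); K >= D with equality iff D = 0.
    """
    if D < 0:
        raise ValueError("divergence must be non-negative")
    if D >= JC_SATURATION_PCT:
        raise SaturationError(f"divergence {D}% at or beyond JC saturation (75%)")
    return -75.0 * math.log(1.0 - D * 4.0 / 300.0)


def estimate_age(K: float, cfg: AgeModelConfig = AgeModelConfig()) -> float:
    """Insertion age in years from corrected divergence K (percent).

    t = (K/100) / (2 r): K is converted to a per-site fraction first so the
    rate's units (substitutions/site/year) match.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    return (K / 100.0) / (2.0 * cfg.r)


def date_annotation(a: TEAnnotation, cfg: AgeModelConfig = AgeModelConfig()) -> AgeEstimate:
    K = jc_correct(a.divergence_pct)
    return AgeEstimate(D=a.divergence_pct, K=K, t=estimate_age(K, cfg))


def age_histogram(
    annotations: Sequence[TEAnnotation],
    genome_size: int,
    group_by: str = "family",
    cfg: AgeModelConfig = AgeModelConfig(),
) -> pd.DataFrame:
    """Percent of the genome per (group, age bin).

    Each annotation contributes its genomic length to the bin containing its
    estimated age; bins are half-open [lo, hi) of width ``bin_width_mya``.
    Saturated copies (D >= 75%) and ages >= ``max_age_mya`` land in an
    overflow bin (bin_lo_mya = max_age_mya, bin_hi_mya = inf) rather than
    being dropped.  Cell value = summed bp / genome_size * 100.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if group_by not in ("class", "family", "subfamily"):
        raise ValueError("group_by must be one of class/family/subfamily")
    key = {"class": "te_class", "family": "family", "subfamily": "subfamily"}[group_by]
    cells: dict[tuple[str, float, float], int] = {}
    for a in annotations:
        group = getattr(a, key)
        try:
            t_mya = estimate_age(jc_correct(a.divergence_pct), cfg) / 1e6
            overflow = t_mya >= cfg.max_age_mya
        except SaturationError:
            overflow = True
        if overflow:
            lo, hi = cfg.max_age_mya, math.inf
        else:
            idx = math.floor(t_mya / cfg.bin_width_mya)
            lo = idx * cfg.bin_width_mya
            hi = lo + cfg.bin_width_mya
        cells[(group, lo, hi)] = cells.get((group, lo, hi), 0) + len(a.interval)
    rows = [
        {"group": g, "bin_lo_mya": lo, "bin_hi_mya": hi,
         "pct_genome": bp / genome_size * 100.0}
        for (g, lo, hi), bp in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["group", "bin_lo_mya", "bin_hi_mya", "pct_genome"])
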