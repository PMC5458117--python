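"""Evaluation statistics: error rates per support level, error spectrum,
sensitivity/FPR against a gold standard, mixture allele-frequency arithmetic,
depth bias and data utilization.

Error rates are fractions of usable consensus base observations; positions on
the gold-standard or exclusion lists are removed from both numerator and
denominator so known strain differences and noisy loci never count as error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calling import PileupColumn, VariantCall
from .simulate import TruthVariant

_TRANSITIONS_CLASSES = [
    f"{x}>{y}" for x in "ACGT" for y in "ACGT" if x != y
]  # the 12 substitution classes


@dataclass
class GoldStandard:
    """Truth sites plus positions excluded from every statistic."""

    sites: list[TruthVariant]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site_positions() & self.excluded_positions():
            raise ValueError("gold sites and exclusions must be disjoint")

    def site_positions(self) -> set[int]:
        return {v.position for v in self.sites}

    def excluded_positions(self) -> set[int]:
        return {p for p, _ in self.excluded}

    def site_keys(self) -> set[tuple[int, str]]:
        return {(v.position, v.alt_base) for v in self.sites}


def theoretical_mixture_af(
    af_strain_a: float,
    af_strain_b: float,
    ratio_a_to_b: tuple[float, float],
) -> float:
    """Ratio-weighted average allele frequency of a two-strain mixture."""
    w_a, w_b = ratio_a_to_b
    if w_a <= 0 or w_b <= 0:
        raise ValueError("mixture weights must be positive")
    if not (0 <= af_strain_a <= 1 and 0 <= af_strain_b <= 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return (w_a * af_strain_a + w_b * af_strain_b) / (w_a + w_b)


def error_rate_by_level(
    columns: Iterable[PileupColumn],
    gold: GoldStandard,
    levels: Sequence[int] = (1, 2, 3, 4, 5),
) -> dict[int, float | None]:
    """Error rate when only alleles with distinct-CS support >= n count.

    The numerator counts non-reference base *observations* (not distinct
    alleles) whose allele clears the support level; the denominator is every
    usable base observation at surveyed (non-gold, non-excluded) positions.
    """
    skip = gold.site_positions() | gold.excluded_positions()
    denom = 0
    numer = {n: 0 for n in levels}
    for col in columns:
        if col.position in skip:
            continue
        denom += col.depth
        for base, obs in col.alleles.items():
            if base == col.ref_base or base == "N" or obs.count == 0:
                continue
            support = len(obs.contexts)
            for n in levels:
                if support >= n:
                    numer[n] += obs.count
    if denom == 0:
        return {n: None for n in levels}
    return {n: numer[n] / denom for n in levels}


def error_spectrum(
    columns: Iterable[PileupColumn],
    gold: GoldStandard | None = None,
    min_support: int = 1,
) -> dict[str, float | None]:
    """Per-class substitution error rates ``rate(X>Y)``.

    ``rate(X>Y)`` divides erroneous observations of X read as Y by the total
    usable observations of reference base X; classes with zero exposure are
    reported as ``None``.
    """
    skip = (
        (gold.site_positions() | gold.excluded_positions()) if gold is not None else set()
    )
    exposure = {b: 0 for b in "ACGT"}
    errors = {c: 0 for c in _TRANSITIONS_CLASSES}
    for col in columns:
        if col.position in skip or col.ref_base not in exposure:
            continue
        exposure[col.ref_base] += col.depth
        for base, obs in col.alleles.items():
            if base == col.ref_base or base == "N" or obs.count == 0:
                continue
            if len(obs.contexts) >= min_support:
                errors[f"{col.ref_base}>{base}"] += obs.count
    return {
        c: (errors[c] / exposure[c[0]] if exposure[c[0]] > 0 else None)
        for c in _TRANSITIONS_CLASSES
    }


def sensitivity_fpr(
    calls: Sequence[VariantCall],
    gold: GoldStandard,
) -> tuple[float | None, float | None]:
    """(sensitivity, FPR) of a deduplicated call set against the gold standard.

    Excluded positions are removed from calls before counting; sensitivity is
    the fraction of gold sites matched by a call (position and alternate
    base), FPR the fraction of eligible calls not matching any gold site.
    """
    excluded = gold.excluded_positions()
    eligible = [c for c in calls if c.position not in excluded]
    gold_keys = gold.site_keys()
    if not gold.sites:
        sensitivity = None
    else:
        hit = {(c.position, c.alt_base) for c in eligible} & gold_keys
        sensitivity = len(hit) / len(gold.sites)
    if not eligible:
        fpr = None
    else:
        fp = sum(1 for c in eligible if (c.position, c.alt_base) not in gold_keys)
        fpr = fp / len(eligible)
    return sensitivity, fpr


@dataclass
class DepthStats:
    cv: float
    log_ratio_min: float
    log_ratio_median: float
    log_ratio_max: float


def depth_stats(per_site_depths: Sequence[float], edge_exclusion: int = 100) -> DepthStats:
    """Depth coefficient of variation and ln(depth/mean) summary.

    The first and last ``edge_exclusion`` sites are excluded; the CV uses the
    population standard deviation.  Zero-depth sites are excluded from the
    log-ratio summary (their ratio is undefined).
    """
    depths = np.asarray(per_site_depths, dtype=float)
    if depths.size <= 2 * edge_exclusion:
        raise ValueError("depth vector shorter than twice the edge exclusion")
    interior = depths[edge_exclusion : depths.size - edge_exclusion] if edge_exclusion else depths
    mean = interior.mean()
    if mean == 0:
        raise ValueError("zero mean depth")
    cv = float(interior.std(ddof=0) / mean)
    ratios = np.log(interior[interior > 0] / mean)
    return DepthStats(
        cv=cv,
        log_ratio_min=float(ratios.min()),
        log_ratio_median=float(np.median(ratios)),
        log_ratio_max=float(ratios.max()),
    )


def data_utilization(raw_base_count: int, cs_usable_base_count: int) -> float:
    """Fraction of raw sequenced bases surviving as usable consensus bases."""
    if raw_base_count <= 0:
        raise ValueError("raw_base_count must be positive")
    return cs_usable_base_count / raw_base_count


@dataclass
class EvalReport:
    """Bundle of the evaluation statistics for one run."""

    error_rate: dict[int, float | None] = field(default_factory=dict)
    sensitivity: dict[int, float | None] = field(default_factory=dict)
    fpr: dict[int, float | None] = field(default_factory=dict)
    spectrum: dict[str, float | None] = field(default_factory=dict)
    depth: DepthStats | None = None
    data_utilization: float | None = None

    def to_dict(self) -> dict:
        out = {
            "error_rate": {str(k): v for k, v in self.error_rate.items()},
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "fpr": {str(k): v for k, v in self.fpr.items()},
            "spectrum": self.spectrum,
            "data_utilization": self.data_utilization,
        }
        if self.depth is not None:
            out["depth"] = {
                "cv": self.depth.cv,
                "log_ratio_min": self.depth.log_ratio_min,
                "log_ratio_median": self.depth.log_ratio_median,
                "log_ratio_max": self.depth.log_ratio_max,
            }
        return out
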