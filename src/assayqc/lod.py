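"""Limit-of-detection estimation from dilution-series replicates.

Replicate libraries of a dilution series are scored against the truth
expected at each level: a truth variant counts as detected in a replicate
iff a call matching its exact variant key passes the active call policy
(minimum depth, frequency, quality; maximum strand bias — all inclusive).
Detection rates are grouped by nominal expected VAF (rounded to 0.1%), and
the LoD is the lowest level detected at the required rate (default 100%)
with every higher level also meeting it — so a non-monotone series cannot
return a spuriously low LoD.  Linearity of observed versus expected
frequencies is summarized by Pearson r and an OLS fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .mixtures import ExpectedProfile
from .variants_io import VariantCall, VariantKey


@dataclass
class CallPolicy:
    """Thresholds a call must meet to count as a detection.

    Defaults mirror the validated pipeline parameters: minimum coverage
    200 reads, minimum quality 300 (raw scale), maximum strand bias 0.79,
    and a 4% minimum frequency at the assay's limit of detection.  All
    comparisons are inclusive.
    """

    min_depth: int = 200
    min_freq_pct: float = 4.0
    min_quality: float = 300.0
    max_strand_bias: float = 0.79

    def __post_init__(self):
        if min(self.min_depth, self.min_freq_pct, self.min_quality) < 0:
            raise ValidationError("policy thresholds must be non-negative")
        if not 0.5 <= self.max_strand_bias <= 1.0:
            raise ValidationError("max_strand_bias must be in [0.5, 1]")

    def passes(self, call: VariantCall) -> bool:
        return (call.depth >= self.min_depth
                and call.observed_pct >= self.min_freq_pct
                and call.quality >= self.min_quality
                and call.strand_bias <= self.max_strand_bias)


@dataclass
class DetectionSeries:
    """Replicate detection outcomes per nominal expected-VAF level."""

    levels: dict[float, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for level, (k, n) in self.levels.items():
            if level <= 0:
                raise ValidationError(f"nominal level {level} must be positive")
            if not 0 <= k <= n or n < 1:
                raise ValidationError(f"invalid counts {k}/{n} at level {level}")

    def rate(self, level: float) -> float:
        k, n = self.levels[level]
        return k / n


def detection_rate(replicates: Sequence[tuple[ExpectedProfile, Sequence[VariantCall]]],
                   policy: CallPolicy | None = None) -> DetectionSeries:
    """Aggregate detection outcomes across labeled replicates.

    Each replicate is a ``(truth, calls)`` pair: the expected profile for
    its dilution level and the calls observed in that library.  Every truth
    variant with a positive expectation contributes one Bernoulli outcome
    to the level given by its expected VAF rounded to 0.1%.  Duplicate
    calls within a replicate and replicate ordering do not matter.
    """
    policy = policy or CallPolicy()
    counts: dict[float, list[int]] = {}
    for item in replicates:
        try:
            truth, calls = item
        except (TypeError, ValueError):
            raise ValidationError("each replicate must be a (truth, calls) pair") from None
        if truth is None:
            raise ValidationError("replicate lacks a nominal-level truth label")
        passing = {c.key for c in calls if policy.passes(c)}
        for key, expected_pct in truth.items():
            if expected_pct <= 0:
                continue
            level = round(expected_pct, 1)
            k_n = counts.setdefault(level, [0, 0])
            k_n[1] += 1
            if key in passing:
                k_n[0] += 1
    return DetectionSeries({lvl: (k, n) for lvl, (k, n) in counts.items()})


def estimate_lod(series: DetectionSeries, required_rate: float = 1.0) -> float | None:
    """Lowest level meeting ``required_rate`` with all higher levels too.

    Returns ``None`` when no level qualifies ("LoD not reached").  Raising
    ``required_rate`` can never lower the estimate.
    """
    if not 0.0 < required_rate <= 1.0:
        raise ValidationError(f"required_rate {required_rate} outside (0, 1]")
    if not series.levels:
        raise ValidationError("empty detection series")
    lod: float | None = None
    for level in sorted(series.levels, reverse=True):
        if series.rate(level) >= required_rate:
            lod = level
        else:
            break
    return lod


def linearity(expected: ExpectedProfile | Mapping[VariantKey, float],
              observed: Mapping[VariantKey, float]) -> tuple[float, float, float]:
    """Pearson r plus OLS slope/intercept of observed on expected VAF.

    Requires at least 3 loci shared between the two maps and non-zero
    variance on both axes.
    """
    exp_map = expected.values if isinstance(expected, ExpectedProfile) else expected
    shared = sorted(set(exp_map) & set(observed))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared loci for linearity, got {len(shared)}"
        )
    x = np.array([exp_map[k] for k in shared], dtype=float)
    y = np.array([observed[k] for k in shared], dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance on one axis")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return r, float(fit.slope), float(fit.intercept)
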