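"""Run-acceptance cutoffs and QC-material monitoring.

Two related workflows live here:

1. **Cutoff derivation.**  Historical values of a run- or call-level metric
   (coverage, Q20 base yield, call quality, strand bias) are checked for
   normality (Shapiro-Wilk); a metric that is normal only after a log10
   transform is handled on that scale.  A one-sided acceptance bound is
   then the classical z-score limit ``mean -/+ z*sd``, back-transformed and
   rounded per a configurable reporting policy.  Bounds are inclusive: a
   value equal to the cutoff passes.

2. **Levey-Jennings monitoring.**  A QC material sequenced over >= n_min
   baseline runs yields per-variant mean, sample SD (n-1 denominator), CV
   and +/-2SD / +/-3SD control limits.  Each subsequent run is banded:
   within 2SD in control, 2-3SD a warning, beyond 3SD a rejection; an
   expected variant missing from the run rejects the run outright.
   Optional Westgard multi-rules (2_2s, R_4s) flag slower drifts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateSampleError,
    InsufficientBaselineError,
    InsufficientDataError,
    NoUsableTransformError,
    ValidationError,
)
from .variants_io import VariantCall, VariantKey

IDENTITY = "identity"
LOG10 = "log10"
AUTO = "auto"


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston approximation).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise InsufficientDataError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {arr.size}")
    if np.ptp(arr) == 0.0:
        raise DegenerateSampleError("constant sample has no distribution to test")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


@dataclass
class MetricSample:
    """Historical values of one metric, with a transform hint."""

    metric_name: str
    values: Sequence[float]
    transform_hint: str = AUTO

    def __post_init__(self):
        if self.transform_hint not in (IDENTITY, LOG10, AUTO):
            raise ValidationError(f"unknown transform hint {self.transform_hint!r}")
        if len(self.values) < 3:
            raise InsufficientDataError("need >= 3 values for normality testing")
        if self.transform_hint == LOG10 and min(self.values) <= 0:
            raise ValidationError("log10 transform requires strictly positive values")


# ---------------------------------------------------------------------------
# cutoff rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoundingPolicy:
    """How a derived bound is rounded for reporting.

    ``kind`` is one of ``none``, ``integer``, ``decimals``, ``sigfigs``;
    ``digits`` applies to the latter two.  Rounding is round-half-to-even.
    """

    kind: str = "none"
    digits: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "integer", "decimals", "sigfigs"):
            raise ValidationError(f"unknown rounding kind {self.kind!r}")
        if self.kind == "sigfigs" and self.digits < 1:
            raise ValidationError("sigfigs rounding needs digits >= 1")

    def apply(self, x: float) -> float:
        if self.kind == "integer":
            return float(round(x))
        if self.kind == "decimals":
            return round(x, self.digits)
        if self.kind == "sigfigs":
            if x == 0.0:
                return 0.0
            magnitude = math.floor(math.log10(abs(x)))
            return round(x, self.digits - 1 - magnitude)
        return x


@dataclass(frozen=True)
class CutoffRule:
    """A derived acceptance bound for one metric.

    ``bound_raw`` lives on the recorded (possibly log10) scale;
    ``bound_reported`` is back-transformed and rounded per policy.
    """

    metric_name: str
    transform: str
    side: str
    confidence_pct: float
    z: float
    mean: float
    sd: float
    bound_raw: float
    bound_reported: float
    rounding: RoundingPolicy = RoundingPolicy()

    def __post_init__(self):
        if self.side not in ("lower", "upper"):
            raise ValidationError(f"side must be lower/upper, got {self.side!r}")
        if self.transform not in (IDENTITY, LOG10):
            raise ValidationError(f"transform must be identity/log10, got {self.transform!r}")
        if self.z < 0:
            raise ValidationError("z must be non-negative")
        expected = self.mean - self.z * self.sd if self.side == "lower" \
            else self.mean + self.z * self.sd
        if not math.isclose(self.bound_raw, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(
                f"bound_raw {self.bound_raw} != mean -/+ z*sd ({expected})"
            )

    def passes(self, value: float) -> bool:
        """Inclusive comparison of a metric value against the bound."""
        if self.side == "lower":
            return value >= self.bound_reported
        return value <= self.bound_reported


def derive_cutoff(sample: MetricSample | None = None, *,
                  mean: float | None = None, sd: float | None = None,
                  metric_name: str | None = None,
                  confidence_pct: float, side: str, z: float,
                  rounding: RoundingPolicy | None = None,
                  alpha: float = 0.05) -> CutoffRule:
    """Derive a z-score acceptance bound for a metric.

    Either ``sample`` (raw historical values; normality is gated with
    Shapiro-Wilk at ``alpha``, falling back to the log10 scale when the
    hint is ``auto``) or summary statistics ``mean``/``sd`` (gate skipped;
    the arithmetic contract alone applies) must be supplied.  ``z`` is
    explicit because published conventions mix one- and two-sided values.
    """
    rounding = rounding or RoundingPolicy()
    if sample is not None:
        transform, values = _gated_scale(sample, alpha)
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        metric_name = sample.metric_name
    else:
        if mean is None or sd is None or metric_name is None:
            raise ValidationError(
                "supply either a MetricSample or mean, sd and metric_name"
            )
        transform = IDENTITY
    return _build_rule(metric_name, transform, side, confidence_pct, z,
                       mean, sd, rounding)


def derive_cutoff_from_summary(metric_name: str, mean: float, sd: float, *,
                               confidence_pct: float, side: str, z: float,
                               transform: str = IDENTITY,
                               rounding: RoundingPolicy | None = None) -> CutoffRule:
    """Cutoff from published summary statistics on a stated scale.

    ``mean``/``sd`` are taken as already living on ``transform``'s scale
    (e.g. a log10-quality mean); no normality gate applies.
    """
    return _build_rule(metric_name, transform, side, confidence_pct, z,
                       mean, sd, rounding or RoundingPolicy())


def _gated_scale(sample: MetricSample, alpha: float) -> tuple[str, np.ndarray]:
    values = np.asarray(sample.values, dtype=float)
    if sample.transform_hint in (IDENTITY, AUTO):
        _, p = shapiro_wilk(values)
        if p >= alpha:
            return IDENTITY, values
        if sample.transform_hint == IDENTITY:
            raise NoUsableTransformError(
                f"{sample.metric_name}: normality rejected (p={p:.4g})"
            )
    if min(sample.values) <= 0:
        raise ValidationError(
            f"{sample.metric_name}: log10 transform requires positive values"
        )
    logged = np.log10(values)
    _, p = shapiro_wilk(logged)
    if p < alpha:
        raise NoUsableTransformError(
            f"{sample.metric_name}: normality rejected on identity and log10 scales"
        )
    return LOG10, logged


def _build_rule(metric_name, transform, side, confidence_pct, z, mean, sd,
                rounding: RoundingPolicy) -> CutoffRule:
    bound_raw = mean - z * sd if side == "lower" else mean + z * sd
    back = 10.0 ** bound_raw if transform == LOG10 else bound_raw
    return CutoffRule(
        metric_name=metric_name, transform=transform, side=side,
        confidence_pct=confidence_pct, z=z, mean=mean, sd=sd,
        bound_raw=bound_raw, bound_reported=rounding.apply(back),
        rounding=rounding,
    )


# ---------------------------------------------------------------------------
# run evaluation
# ---------------------------------------------------------------------------

class RuleStatus(str, enum.Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    MISSING = "MISSING"


@dataclass
class RunVerdict:
    """Per-rule outcomes plus the overall accept/reject decision."""

    results: dict[str, RuleStatus]
    overall_pass: bool


def evaluate_run(metrics: Mapping[str, float], rules: Iterable[CutoffRule]) -> RunVerdict:
    """Check a run's metric values against derived cutoff rules.

    A metric absent from ``metrics`` yields an explicit MISSING verdict for
    its rule and fails the run.
    """
    results: dict[str, RuleStatus] = {}
    for rule in rules:
        if rule.metric_name not in metrics:
            results[rule.metric_name] = RuleStatus.MISSING
        else:
            ok = rule.passes(metrics[rule.metric_name])
            results[rule.metric_name] = RuleStatus.PASS if ok else RuleStatus.FAIL
    overall = bool(results) and all(s is RuleStatus.PASS for s in results.values())
    return RunVerdict(results=results, overall_pass=overall)


# ---------------------------------------------------------------------------
# QC-material baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineStats:
    """Control statistics of one monitored variant over baseline runs."""

    mean_pct: float
    sd_pct: float

    @property
    def cv_pct(self) -> float:
        return 100.0 * self.sd_pct / self.mean_pct if self.mean_pct else math.inf

    @property
    def limit_2sd(self) -> tuple[float, float]:
        return (self.mean_pct - 2 * self.sd_pct, self.mean_pct + 2 * self.sd_pct)

    @property
    def limit_3sd(self) -> tuple[float, float]:
        return (self.mean_pct - 3 * self.sd_pct, self.mean_pct + 3 * self.sd_pct)


@dataclass
class QCBaseline:
    """Per-variant control statistics characterized over >= n_min runs."""

    stats: dict[VariantKey, BaselineStats]
    n_runs: int
    rejected_runs: list[str] = field(default_factory=list)


def characterize_baseline(runs: Sequence[Sequence[VariantCall]] |
                          Mapping[str, Sequence[VariantCall]],
                          truth: Iterable[VariantKey],
                          n_min: int = 10) -> QCBaseline:
    """Characterize the QC material over consecutive baseline runs.

    A run missing any expected variant is rejected from the baseline (and
    reported); fewer than ``n_min`` usable runs raises
    :class:`InsufficientBaselineError`.  SD uses the n-1 denominator.
    """
    truth = list(truth)
    if not truth:
        raise ValidationError("truth variant list is empty")
    if isinstance(runs, Mapping):
        labeled = list(runs.items())
    else:
        labeled = [(f"run_{i + 1:02d}", calls) for i, calls in enumerate(runs)]
    usable: list[dict[VariantKey, float]] = []
    rejected: list[str] = []
    for run_id, calls in labeled:
        observed = {c.key: c.observed_pct for c in calls}
        if all(k in observed for k in truth):
            usable.append(observed)
        else:
            rejected.append(run_id)
    if len(usable) < n_min:
        raise InsufficientBaselineError(
            f"only {len(usable)} usable baseline runs (need {n_min}); "
            f"rejected: {rejected or 'none'}"
        )
    stats_map: dict[VariantKey, BaselineStats] = {}
    for key in truth:
        values = np.array([obs[key] for obs in usable])
        stats_map[key] = BaselineStats(
            mean_pct=float(values.mean()),
            sd_pct=float(values.std(ddof=1)),
        )
    return QCBaseline(stats=stats_map, n_runs=len(usable), rejected_runs=rejected)


# ---------------------------------------------------------------------------
# Levey-Jennings
# ---------------------------------------------------------------------------

class LJState(str, enum.Enum):
    IN_CONTROL = "IN_CONTROL"
    WARNING_2SD = "WARNING_2SD"
    REJECT_3SD = "REJECT_3SD"
    MISSING_VARIANT = "MISSING_VARIANT"


@dataclass
class LJStatus:
    """Control status of one monitored variant in one run."""

    key: VariantKey
    status: LJState
    deviation_sd: float
    observed_pct: float | None = None


@dataclass
class LJReport:
    statuses: dict[VariantKey, LJStatus]
    reject: bool


def _band(deviation_sd: float) -> LJState:
    a = abs(deviation_sd)
    if a <= 2.0:
        return LJState.IN_CONTROL
    if a <= 3.0:
        return LJState.WARNING_2SD
    return LJState.REJECT_3SD


def lj_evaluate(run_calls: Sequence[VariantCall], baseline: QCBaseline) -> LJReport:
    """Band one run's QC-material variants against the baseline.

    ``deviation_sd = (observed - mean) / sd``; a zero-SD baseline with a
    discrepant observation maps to a signed infinite deviation and a
    3SD rejection.  The run is rejected iff any variant is beyond 3SD or
    missing altogether.
    """
    observed = {c.key: c.observed_pct for c in run_calls}
    statuses: dict[VariantKey, LJStatus] = {}
    for key, st in baseline.stats.items():
        if key not in observed:
            statuses[key] = LJStatus(key, LJState.MISSING_VARIANT, math.nan, None)
            continue
        obs = observed[key]
        if st.sd_pct == 0.0:
            dev = 0.0 if obs == st.mean_pct else math.copysign(math.inf, obs - st.mean_pct)
        else:
            dev = (obs - st.mean_pct) / st.sd_pct
        statuses[key] = LJStatus(key, _band(dev), dev, obs)
    reject = any(
        s.status in (LJState.REJECT_3SD, LJState.MISSING_VARIANT)
        for s in statuses.values()
    )
    return LJReport(statuses=statuses, reject=reject)


#: Westgard multi-rules supported by :func:`lj_series` (opt-in advisories).
WESTGARD_RULES = ("2_2s", "R_4s")


def lj_series(history: Sequence[tuple[str, Sequence[VariantCall]]],
              baseline: QCBaseline,
              westgard: Iterable[str] = ()) -> tuple["object", list[tuple[str, VariantKey, str]]]:
    """Build a Levey-Jennings chart table over an ordered run history.

    Returns a pandas DataFrame (one row per run per variant: observed,
    mean, 2SD/3SD limits, deviation and status) and a list of advisory
    Westgard flags ``(run_id, variant, rule)`` for the enabled rules:

    * ``2_2s`` — two consecutive runs beyond the same 2SD limit;
    * ``R_4s`` — consecutive deviations spanning more than 4 SD.
    """
    import pandas as pd

    if not history:
        raise InsufficientDataError("need at least one evaluated run")
    westgard = set(westgard)
    unknown = westgard - set(WESTGARD_RULES)
    if unknown:
        raise ValidationError(f"unknown Westgard rules: {sorted(unknown)}")

    rows = []
    flags: list[tuple[str, VariantKey, str]] = []
    prev_dev: dict[VariantKey, float] = {}
    for run_id, calls in history:
        report = lj_evaluate(calls, baseline)
        for key, status in report.statuses.items():
            st = baseline.stats[key]
            lo2, hi2 = st.limit_2sd
            lo3, hi3 = st.limit_3sd
            rows.append({
                "run_id": run_id, "variant": str(key),
                "observed_pct": status.observed_pct,
                "mean_pct": st.mean_pct,
                "minus_3sd": lo3, "minus_2sd": lo2,
                "plus_2sd": hi2, "plus_3sd": hi3,
                "deviation_sd": status.deviation_sd,
                "status": status.status.value,
            })
            dev = status.deviation_sd
            if key in prev_dev and math.isfinite(dev) and math.isfinite(prev_dev[key]):
                p = prev_dev[key]
                if "2_2s" in westgard and abs(dev) > 2 and abs(p) > 2 and dev * p > 0:
                    flags.append((run_id, key, "2_2s"))
                if "R_4s" in westgard and abs(dev - p) > 4:
                    flags.append((run_id, key, "R_4s"))
            prev_dev[key] = dev
    return pd.DataFrame(rows), flags
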