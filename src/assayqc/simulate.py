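"""Synthetic sequencing-run generator for the assay-QC pipeline.

The generator emulates the data-generating process the analysis assumes:
per-locus read depth drawn from a lognormal (or negative binomial) model,
alternate-read counts binomially sampled at the true VAF perturbed by a
per-read base error rate, call quality lognormal on the log10 scale,
strand bias near-symmetric, and run-level metrics drawn from configured
normal summaries.  Presets match the validated assay's operating points:
fresh-frozen libraries average ~2000x coverage, FFPE libraries ~1300x,
FFPE adds sporadic low-frequency C:G>T:A deamination artifacts kept below
the assay's 4% limit of detection.

All randomness flows from a single integer seed through numpy
``SeedSequence`` sub-streams (one per run index), so identical configs
reproduce byte-identical outputs and runs can be regenerated
independently.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .mixtures import (
    CopyState,
    ExpectedProfile,
    LineProfile,
    LocusGenotype,
    MixtureSpec,
    mixture_profile,
    serial_dilute,
)
from .variants_io import RunMetrics, VariantCall, VariantKey

_CHROM_POOL = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X"])


@dataclass(frozen=True)
class DepthModel:
    """Per-locus read depth distribution."""

    distribution: str = "lognormal"  # or "negative_binomial"
    mean: float = 2000.0
    dispersion: float = 0.3  # CV for lognormal; 1/size for negative binomial

    def __post_init__(self):
        if self.distribution not in ("lognormal", "negative_binomial"):
            raise ValidationError(f"unknown depth distribution {self.distribution!r}")
        if self.mean <= 0 or self.dispersion < 0:
            raise ValidationError("depth mean must be positive, dispersion non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dispersion == 0:
            return np.full(n, round(self.mean), dtype=int)
        if self.distribution == "lognormal":
            sigma2 = math.log1p(self.dispersion ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), n).round().astype(int)
        size = 1.0 / self.dispersion
        p = size / (size + self.mean)
        return rng.negative_binomial(size, p, n)


@dataclass(frozen=True)
class NoiseModel:
    """Sequencing noise and FFPE damage parameters."""

    base_error_rate: float = 1e-3
    ffpe_ct_rate: float = 0.0      # P(artifact) per susceptible locus per run
    artifact_vaf_range: tuple[float, float] = (1.0, 3.0)  # percent
    n_susceptible_loci: int = 50

    def __post_init__(self):
        for p in (self.base_error_rate, self.ffpe_ct_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        lo, hi = self.artifact_vaf_range
        if not 0.0 <= lo <= hi <= 100.0:
            raise ValidationError("artifact_vaf_range must be within [0, 100]")


@dataclass(frozen=True)
class MetricModel:
    """Normal (mean, sd) summaries for call- and run-level metrics."""

    quality_log10: tuple[float, float] = (3.65, 0.45)
    strand_bias: tuple[float, float] = (0.7, 0.04)
    q20_bases: tuple[float, float] = (2.5e7, 2.4e6)
    reads_on_target_pct: tuple[float, float] = (95.13, 2.33)
    uniformity_pct: tuple[float, float] = (98.26, 0.68)


@dataclass(frozen=True)
class SimulatorConfig:
    """Everything a simulation needs; the seed is mandatory."""

    seed: int
    depth: DepthModel = DepthModel()
    noise: NoiseModel = NoiseModel()
    metrics: MetricModel = MetricModel()
    n_replicates: int = 3

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def frozen_config(seed: int, **overrides) -> SimulatorConfig:
    """Preset for fresh-frozen libraries (~2000x mean coverage)."""
    return SimulatorConfig(seed=seed, depth=DepthModel(mean=2000.0), **overrides)


def ffpe_config(seed: int, **overrides) -> SimulatorConfig:
    """Preset for FFPE libraries (~1300x coverage, deamination artifacts)."""
    return SimulatorConfig(
        seed=seed,
        depth=DepthModel(mean=1300.0),
        noise=NoiseModel(ffpe_ct_rate=0.02),
        **overrides,
    )


@dataclass
class SimulatedRun:
    """One synthetic sequencing run with full provenance."""

    run_id: str
    calls: list[VariantCall]
    metrics: RunMetrics
    truth: ExpectedProfile
    config: SimulatorConfig
    stream_key: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def simulate_profiles(seed: int, n_lines: int = 4, n_loci: int = 40,
                      freq_spectrum: Sequence[float] = (50.0, 100.0),
                      presence_rate: float = 0.5,
                      hom_deletion_rate: float = 0.0,
                      jitter_sd: float = 0.0) -> dict[str, LineProfile]:
    """Generate characterized cell-line profiles.

    Loci are drawn without collision across a pool of chromosomes; each
    line carries each locus with probability ``presence_rate``, at a
    frequency drawn uniformly from ``freq_spectrum`` (typically values
    near 50 for heterozygous and 100 for homozygous clonal variants, or a
    custom list) plus optional normal jitter, clipped to [0.1, 100].
    ``hom_deletion_rate`` marks carried loci as homozygously deleted.
    """
    if n_lines < 1 or n_loci < 1:
        raise ValidationError("n_lines and n_loci must be >= 1")
    if not freq_spectrum:
        raise ValidationError("freq_spectrum is empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bases = np.array(list("ACGT"))
    seen: set[tuple[str, int]] = set()
    keys: list[VariantKey] = []
    while len(keys) < n_loci:
        chrom = str(rng.choice(_CHROM_POOL))
        pos = int(rng.integers(1_000_000, 200_000_000))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref, alt = rng.choice(bases, size=2, replace=False)
        keys.append(VariantKey(chrom, pos, str(ref), str(alt),
                               gene=f"GENE{len(keys) + 1:03d}"))
    profiles: dict[str, LineProfile] = {}
    spectrum = np.asarray(freq_spectrum, dtype=float)
    for i in range(n_lines):
        name = f"LINE{i + 1:02d}"
        entries: dict[VariantKey, LocusGenotype] = {}
        for key in keys:
            if rng.random() >= presence_rate:
                continue
            if hom_deletion_rate and rng.random() < hom_deletion_rate:
                entries[key] = LocusGenotype(0.0, CopyState.HOM_DELETION)
                continue
            freq = float(rng.choice(spectrum))
            if jitter_sd:
                freq = float(np.clip(freq + rng.normal(0.0, jitter_sd), 0.1, 100.0))
            entries[key] = LocusGenotype(freq, CopyState.NORMAL)
        profiles[name] = LineProfile(name, entries)
    return profiles


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

def _effective_p(f_pct: float, base_error_rate: float) -> float:
    p = f_pct / 100.0
    return p * (1.0 - base_error_rate) + (1.0 - p) * base_error_rate


def simulate_run(truth: ExpectedProfile, config: SimulatorConfig,
                 run_id: str = "sim_run",
                 stream_key: tuple[int, ...] = ()) -> SimulatedRun:
    """Simulate one sequencing run of a sample with known truth.

    Per locus: depth from the depth model; alternate reads binomial at the
    truth VAF adjusted by the base error rate; observed percent is the
    exact read ratio, so alt reads never exceed depth.  Zero-depth draws
    emit a zero-depth call flagged ``ZERO_DEPTH`` rather than dropping the
    locus.  FFPE C>T artifacts are injected at synthetic susceptible loci
    with the configured probability, at VAFs inside the configured range.
    ``stream_key`` selects a reproducible sub-stream of the config seed.
    """
    if not len(truth):
        raise ValidationError("truth profile is empty")
    seq = np.random.SeedSequence(config.seed, spawn_key=stream_key)
    rng = np.random.default_rng(seq)
    keys = sorted(truth.values)
    depths = config.depth.sample(rng, len(keys))
    q_mu, q_sd = config.metrics.quality_log10
    sb_mu, sb_sd = config.metrics.strand_bias
    calls: list[VariantCall] = []
    for key, depth in zip(keys, depths):
        depth = int(depth)
        quality = float(10.0 ** rng.normal(q_mu, q_sd))
        strand_bias = float(np.clip(rng.normal(sb_mu, sb_sd), 0.5, 1.0))
        if depth <= 0:
            calls.append(VariantCall(key, 0.0, 0, alt_depth=0, quality=quality,
                                     strand_bias=strand_bias,
                                     filters={"ZERO_DEPTH"}))
            continue
        p = _effective_p(truth[key], config.noise.base_error_rate)
        alt = int(rng.binomial(depth, p))
        calls.append(VariantCall(
            key, 100.0 * alt / depth, depth, alt_depth=alt,
            quality=quality, strand_bias=strand_bias,
        ))
    calls.extend(_ffpe_artifacts(rng, config))
    metrics = _sample_metrics(rng, config, run_id, depths)
    return SimulatedRun(run_id=run_id, calls=calls, metrics=metrics,
                        truth=truth, config=config, stream_key=stream_key)


def _ffpe_artifacts(rng: np.random.Generator, config: SimulatorConfig) -> list[VariantCall]:
    noise = config.noise
    if noise.ffpe_ct_rate <= 0.0:
        return []
    lo, hi = noise.artifact_vaf_range
    artifacts = []
    for i in range(noise.n_susceptible_loci):
        if rng.random() >= noise.ffpe_ct_rate:
            continue
        key = VariantKey(
            chrom=str(rng.choice(_CHROM_POOL)),
            pos=int(rng.integers(1_000_000, 200_000_000)),
            ref="C", alt="T", gene=f"FFPE{i + 1:03d}",
        )
        depth = max(int(config.depth.sample(rng, 1)[0]), 1)
        vaf = float(rng.uniform(lo, hi))
        alt = int(rng.binomial(depth, vaf / 100.0))
        artifacts.append(VariantCall(
            key, 100.0 * alt / depth, depth, alt_depth=alt,
            quality=float(10.0 ** rng.normal(*config.metrics.quality_log10)),
            strand_bias=float(np.clip(rng.normal(*config.metrics.strand_bias), 0.5, 1.0)),
            filters={"FFPE_ARTIFACT"},
        ))
    return artifacts


def _sample_metrics(rng, config: SimulatorConfig, run_id: str,
                    depths: np.ndarray) -> RunMetrics:
    m = config.metrics
    return RunMetrics(
        run_id=run_id,
        mean_depth=float(np.mean(depths)) if len(depths) else 0.0,
        q20_bases=max(int(rng.normal(*m.q20_bases)), 0),
        reads_on_target_pct=float(np.clip(rng.normal(*m.reads_on_target_pct), 0, 100)),
        uniformity_pct=float(np.clip(rng.normal(*m.uniformity_pct), 0, 100)),
    )


# ---------------------------------------------------------------------------
# dilution series and drift
# ---------------------------------------------------------------------------

def simulate_dilution_series(profiles: Mapping[str, LineProfile],
                             spec: MixtureSpec,
                             diluent: LineProfile,
                             fractions: Sequence[float],
                             config: SimulatorConfig
                             ) -> dict[float, list[SimulatedRun]]:
    """Simulate replicate libraries across a dilution series.

    Truth per level is the mixture expectation serially diluted at each
    mix fraction; ``config.n_replicates`` runs are generated per level,
    each labeled with its nominal truth.
    """
    base = mixture_profile(profiles, spec)
    out: dict[float, list[SimulatedRun]] = {}
    for li, fraction in enumerate(fractions):
        truth = base if fraction == 1.0 else serial_dilute(base, diluent, fraction)
        runs = []
        for rep in range(config.n_replicates):
            runs.append(simulate_run(
                truth, config,
                run_id=f"level{li}_rep{rep + 1}",
                stream_key=(li, rep),
            ))
        out[fraction] = runs
    return out


def inject_drift(baseline_truth: ExpectedProfile, shift_sd: float,
                 from_run: int, n_runs: int,
                 config: SimulatorConfig) -> list[SimulatedRun]:
    """Simulate an ordered run sequence with a known changepoint.

    Runs with 0-based index < ``from_run`` follow the baseline truth;
    from ``from_run`` onward each variant's truth mean is shifted by
    ``shift_sd`` times its binomial sampling SD at the model's mean depth,
    clipped to [0, 100].  A shift of 0 reproduces the null.
    """
    if from_run > n_runs:
        raise ValidationError("from_run must be <= n_runs")
    shifted = ExpectedProfile({
        key: float(np.clip(f + shift_sd * binomial_sd_pct(f, config.depth.mean), 0, 100))
        for key, f in baseline_truth.items()
    })
    runs = []
    for i in range(n_runs):
        truth = baseline_truth if i < from_run else shifted
        runs.append(simulate_run(truth, config, run_id=f"monitor_{i + 1:02d}",
                                 stream_key=(i,)))
    return runs


def binomial_sd_pct(f_pct: float, depth: float) -> float:
    """Closed-form binomial SD of an observed VAF, in percent."""
    p = f_pct / 100.0
    return 100.0 * math.sqrt(p * (1.0 - p) / depth)


def detection_tail_probability(truth_pct: float, depth: int,
                               min_freq_pct: float) -> float:
    """Exact P(observed VAF >= threshold) under binomial read sampling."""
    from scipy import stats as _stats

    k_min = math.ceil(min_freq_pct / 100.0 * depth)
    return float(_stats.binom.sf(k_min - 1, depth, truth_pct / 100.0))
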