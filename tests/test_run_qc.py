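"""Cutoff derivation, run evaluation, baselines and Levey-Jennings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assayqc import datasets
from assayqc.exceptions import (
    DegenerateSampleError,
    InsufficientBaselineError,
    InsufficientDataError,
    NoUsableTransformError,
    ValidationError,
)
from assayqc.run_qc import (
    LJState,
    MetricSample,
    RoundingPolicy,
    RuleStatus,
    characterize_baseline,
    derive_cutoff,
    derive_cutoff_from_summary,
    evaluate_run,
    lj_evaluate,
    lj_series,
    shapiro_wilk,
)
from assayqc.simulate import binomial_sd_pct
from assayqc.variants_io import VariantKey
from conftest import make_call

QC_KEYS = list(datasets.qc_material_stats())


def qc_run(rng, truth, depth=1300):
    """One synthetic QC-material run: binomial sampling at fixed depth."""
    return [
        make_call(chrom=k.chrom, pos=k.pos, ref=k.ref, alt=k.alt, gene=k.gene,
                  pct=100.0 * rng.binomial(depth, m / 100.0) / depth, depth=depth)
        for k, m in truth.items()
    ]


class TestShapiroWilk:
    def test_null_rarely_rejected(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.normal(size=500))
            rejections += p <= 0.01
        assert rejections <= 5

    def test_exponential_usually_rejected_at_n50(self):
        rejected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.exponential(size=50))
            rejected += p < 0.05
        assert rejected >= 45

    def test_boundary_n3_well_defined(self):
        w, p = shapiro_wilk([-1.0, 0.0, 1.0])
        assert 0 < w <= 1 and 0 <= p <= 1

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([5.0] * 10)

    @pytest.mark.parametrize("n", [2, 5001])
    def test_size_limits(self, n):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk(list(range(n)))


class TestDeriveCutoff:
    @pytest.mark.parametrize("spec,expected", [
        (dict(metric_name="coverage", mean=1231.0, sd=526.0, z=1.96,
              side="lower", rounding=RoundingPolicy("integer")), 200.0),
        (dict(metric_name="q20_bases", mean=2.5e7, sd=2.4e6, z=1.96,
              side="lower", rounding=RoundingPolicy("sigfigs", 2)), 2.0e7),
        (dict(metric_name="strand_bias", mean=0.7, sd=0.04, z=2.326,
              side="upper", rounding=RoundingPolicy("decimals", 2)), 0.79),
    ])
    def test_published_summary_cutoffs(self, spec, expected):
        rule = derive_cutoff(confidence_pct=95.0, **spec)
        assert rule.bound_reported == expected

    def test_log_scale_quality_bound_antilogged(self):
        rule = derive_cutoff_from_summary(
            "quality", 3.65, 0.45, confidence_pct=99.0, side="lower",
            z=2.576, transform="log10", rounding=RoundingPolicy("sigfigs", 1))
        assert rule.bound_raw == pytest.approx(2.4908)
        assert rule.bound_reported == 300.0

    def test_zero_variance_bound_is_mean(self):
        rule = derive_cutoff(metric_name="m", mean=42.0, sd=0.0,
                             confidence_pct=95.0, side="lower", z=5.0)
        assert rule.bound_raw == 42.0 == rule.bound_reported

    def test_closed_form_exact_before_rounding(self):
        rule = derive_cutoff(metric_name="m", mean=10.0, sd=3.0,
                             confidence_pct=95.0, side="upper", z=1.96)
        assert rule.bound_raw == pytest.approx(10.0 + 1.96 * 3.0, abs=1e-12)

    def test_normality_gate_picks_log_scale(self):
        rng = np.random.default_rng(11)
        sample = MetricSample("quality", 10.0 ** rng.normal(3.65, 0.45, 200))
        rule = derive_cutoff(sample, confidence_pct=99.0, side="lower", z=2.576)
        assert rule.transform == "log10"
        # mean/sd recorded on the log scale
        assert 3.0 < rule.mean < 4.3

    def test_identity_scale_kept_when_normal(self):
        rng = np.random.default_rng(12)
        sample = MetricSample("coverage", rng.normal(1231, 526, 200))
        rule = derive_cutoff(sample, confidence_pct=95.0, side="lower", z=1.96)
        assert rule.transform == "identity"

    def test_no_usable_transform(self):
        rng = np.random.default_rng(13)
        # heavy bimodal sample: non-normal on both scales
        values = np.concatenate([rng.normal(10, 0.1, 100), rng.normal(1000, 0.1, 100)])
        sample = MetricSample("weird", values)
        with pytest.raises(NoUsableTransformError):
            derive_cutoff(sample, confidence_pct=95.0, side="lower", z=1.96)

    def test_log_identity_round_trip_at_zero_sd(self):
        rule = derive_cutoff_from_summary(
            "q", 2.0, 0.0, confidence_pct=95.0, side="lower", z=1.96,
            transform="log10")
        assert rule.bound_reported == pytest.approx(100.0)


class TestEvaluateRun:
    @pytest.fixture
    def rules(self):
        return [
            derive_cutoff(metric_name="coverage", mean=1231.0, sd=526.0,
                          confidence_pct=95.0, side="lower", z=1.96,
                          rounding=RoundingPolicy("integer")),
            derive_cutoff(metric_name="strand_bias", mean=0.7, sd=0.04,
                          confidence_pct=99.0, side="upper", z=2.326,
                          rounding=RoundingPolicy("decimals", 2)),
        ]

    def test_historical_means_pass_their_own_cutoffs(self, rules):
        verdict = evaluate_run({"coverage": 1231.0, "strand_bias": 0.7}, rules)
        assert verdict.overall_pass

    def test_violations_fail(self, rules):
        verdict = evaluate_run({"coverage": 1231.0, "strand_bias": 0.85}, rules)
        assert verdict.results["strand_bias"] is RuleStatus.FAIL
        assert not verdict.overall_pass

    def test_bounds_inclusive(self, rules):
        verdict = evaluate_run({"coverage": 200.0, "strand_bias": 0.79}, rules)
        assert verdict.overall_pass

    def test_missing_metric_explicit_and_fails_run(self, rules):
        verdict = evaluate_run({"coverage": 1231.0}, rules)
        assert verdict.results["strand_bias"] is RuleStatus.MISSING
        assert not verdict.overall_pass


class TestBaseline:
    def test_constant_observations(self):
        key = QC_KEYS[0]
        runs = [[make_call(chrom=key.chrom, pos=key.pos, ref=key.ref,
                           alt=key.alt, gene=key.gene, pct=18.5, depth=1200)]
                for _ in range(10)]
        baseline = characterize_baseline(runs, [key], n_min=10)
        st_ = baseline.stats[key]
        assert (st_.mean_pct, st_.sd_pct, st_.cv_pct) == (18.5, 0.0, 0.0)

    def test_parameter_recovery_under_binomial_noise(self):
        rng = np.random.default_rng(42)
        truth = {QC_KEYS[0]: 18.5}
        depth = 1200
        runs = [qc_run(rng, truth, depth) for _ in range(10)]
        baseline = characterize_baseline(runs, list(truth), n_min=10)
        tol = 3 * binomial_sd_pct(18.5, depth) / math.sqrt(10)
        assert abs(baseline.stats[QC_KEYS[0]].mean_pct - 18.5) < tol

    def test_incomplete_runs_rejected_and_reported(self):
        key = QC_KEYS[0]
        good = [make_call(chrom=key.chrom, pos=key.pos, ref=key.ref,
                          alt=key.alt, gene=key.gene, pct=18.5, depth=1200)]
        runs = {"r1": good, "r2": [], "r3": good, "r4": good}
        with pytest.raises(InsufficientBaselineError, match="r2"):
            characterize_baseline(runs, [key], n_min=4)
        baseline = characterize_baseline(runs, [key], n_min=3)
        assert baseline.rejected_runs == ["r2"]
        assert baseline.n_runs == 3

    def test_too_few_runs(self):
        key = QC_KEYS[0]
        runs = [[make_call(chrom=key.chrom, pos=key.pos, ref=key.ref,
                           alt=key.alt, gene=key.gene, pct=18.5, depth=1200)]
                for _ in range(9)]
        with pytest.raises(InsufficientBaselineError):
            characterize_baseline(runs, [key], n_min=10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.05, 5.0))
    def test_cv_scale_invariant(self, scale):
        key = QC_KEYS[0]
        values = [17.0, 18.0, 19.0, 18.5, 17.5, 18.2, 18.8, 17.9, 18.1, 18.6]
        def runs_for(k):
            return [[make_call(chrom=key.chrom, pos=key.pos, ref=key.ref,
                               alt=key.alt, gene=key.gene, pct=v * k, depth=1200)]
                    for v in values]
        base = characterize_baseline(runs_for(1.0), [key]).stats[key].cv_pct
        scaled = characterize_baseline(runs_for(scale), [key]).stats[key].cv_pct
        assert scaled == pytest.approx(base, rel=1e-9)


class TestLeveyJennings:
    @pytest.fixture
    def baseline(self):
        stats = datasets.qc_material_stats()
        rng = np.random.default_rng(5)
        runs = []
        for _ in range(10):
            runs.append([
                make_call(chrom=k.chrom, pos=k.pos, ref=k.ref, alt=k.alt,
                          gene=k.gene, pct=float(np.clip(rng.normal(m, s), 0, 100)),
                          depth=1300)
                for k, (m, s, _) in stats.items()
            ])
        return characterize_baseline(runs, list(stats), n_min=10)

    def run_at(self, baseline, deviations):
        return [
            make_call(chrom=k.chrom, pos=k.pos, ref=k.ref, alt=k.alt, gene=k.gene,
                      pct=float(np.clip(
                          baseline.stats[k].mean_pct
                          + deviations.get(k, 0.0) * baseline.stats[k].sd_pct,
                          0, 100)),
                      depth=1300)
            for k in baseline.stats
        ]

    def test_observed_mean_in_control(self, baseline):
        report = lj_evaluate(self.run_at(baseline, {}), baseline)
        assert all(s.status is LJState.IN_CONTROL for s in report.statuses.values())
        assert not report.reject

    def test_banding_partition(self, baseline):
        key = QC_KEYS[0]
        for dev, state in ((0.0, LJState.IN_CONTROL), (2.0, LJState.IN_CONTROL),
                           (2.5, LJState.WARNING_2SD), (-2.5, LJState.WARNING_2SD),
                           (3.0, LJState.WARNING_2SD), (3.5, LJState.REJECT_3SD),
                           (-4.0, LJState.REJECT_3SD)):
            report = lj_evaluate(self.run_at(baseline, {key: dev}), baseline)
            assert report.statuses[key].status is state, dev
            assert report.statuses[key].deviation_sd == pytest.approx(dev, abs=1e-6)

    def test_missing_expected_variant_rejects_run(self, baseline):
        run = self.run_at(baseline, {})[1:]  # drop one expected variant
        report = lj_evaluate(run, baseline)
        dropped = next(iter(baseline.stats))
        assert report.statuses[dropped].status is LJState.MISSING_VARIANT
        assert report.reject

    def test_zero_sd_guard(self):
        key = QC_KEYS[0]
        runs = [[make_call(chrom=key.chrom, pos=key.pos, ref=key.ref,
                           alt=key.alt, gene=key.gene, pct=18.5, depth=1200)]
                for _ in range(10)]
        baseline = characterize_baseline(runs, [key])
        off = [make_call(chrom=key.chrom, pos=key.pos, ref=key.ref,
                         alt=key.alt, gene=key.gene, pct=19.0, depth=1200)]
        report = lj_evaluate(off, baseline)
        assert report.statuses[key].status is LJState.REJECT_3SD
        assert math.isinf(report.statuses[key].deviation_sd)

    def test_series_flags_westgard_2_2s(self, baseline):
        key = QC_KEYS[0]
        history = [
            ("r1", self.run_at(baseline, {})),
            ("r2", self.run_at(baseline, {key: 2.5})),
            ("r3", self.run_at(baseline, {key: 2.6})),
        ]
        frame, flags = lj_series(history, baseline, westgard={"2_2s"})
        assert ("r3", key, "2_2s") in flags
        assert ("r2", key, "2_2s") not in flags
        assert set(frame["run_id"]) == {"r1", "r2", "r3"}

    def test_series_flags_westgard_r_4s(self, baseline):
        key = QC_KEYS[0]
        history = [
            ("r1", self.run_at(baseline, {key: 2.5})),
            ("r2", self.run_at(baseline, {key: -2.5})),
        ]
        _, flags = lj_series(history, baseline, westgard={"R_4s"})
        assert ("r2", key, "R_4s") in flags

    def test_in_control_series_has_no_flags(self, baseline):
        history = [(f"r{i}", self.run_at(baseline, {})) for i in range(6)]
        _, flags = lj_series(history, baseline, westgard={"2_2s", "R_4s"})
        assert flags == []

    def test_empty_history_rejected(self, baseline):
        with pytest.raises(InsufficientDataError):
            lj_series([], baseline)
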