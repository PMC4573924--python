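# Methods

This note documents the models, conventions and numerical choices behind
`assayqc`, and what the synthetic-data generator does and does not
emulate.

## Conventions at the I/O boundary

Genomic coordinates are 1-based internally (the convention of clinical
hotspot reports); BED input is converted once on read and back on write.
Allele frequencies are carried in **percent** (0–100) end to end; VCF
fractional `AF` values are converted at the boundary.  Deletions are
stored VCF-style (anchored reference allele, shorter alternate); display
forms such as "DEL CTT" are presentation only.  Strand bias is defined as
the larger per-strand alternate-read proportion, hence in [0.5, 1]; an
upper bound near 0.79 flags one-sided support.  Text round-trips retain
six decimals, which makes VCF float32 storage lossless for values printed
with up to four decimals.

The characterization tables in `assayqc.datasets` print only the
alternate base for most loci, so reference bases there are synthetic
placeholders (documented in the module docstring); positions, genes,
alternate alleles and every frequency are the published values.

## Mixture expectation model

For lines i with per-locus VAF f_i (percent), copy weight c_i ∈ {0, 1}
and DNA mass fractions w_i (Σ w_i = 1):

    E[f] = Σ w_i·c_i·f_i / Σ w_i·c_i.

Assumptions: mixing is by DNA mass; loci are copy-neutral unless declared
homozygously deleted; amplification is unbiased across components.  When
every c_i = 1 this is the plain weighted mean with absent variants
counted at 0 %, which reproduces the published equal-mix expected values
to within ±0.1 (the residual is the source tables' own rounding).  A
locus deleted in every component has no template to sequence and raises
an explicit error rather than returning 0.

Two published conventions needed a decision:

* **"Dilution 1:k"** is interpreted as final mix fraction 1/k (not
  1/(k+1)); this reproduces the diluent-borne germline expectations
  (e.g. 55.8 % → 27.9 % at 1:2 and 37.2 % at 1:3) exactly.
* **Idealized genotypes in dilution expectations.**  The published
  dilution expected column uses genotype values (homozygous = 100 %)
  rather than the measured pure-line VAFs: a homozygous variant diluted
  into a line with a homozygous deletion of the same gene is expected at
  100.0 % at any mixing ratio, because only the carrier contributes
  templates.  `datasets.ffpe_dilution_profiles()` therefore carries the
  idealized genotype for that locus, while the measured value remains in
  the per-line profile table.

Several published dilution expected cells do not follow any single
mixing convention derivable from the printed pure-line frequencies; they
are excluded from numeric verification (the equal-mix columns and the
diluent-borne loci are verified in full).

Reported expectations are rounded half-to-even to one decimal; internal
computation is full precision.

## Limit of detection

A truth variant counts as detected in a replicate iff a call with the
exact same variant key passes the active `CallPolicy`.  The shipped
default policy mirrors the validated pipeline: minimum depth 200 reads,
minimum quality 300 (raw scale), maximum strand bias 0.79, minimum
frequency 4 %.  All thresholds are inclusive, matching the cutoff
semantics ("cutoff" = last acceptable value).

Detection outcomes are grouped by expected VAF rounded to 0.1 %, because
the dilution experiment is indexed by expectation, not by observed means.
The LoD estimator returns the smallest level meeting the required rate
(default 1.0) **whose higher levels all meet it too**; without the suffix
condition a non-monotone series could return a spuriously low LoD.
"Not reached" is returned as Python `None`.  Probit/logistic LoD models
and confidence intervals on the LoD are out of scope.

## Run-metric cutoffs

Cutoffs are classical one-sided z-score bounds x̄ ∓ z·s.  When raw
historical values are supplied, normality is gated with Shapiro–Wilk
(scipy's Royston implementation) at α = 0.05 on the identity scale,
falling back to log10 when the hint allows; a metric normal on neither
scale raises rather than producing a bound.  When published summary
statistics are supplied the gate is skipped and the arithmetic contract
alone applies, on whichever scale the summary is stated (a log10-scale
bound is back-transformed before rounding).

z is explicit per rule because published conventions mix one- and
two-sided values: the shipped defaults use z = 1.96 for the 95 % rows,
one-sided z = 2.326 for the 99 % strand-bias bound, and two-sided
z = 2.576 for the 99 % log-quality bound.  The log-quality bound computes
as 3.65 − 2.576·0.45 = 2.4908 (the corresponding source z value appears
as 2.48, presumably from unrounded inputs; the difference vanishes at the
reported precision of the back-transformed bound, 10^2.4908 ≈ 310 → 300
at one significant figure).  Rounding policy (nearest integer, decimals,
significant figures; round-half-to-even) is part of each rule because the
published table mixes conventions.  Bounds are inclusive, so a historical
mean always passes its own cutoff.  Sample SD uses the n−1 denominator
throughout (standard clinical-QC practice).

## QC-material baseline and Levey-Jennings monitoring

The baseline requires ≥ n_min runs (default 10, configurable) in which
every expected variant was called; incomplete runs are rejected from the
baseline and reported.  Per variant: mean, SD (n−1), CV = 100·SD/mean,
and ±2SD/±3SD limits.  CVs are computed from full-precision SDs, so they
can differ in the last digit from CVs recomputed from rounded SDs.

Monitoring bands the signed deviation (observed − mean)/SD:
|dev| ≤ 2 in control, 2 < |dev| ≤ 3 warning, > 3 reject; an expected
variant absent from a run rejects the run outright.  A zero-SD baseline
with a discrepant observation maps to a signed infinite deviation and a
3SD rejection (documented sentinel).  The banding is a partition: every
finite deviation maps to exactly one status.  Westgard multi-rules are
opt-in advisories on top of the 1_2s/1_3s core: `2_2s` (two consecutive
runs beyond the same 2SD limit, same sign) and `R_4s` (consecutive
deviations spanning more than 4 SD).  CUSUM/EWMA charts are out of scope.

## Concordance scoring

The scoring unit is the **sample** over the queried gene set: a sample is
reference-positive if any queried gene is positive by the reference
assay, test-positive if the panel produced any policy-passing call in
those genes (or any positive result row, for assay-versus-assay tables).
This per-sample accounting is what yields the published 29/30 positive
and 25/25 negative split on the 55-sample cohort (sensitivity 96.7 %,
specificity 100.0 %): the single discordance is a reference-positive
sample whose variant sat below the panel's 4 % limit of detection and so
scores as a false negative, exactly as the policy dictates.  An
`hgvs_level` mode additionally requires the coding change to match
(exact string comparison; HGVS normalization is out of scope).  With all
negatives concordant, sample-level and sample-gene-level specificity
coincide here; the sample reading is adopted without claiming it is the
only one.

## Artifact rules

Three independent predicates, each configurable and each disabled when
its annotation source is absent:

* `HIGH_MAF_SNP`: annotated global minor allele frequency ≥ 0.01 (the
  common-SNP convention; the published exemplar has MAF 0.4183).
* `END_OF_AMPLICON`: the position lies within 5 bp of a boundary in
  *every* covering amplicon (a second amplicon covering the position
  mid-body rescues it); a position covered by no amplicon gets
  `OFF_TARGET` instead.
* `HOMOPOLYMER`: the position lies within or immediately adjacent to a
  single-base reference run of length ≥ 4 — a known error mode of
  semiconductor sequencing.

The MAF threshold, edge distance and run length are package defaults
(the source names the classes but not the parameters) and are explicit
config.  Blacklisted calls retain all their data and are only removed
from the "reportable" view.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* per-locus depth ~ lognormal with configurable mean and CV (negative
  binomial available); presets use mean 2000× (fresh-frozen) and 1300×
  (FFPE) with CV 0.3 — the means match the assay's reported operating
  points, the spread is a package choice;
* alternate reads ~ Binomial(depth, p) with p the truth VAF perturbed by
  a symmetric per-read error rate (default 10⁻³); observed percent is the
  exact read ratio, so alt ≤ depth always holds;
* call quality ~ 10^N(3.65, 0.45), strand bias ~ N(0.7, 0.04) clipped to
  [0.5, 1], run metrics from their published normal summaries;
* the FFPE preset injects C>T artifacts at 2 % of susceptible loci at
  VAF 1–3 % — deliberately below the 4 % LoD so the preset does not
  perturb detection statistics;
* drift scenarios shift each variant's truth mean from a 0-based
  changepoint index by a stated multiple of its binomial SD at the
  model's mean depth.

All randomness flows from one integer seed through numpy `SeedSequence`
sub-streams keyed by run/replicate index, so outputs are byte-identical
across invocations and runs are independently regenerable.

What the generator does **not** emulate: PCR amplification bias and
duplicates, context-dependent error spectra, read-level data (FASTQ/BAM),
and the per-variant run-to-run variance of real libraries beyond binomial
sampling.  Passing tests therefore demonstrate correctness of the
statistics under the assumed mechanism, not the assay's wet-lab
performance; the published per-variant SDs are larger than binomial for
several loci, which is precisely why the empirical baseline procedure
exists.

## Verification sizes and statistical tolerances

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen
once: 50 random mixtures × 10⁶ templates for the sampling oracle (each
checked within 3 Monte-Carlo SEs); 100 seeds × 10 runs at 1300× for
baseline recovery (each variant within 3 SE of truth for ≥ 95 % of
cases); 100 null scenarios and 50 drift scenarios for Levey-Jennings
behaviour (false-alarm rate ≤ 1 % per variant-run at the 3SD rule;
≥ 90 % of drift scenarios first reject within one run of the
changepoint); 20 seeds × 10 replicates for the binomial-tail detection
check.  Monitoring simulations are evaluated against control limits set
from the generating process's true parameters — the established-baseline
situation — because limits re-estimated from 10 runs inflate the
false-alarm rate by Student-t widening, which is a property of small
baselines, not of the charting logic.  Equal-mix published cells are
verified at ±0.1 (their printed rounding); derived bounds are unit-tested
to 1e-12 before rounding.
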