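# assayqc

Validation and run-quality-control toolkit for targeted somatic NGS
panels — the desk-side statistics a clinical laboratory needs to validate
an amplicon hotspot assay and keep it in control afterwards.

## What it does

Clinical laboratories validating a hotspot panel (e.g. a 50-gene amplicon
assay on a benchtop sequencer) repeatedly need the same computations:

* **Mixture expectations** (`assayqc.mixtures`).  Characterized cell lines
  carry variants at known allele frequencies f_i; mixing their DNA by mass
  fractions w_i gives an expected variant allele frequency (VAF) per locus

      E[f] = Σ_i w_i·c_i·f_i / Σ_i w_i·c_i

  with copy weight c_i = 0 at a homozygously deleted locus (the line
  contributes no templates there) and 1 otherwise.  Serial dilution "1:k"
  into a normal diluent is the two-component case with mix fraction 1/k;
  germline variants private to the diluent surface in the diluted
  expectation.

* **Limit of detection** (`assayqc.lod`).  Replicate libraries of a
  dilution series are scored against the truth expected at each level; a
  variant counts as detected iff a call matching its key passes the call
  policy (min depth/frequency/quality, max strand bias).  The LoD is the
  lowest expected-VAF level detected at the required rate (default 100 %)
  with all higher levels also meeting it.  Linearity of observed vs
  expected VAF is summarized by Pearson r and an OLS fit.

* **Run-metric cutoffs and Levey-Jennings monitoring** (`assayqc.run_qc`).
  Historical metric values are tested for normality (Shapiro–Wilk, with a
  log10 fallback); acceptance bounds are the classical z-score limits
  x̄ ∓ z·s, back-transformed and rounded per a configurable policy, and
  applied inclusively.  A QC material sequenced over ≥ 10 baseline runs
  yields per-variant mean, SD (n−1), CV and ±2SD/±3SD control limits;
  subsequent runs are banded on a Levey-Jennings chart (in control /
  2SD warning / 3SD reject / missing variant), with opt-in Westgard
  multi-rules (2_2s, R_4s).

* **Concordance and artifact flagging** (`assayqc.concordance`).
  Per-sample sensitivity/specificity against orthogonal single-gene
  assays; Pearson correlation of paired frequency sets (replicates,
  fixation pairs, microdissection pairs); flagging of recurrent artifact
  classes (high-MAF germline SNPs, amplicon-edge calls, homopolymer
  contexts) and blacklist suppression.

* **Synthetic runs** (`assayqc.simulate`).  A seeded generator emulating
  the assumed data-generating process — lognormal per-locus depth,
  binomial alternate-read sampling, log-normal call quality, optional
  FFPE-like low-frequency C>T artifacts and injected run-to-run drift —
  so every stage is testable without sequencing data.

`assayqc.datasets` ships the published characterization tables this
package operationalizes (cell-line profiles, metric summaries, the
55-sample clinical cohort, the recurrent-variant blacklist, QC-material
baseline) as program inputs.

## Worked example

Expected VAFs for an equal four-line FFPE mixture, then a Levey-Jennings
check of a simulated run:

```python
from assayqc import datasets
from assayqc.mixtures import MixtureSpec, mixture_profile, round_expected

profiles = datasets.ffpe_line_profiles()
mix = mixture_profile(profiles, MixtureSpec.equal(datasets.FROZEN_LINE_NAMES))
apc = next(k for k in mix if k.gene == "APC")
print(f"{apc}: expected {round_expected(mix[apc])}%")
```

prints

```
APC_112175770_C>A: expected 74.6%
```

i.e. the APC variant carried at 98.0/72.7/36.5/91.3 % by the four lines
is expected at 74.6 % in the equal mix — the template-weighted mean.

Deriving the published run-acceptance cutoffs from their metric summaries:

```python
from assayqc.run_qc import RoundingPolicy, derive_cutoff_from_summary

rule = derive_cutoff_from_summary(
    "coverage", mean=1231.0, sd=526.0, confidence_pct=95.0,
    side="lower", z=1.96, rounding=RoundingPolicy("integer"))
print(rule.bound_reported)   # 200.0  (= 1231 − 1.96·526, rounded)
```

A coverage of exactly 200 reads passes (bounds are inclusive); the same
call derives the ≥Q20-bases bound 2.0e7, the log10-quality bound 300 and
the strand-bias bound 0.79 from their summaries.

The same computations are scriptable from the shell:

```bash
assayqc expect --profiles profiles.tsv --mix mix.json --out expected.tsv
assayqc cutoffs --samples metrics.tsv --config cutoff_config.json --out rules.json
assayqc run-check --metrics run.json --rules rules.json
assayqc baseline --runs runs/ --truth qc_truth.tsv --out baseline.tsv
assayqc monitor --run todays_run.tsv --baseline baseline.tsv --out lj.tsv
```

## Layout

```
src/assayqc/
  variants_io.py   domain types; VCF/TSV/BED/JSON readers and writers
  mixtures.py      expected-VAF model for mixtures and dilutions
  lod.py           call policy, detection rates, LoD estimator, linearity
  run_qc.py        Shapiro–Wilk gate, z-score cutoffs, baselines, LJ charts
  concordance.py   reference-assay scoring, correlation, artifact rules
  simulate.py      seeded synthetic-run generator
  datasets.py      published characterization tables as inputs
  cli.py           `assayqc` command line
```
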