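"""Concordance with orthogonal assays, frequency correlation, artifacts.

Concordance against single-gene reference assays is scored per *sample*
over the queried gene set: a sample is reference-positive if any queried
gene is positive by the reference assay, and test-positive if the NGS
call set contains any policy-passing call in those genes.  Sensitivity is
100*TP/(TP+FN) percent; specificity 100*TN/(TN+FP).  An ``hgvs_level``
mode additionally requires the coding change to match for a true positive.

Frequency correlation (replicates, fixation pairs, microdissection pairs)
is plain Pearson r over paired VAFs, with variants absent from one set
either zero-filled (default, matching scatter plots that include
near-zero points) or dropped (intersection mode).

Recurrent artifact flagging annotates calls with the classes observed to
recur across unrelated samples: common germline SNPs (high global minor
allele frequency), calls hugging an amplicon boundary, and calls in or
adjacent to reference homopolymer runs (a known error mode of
semiconductor sequencing).  The rules are independent; a call may carry
zero to three classes.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    MissingSampleError,
    UndefinedCorrelationError,
    ValidationError,
)
from .lod import CallPolicy
from .variants_io import Amplicon, VariantCall, VariantKey


# ---------------------------------------------------------------------------
# reference-assay concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceResult:
    """One orthogonal-assay result: a sample's status for one gene."""

    sample_id: str
    gene: str
    status: str  # "positive" | "negative"
    hgvs_c: str = ""

    def __post_init__(self):
        if self.status not in ("positive", "negative"):
            raise ValidationError(f"status must be positive/negative, got {self.status!r}")
        if self.status == "negative" and self.hgvs_c:
            raise ValidationError("negative result cannot carry an hgvs_c change")


class Label(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


@dataclass
class ConcordanceTable:
    """Per-sample concordance labels and the derived aggregates."""

    labels: dict[str, Label]

    def count(self, label: Label) -> int:
        return sum(1 for v in self.labels.values() if v is label)

    @property
    def tp(self) -> int: return self.count(Label.TP)
    @property
    def fp(self) -> int: return self.count(Label.FP)
    @property
    def tn(self) -> int: return self.count(Label.TN)
    @property
    def fn(self) -> int: return self.count(Label.FN)

    @property
    def sensitivity_pct(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity_pct(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")


def _reference_by_sample(reference: Iterable[ReferenceResult], genes: set[str]):
    by_sample: dict[str, list[ReferenceResult]] = {}
    for row in reference:
        by_sample.setdefault(row.sample_id, []).append(row)
    return by_sample


def score_concordance(test: Mapping[str, Sequence[VariantCall]] |
                      Iterable[ReferenceResult],
                      reference: Iterable[ReferenceResult],
                      genes: Iterable[str],
                      mode: str = "gene_level",
                      policy: CallPolicy | None = None) -> ConcordanceTable:
    """Score NGS results against orthogonal single-gene reference results.

    ``test`` is either a mapping of sample id to NGS calls (a sample is
    test-positive iff any call in the queried genes passes ``policy``) or,
    for assay-versus-assay tables, an iterable of per-gene test results in
    the same shape as ``reference``.  ``hgvs_level`` mode requires result
    rows on the test side (calls carry no coding-change nomenclature) and
    counts a TP only when the coding change matches exactly.
    """
    genes = set(genes)
    if not genes:
        raise ValidationError("gene set is empty")
    if mode not in ("gene_level", "hgvs_level"):
        raise ValidationError(f"unknown mode {mode!r}")
    reference = list(reference)
    ref_by_sample = _reference_by_sample(reference, genes)

    if isinstance(test, Mapping):
        if mode == "hgvs_level":
            raise ValidationError(
                "hgvs_level scoring needs test result rows with coding changes"
            )
        policy = policy or CallPolicy()
        missing = set(ref_by_sample) - set(test)
        if missing:
            raise MissingSampleError(missing)
        test_pos = {
            s: any(c.key.gene in genes and policy.passes(c) for c in calls)
            for s, calls in test.items()
        }
        test_hgvs: dict[str, set[tuple[str, str]]] = {}
    else:
        test_rows = list(test)
        test_samples = {r.sample_id for r in test_rows}
        missing = set(ref_by_sample) - test_samples
        if missing:
            raise MissingSampleError(missing)
        test_pos = {s: False for s in test_samples}
        test_hgvs = {s: set() for s in test_samples}
        for r in test_rows:
            if r.gene in genes and r.status == "positive":
                test_pos[r.sample_id] = True
                test_hgvs[r.sample_id].add((r.gene, r.hgvs_c))

    labels: dict[str, Label] = {}
    for sample, rows in ref_by_sample.items():
        ref_positive_rows = [r for r in rows if r.gene in genes and r.status == "positive"]
        ref_pos = bool(ref_positive_rows)
        t_pos = test_pos.get(sample, False)
        if ref_pos and t_pos:
            if mode == "hgvs_level":
                wanted = {(r.gene, r.hgvs_c) for r in ref_positive_rows}
                labels[sample] = Label.TP if wanted & test_hgvs.get(sample, set()) \
                    else Label.FN
            else:
                labels[sample] = Label.TP
        elif ref_pos:
            labels[sample] = Label.FN
        elif t_pos:
            labels[sample] = Label.FP
        else:
            labels[sample] = Label.TN
    return ConcordanceTable(labels=labels)


# ---------------------------------------------------------------------------
# frequency correlation
# ---------------------------------------------------------------------------

def correlate_frequencies(set_a: Sequence[VariantCall],
                          set_b: Sequence[VariantCall],
                          join: str = "union_zero_fill") -> float:
    """Pearson r between two call sets' VAFs.

    ``union_zero_fill`` treats a variant absent from one set as observed
    at 0% (the convention behind replicate scatter plots); ``intersection``
    keeps only shared variants.  Requires >= 3 paired points and non-zero
    variance in both vectors.
    """
    if join not in ("union_zero_fill", "intersection"):
        raise ValidationError(f"unknown join {join!r}")
    a = {c.key: c.observed_pct for c in set_a}
    b = {c.key: c.observed_pct for c in set_b}
    keys = sorted(set(a) | set(b)) if join == "union_zero_fill" else sorted(set(a) & set(b))
    if len(keys) < 3:
        raise InsufficientDataError(f"need >= 3 paired points, got {len(keys)}")
    x = np.array([a.get(k, 0.0) for k in keys])
    y = np.array([b.get(k, 0.0) for k in keys])
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one call set")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# recurrent artifact flagging
# ---------------------------------------------------------------------------

class ArtifactClass(str, enum.Enum):
    HIGH_MAF_SNP = "HIGH_MAF_SNP"
    END_OF_AMPLICON = "END_OF_AMPLICON"
    HOMOPOLYMER = "HOMOPOLYMER"
    OFF_TARGET = "OFF_TARGET"


@dataclass(frozen=True)
class ArtifactAnnotation:
    artifact_class: ArtifactClass
    evidence: str


@dataclass(frozen=True)
class ArtifactConfig:
    """Tunable predicates for the three artifact classes.

    ``maf_threshold`` follows the common-SNP convention (global minor
    allele frequency >= 1%); ``edge_bp`` and ``hp_len`` parameterize the
    amplicon-edge and homopolymer rules.
    """

    maf_threshold: float = 0.01
    edge_bp: int = 5
    hp_len: int = 4


def _homopolymer_runs(context: str) -> list[tuple[int, int, str]]:
    """Maximal single-base runs in a context string as (start, end, base)."""
    runs = []
    i = 0
    while i < len(context):
        j = i
        while j < len(context) and context[j] == context[i]:
            j += 1
        runs.append((i, j, context[i]))
        i = j
    return runs


def flag_artifacts(call: VariantCall,
                   ref_context: str | None = None,
                   amplicons: Sequence[Amplicon] = (),
                   maf_annotations: Mapping[VariantKey, float] | None = None,
                   config: ArtifactConfig | None = None,
                   center: int | None = None) -> list[ArtifactAnnotation]:
    """Annotate one call with any recurrent-artifact classes it matches.

    Parameters
    ----------
    ref_context:
        Reference bases around the call position (default interpretation:
        centered on the position; override with ``center``, a 0-based
        index of the position within the string).  ``None`` disables the
        homopolymer rule.
    amplicons:
        Target regions on the call's chromosome; when none covers the
        position an ``OFF_TARGET`` annotation replaces the edge rule.
    maf_annotations:
        Global minor allele frequencies per variant key; ``None`` disables
        the SNP rule.

    The rules are independent; each contributes at most one annotation.
    """
    config = config or ArtifactConfig()
    annotations: list[ArtifactAnnotation] = []

    if maf_annotations is not None and call.key in maf_annotations:
        maf = maf_annotations[call.key]
        if maf >= config.maf_threshold:
            annotations.append(ArtifactAnnotation(
                ArtifactClass.HIGH_MAF_SNP, f"MAF={maf:g}"
            ))

    if amplicons:
        covering = [a for a in amplicons
                    if a.chrom == call.key.chrom and a.covers(call.key.pos)]
        if not covering:
            annotations.append(ArtifactAnnotation(
                ArtifactClass.OFF_TARGET, "no amplicon covers position"
            ))
        else:
            distances = [a.edge_distance(call.key.pos) for a in covering]
            if all(d <= config.edge_bp for d in distances):
                annotations.append(ArtifactAnnotation(
                    ArtifactClass.END_OF_AMPLICON,
                    f"edge distance {min(distances)} bp",
                ))

    if ref_context:
        c = len(ref_context) // 2 if center is None else center
        for start, end, base in _homopolymer_runs(ref_context.upper()):
            if end - start >= config.hp_len and start - 1 <= c <= end:
                annotations.append(ArtifactAnnotation(
                    ArtifactClass.HOMOPOLYMER,
                    f"{base}-run length {end - start}",
                ))
                break

    return annotations


# ---------------------------------------------------------------------------
# blacklist
# ---------------------------------------------------------------------------

_BLACKLIST_PREFIX = "blacklist"


def apply_blacklist(calls: Sequence[VariantCall],
                    blacklist: Mapping[VariantKey, str] |
                    Iterable[tuple[VariantKey, str]]) -> list[VariantCall]:
    """Annotate calls matching a recurrent-variant blacklist.

    Matching is by exact variant key (same position with a different alt
    allele does not match).  Flagged calls retain all their data; use
    :func:`reportable_calls` for the suppressed view.
    """
    if not isinstance(blacklist, Mapping):
        blacklist = dict(blacklist)
    out = []
    for call in calls:
        if call.key in blacklist:
            flagged = dataclasses.replace(
                call,
                filters=set(call.filters) | {f"{_BLACKLIST_PREFIX}:{blacklist[call.key]}"},
            )
            out.append(flagged)
        else:
            out.append(call)
    return out


def reportable_calls(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Calls not suppressed by a blacklist flag."""
    return [c for c in calls
            if not any(f.startswith(_BLACKLIST_PREFIX + ":") for f in c.filters)]
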