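"""Domain types and file I/O for the assay-QC pipeline.

The internal conventions, enforced once at this boundary:

* genomic coordinates are 1-based (hg19-style positions as printed in
  clinical reports); BED input (0-based half-open) is converted on read;
* allele frequencies are carried in **percent** (0-100) end to end; VCF
  fractional ``AF`` values are converted on read and back on write;
* deletions are stored VCF-style (anchored reference allele, shorter alt);
* strand bias is the larger per-strand alt-read proportion, in [0.5, 1].

Supported formats: a VCF 4.2 subset (via pysam), tab-delimited call and
genotype tables with a header row and ``.`` for missing values, BED target
regions, and a JSON schema for derived cutoff rules.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .exceptions import DialectError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

#: Numeric precision retained for frequencies/qualities when round-tripping
#: through text formats; chosen so VCF float32 storage is lossless for
#: values printed with up to four decimals.
_TEXT_DECIMALS = 6


class VariantType(str, enum.Enum):
    SNV = "SNV"
    MNV = "MNV"
    INS = "INS"
    DEL = "DEL"


def classify_alleles(ref: str, alt: str) -> VariantType:
    """Infer the variant type from REF/ALT allele lengths."""
    if len(ref) == len(alt):
        return VariantType.SNV if len(ref) == 1 else VariantType.MNV
    return VariantType.DEL if len(ref) > len(alt) else VariantType.INS


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: locus, alleles and the gene it falls in."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    vtype: VariantType = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ACGT:
                raise ValidationError(f"{name} allele {allele!r} is not ACGT")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        inferred = classify_alleles(self.ref, self.alt)
        if self.vtype is None:
            object.__setattr__(self, "vtype", inferred)
        elif VariantType(self.vtype) is not inferred:
            raise ValidationError(
                f"vtype {self.vtype} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {inferred.value})"
            )

    def __str__(self) -> str:
        return f"{self.gene or self.chrom}_{self.pos}_{self.ref}>{self.alt}"


@dataclass
class VariantCall:
    """One observed variant call with its quality annotations.

    ``observed_pct`` is the variant allele frequency in percent.  When both
    ``alt_depth`` and ``depth`` are present they must agree with the stated
    frequency to within 0.05 percentage points.
    """

    key: VariantKey
    observed_pct: float
    depth: int
    alt_depth: int | None = None
    quality: float = 0.0
    strand_bias: float = 0.5
    filters: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not 0.0 <= self.observed_pct <= 100.0:
            raise ValidationError(f"observed_pct {self.observed_pct} outside [0, 100]")
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")
        if self.quality < 0:
            raise ValidationError("quality must be non-negative")
        if not 0.5 <= self.strand_bias <= 1.0:
            raise ValidationError(f"strand_bias {self.strand_bias} outside [0.5, 1]")
        if self.alt_depth is not None:
            if self.alt_depth > self.depth:
                raise ValidationError("alt_depth exceeds depth")
            if self.depth > 0:
                implied = 100.0 * self.alt_depth / self.depth
                if abs(self.observed_pct - implied) > 0.05:
                    raise ValidationError(
                        f"observed_pct {self.observed_pct} inconsistent with "
                        f"{self.alt_depth}/{self.depth} reads ({implied:.3f}%)"
                    )


@dataclass
class RunMetrics:
    """Summary metrics for one sequencing run."""

    run_id: str
    mean_depth: float
    q20_bases: int
    reads_on_target_pct: float
    uniformity_pct: float

    def __post_init__(self):
        for name in ("reads_on_target_pct", "uniformity_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} {v} outside [0, 100]")
        if self.mean_depth < 0 or self.q20_bases < 0:
            raise ValidationError("counts must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "coverage": self.mean_depth,
            "q20_bases": self.q20_bases,
            "reads_on_target_pct": self.reads_on_target_pct,
            "uniformity_pct": self.uniformity_pct,
        }


@dataclass(frozen=True, order=True)
class Amplicon:
    """A target region, stored 0-based half-open as in BED."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) for {self.name or self.chrom}"
            )

    def covers(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end

    def edge_distance(self, pos_1based: int) -> int:
        """Distance (bp) from a covered 1-based position to the nearer edge."""
        return min(pos_1based - (self.start + 1), self.end - pos_1based)


# ---------------------------------------------------------------------------
# call tables (TSV dialect)
# ---------------------------------------------------------------------------

_CALL_COLUMNS = (
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "freq_pct",
    "depth",
    "quality",
    "alt_depth",
    "strand_bias",
    "filters",
)
# canonical order for headerless files (spec'd input column order)
_HEADERLESS = ("chrom", "pos", "ref", "alt", "gene", "freq_pct", "depth",
               "quality", "alt_depth", "strand_bias")

_MISSING = {"", ".", "NA", "N.A.", "NaN"}


def _opt(value: str, cast, default=None):
    return default if value in _MISSING else cast(value)


def read_calls(path, dialect: str = "tsv") -> dict[str, list[VariantCall]]:
    """Read variant calls, grouped by sample name.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"tsv"`` for the tab-delimited call table (header row naming any
        of ``sample chrom pos ref alt gene freq_pct depth quality alt_depth
        strand_bias filters``; headerless files are accepted in that order
        minus ``sample``/``filters``), or ``"vcf"`` for the VCF 4.2 subset
        (requires ``AF`` and ``DP``; ``AO``, ``SB`` and ``GENE`` optional).

    Returns
    -------
    dict mapping sample id to its list of calls, one call per ALT allele
    (multi-allelic VCF records are split).  Samples default to the file
    stem when the input carries no sample labels.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_calls_tsv(path)
    if dialect == "vcf":
        return _read_calls_vcf(path)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _read_calls_tsv(path: Path) -> dict[str, list[VariantCall]]:
    groups: dict[str, list[VariantCall]] = {}
    default_sample = path.stem
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        logger.warning("empty call table %s", path)
        return {}
    header = lines[0].rstrip("\n").split("\t")
    if "pos" in header and "chrom" in header:
        columns = header
        body_start = 1
    else:
        columns = list(_HEADERLESS)
        body_start = 0
    idx = {c: i for i, c in enumerate(columns)}
    for col in ("chrom", "pos", "ref", "alt", "freq_pct", "depth"):
        if col not in idx:
            raise DialectError(f"call table lacks required column {col!r}", path)
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < len([c for c in ("chrom", "pos", "ref", "alt", "freq_pct", "depth") ]):
            raise ParseError("too few fields", path, lineno)

        def get(col, default=""):
            i = idx.get(col)
            return f[i].strip() if i is not None and i < len(f) else default

        try:
            key = VariantKey(
                chrom=get("chrom"),
                pos=int(get("pos")),
                ref=get("ref").upper(),
                alt=get("alt").upper(),
                gene=get("gene"),
            )
            call = VariantCall(
                key=key,
                observed_pct=float(get("freq_pct")),
                depth=int(get("depth")),
                alt_depth=_opt(get("alt_depth", "."), int),
                quality=_opt(get("quality", "."), float, 0.0),
                strand_bias=_opt(get("strand_bias", "."), float, 0.5),
                filters=set() if get("filters", ".") in _MISSING
                else set(filter(None, get("filters").split(","))),
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"malformed call record: {exc}", path, lineno) from exc
        groups.setdefault(get("sample") or default_sample, []).append(call)
    return groups


def write_calls(groups: Mapping[str, Sequence[VariantCall]] | Sequence[VariantCall],
                path, dialect: str = "tsv") -> None:
    """Write calls in the chosen dialect; inverse of :func:`read_calls`."""
    path = Path(path)
    if not isinstance(groups, Mapping):
        groups = {path.stem: list(groups)}
    if dialect == "tsv":
        _write_calls_tsv(groups, path)
    elif dialect == "vcf":
        _write_calls_vcf(groups, path)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def _fmt(x: float) -> str:
    return format(round(float(x), _TEXT_DECIMALS), "g")


def _write_calls_tsv(groups: Mapping[str, Sequence[VariantCall]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for sample in groups:
            for c in groups[sample]:
                row = [
                    sample, c.key.chrom, str(c.key.pos), c.key.ref, c.key.alt,
                    c.key.gene, _fmt(c.observed_pct), str(c.depth), _fmt(c.quality),
                    "." if c.alt_depth is None else str(c.alt_depth),
                    _fmt(c.strand_bias), ",".join(sorted(c.filters)) or ".",
                ]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

def _vcf_header(groups: Mapping[str, Sequence[VariantCall]]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    header.add_line('##INFO=<ID=AO,Number=A,Type=Integer,Description="Alt-supporting reads">')
    header.add_line('##INFO=<ID=SB,Number=1,Type=Float,Description="Max-strand alt proportion">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC symbol">')
    header.add_line('##FILTER=<ID=FLAGGED,Description="Carries assayqc flags">')
    chroms = sorted({c.key.chrom for calls in groups.values() for c in calls})
    for chrom in chroms:
        header.contigs.add(chrom)
    return header

def _write_calls_vcf(groups: Mapping[str, Sequence[VariantCall]], path: Path) -> None:
    if len(groups) > 1:
        raise ValidationError("VCF subset writes one sample per file")
    header = _vcf_header(groups)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for calls in groups.values():
            for c in sorted(calls, key=lambda c: (c.key.chrom, c.key.pos, c.key.alt)):
                rec = vcf.new_record(
                    contig=c.key.chrom, start=c.key.pos - 1,
                    alleles=(c.key.ref, c.key.alt),
                )
                rec.info["AF"] = c.observed_pct / 100.0
                rec.info["DP"] = c.depth
                if c.alt_depth is not None:
                    rec.info["AO"] = c.alt_depth
                rec.info["SB"] = c.strand_bias
                if c.key.gene:
                    rec.info["GENE"] = c.key.gene
                rec.qual = c.quality
                vcf.write(rec)


def _read_calls_vcf(path: Path) -> dict[str, list[VariantCall]]:
    sample = path.stem.removesuffix(".vcf")
    calls: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot open VCF: {exc}", path) from exc
    with vcf:
        if list(vcf.header.samples):
            sample = list(vcf.header.samples)[0]
        for rec in vcf:
            if "AF" not in rec.info or "DP" not in rec.info:
                raise DialectError(
                    "VCF dialect requires AF and DP INFO fields", path, rec.pos
                )
            afs = rec.info["AF"]
            if not isinstance(afs, tuple):
                afs = (afs,)
            aos = rec.info["AO"] if "AO" in rec.info else None
            if aos is not None and not isinstance(aos, tuple):
                aos = (aos,)
            for i, alt in enumerate(rec.alts or ()):
                key = VariantKey(
                    chrom=rec.contig, pos=rec.pos, ref=rec.ref.upper(),
                    alt=str(alt).upper(),
                    gene=rec.info["GENE"] if "GENE" in rec.info else "",
                )
                calls.append(VariantCall(
                    key=key,
                    observed_pct=round(100.0 * float(afs[i]), _TEXT_DECIMALS),
                    depth=int(rec.info["DP"]),
                    alt_depth=None if aos is None else int(aos[i]),
                    quality=0.0 if rec.qual is None else round(rec.qual, _TEXT_DECIMALS),
                    strand_bias=round(float(rec.info["SB"]), _TEXT_DECIMALS)
                    if "SB" in rec.info else 0.5,
                    filters=set(rec.filter.keys()) - {"PASS"},
                ))
    if not calls:
        logger.warning("empty VCF %s", path)
        return {}
    return {sample: calls}


# ---------------------------------------------------------------------------
# genotype (cell line profile) tables
# ---------------------------------------------------------------------------

def read_line_profiles(path) -> dict[str, "LineProfile"]:
    """Read per-cell-line genotype tables into :class:`~assayqc.mixtures.LineProfile`.

    Required columns: ``line chrom pos ref alt gene freq_pct copy_state``.
    ``N.A.``/``.`` frequency means 0% at normal copy state.  A
    ``hom_deletion`` row must not carry a frequency (no templates exist).
    """
    from .mixtures import CopyState, LineProfile, LocusGenotype

    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return {}
    header = lines[0].split("\t")
    idx = {c: i for i, c in enumerate(header)}
    required = ("line", "chrom", "pos", "ref", "alt", "gene", "freq_pct", "copy_state")
    for col in required:
        if col not in idx:
            raise DialectError(f"profile table lacks column {col!r}", path)
    entries: dict[str, dict] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        name = f[idx["line"]]
        key = VariantKey(
            chrom=f[idx["chrom"]], pos=int(f[idx["pos"]]),
            ref=f[idx["ref"]].upper(), alt=f[idx["alt"]].upper(),
            gene=f[idx["gene"]],
        )
        raw_freq = f[idx["freq_pct"]].strip()
        raw_state = f[idx["copy_state"]].strip() or "normal"
        try:
            state = CopyState(raw_state)
        except ValueError:
            raise ValidationError(
                f"unknown copy_state {raw_state!r} at {path}:{lineno}"
            ) from None
        freq = _opt(raw_freq, float, None)
        if state is CopyState.HOM_DELETION:
            if freq is not None and freq != 0.0:
                raise ValidationError(
                    f"hom_deletion locus carries frequency {freq} at {path}:{lineno}"
                )
            geno = LocusGenotype(0.0, state)
        else:
            freq = 0.0 if freq is None else freq
            if not 0.0 <= freq <= 100.0:
                raise ValidationError(f"freq {freq} outside [0,100] at {path}:{lineno}")
            geno = LocusGenotype(freq, state)
        bucket = entries.setdefault(name, {})
        if key in bucket:
            raise ValidationError(f"duplicate locus {key} for line {name} at {path}:{lineno}")
        bucket[key] = geno
    return {name: LineProfile(name, genos) for name, genos in entries.items()}


def write_line_profiles(profiles: Mapping[str, "LineProfile"], path) -> None:
    with open(path, "w") as fh:
        fh.write("line\tchrom\tpos\tref\talt\tgene\tfreq_pct\tcopy_state\n")
        for name in profiles:
            prof = profiles[name]
            for key in sorted(prof.entries):
                g = prof.entries[key]
                freq = "." if g.copy_state.value == "hom_deletion" else _fmt(g.freq_pct)
                fh.write("\t".join([
                    name, key.chrom, str(key.pos), key.ref, key.alt, key.gene,
                    freq, g.copy_state.value,
                ]) + "\n")


# ---------------------------------------------------------------------------
# BED amplicons
# ---------------------------------------------------------------------------

def read_amplicons(path) -> list[Amplicon]:
    """Read a 3+ column BED of amplicon targets, sorted per chromosome.

    ``track``/``browser``/``#`` header lines are skipped; overlapping
    amplicons are permitted and preserved.
    """
    amplicons = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            f = s.split("\t") if "\t" in s else s.split()
            if len(f) < 3:
                raise ParseError("BED line has fewer than 3 columns", path, lineno)
            try:
                amp = Amplicon(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    name=f[3] if len(f) > 3 else "",
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"malformed BED record: {exc}", path, lineno) from exc
            amplicons.append(amp)
    return sorted(amplicons)


def write_amplicons(amplicons: Iterable[Amplicon], path) -> None:
    with open(path, "w") as fh:
        for a in sorted(amplicons):
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")


# ---------------------------------------------------------------------------
# cutoff rule JSON
# ---------------------------------------------------------------------------

def write_cutoff_json(rules: Sequence["CutoffRule"], path) -> None:
    """Serialize derived cutoff rules to JSON with a stable key order."""
    from .run_qc import CutoffRule  # noqa: F401  (type reference)

    payload = []
    for r in rules:
        payload.append({
            "metric": r.metric_name,
            "transform": r.transform,
            "side": r.side,
            "confidence_pct": r.confidence_pct,
            "z": r.z,
            "mean": r.mean,
            "sd": r.sd,
            "bound_raw": r.bound_raw,
            "bound_reported": r.bound_reported,
            "rounding": {"kind": r.rounding.kind, "digits": r.rounding.digits},
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_cutoff_json(path) -> list["CutoffRule"]:
    from .run_qc import CutoffRule, RoundingPolicy

    with open(path) as fh:
        payload = json.load(fh)
    rules = []
    for item in payload:
        rules.append(CutoffRule(
            metric_name=item["metric"],
            transform=item["transform"],
            side=item["side"],
            confidence_pct=item["confidence_pct"],
            z=item["z"],
            mean=item["mean"],
            sd=item["sd"],
            bound_raw=item["bound_raw"],
            bound_reported=item["bound_reported"],
            rounding=RoundingPolicy(item["rounding"]["kind"], item["rounding"]["digits"]),
        ))
    return rules
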