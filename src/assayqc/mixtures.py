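"""Expected variant allele frequencies for cell-line mixtures and dilutions.

A characterized cell line *i* carries, at a given locus, a variant allele
frequency ``f_i`` (percent) and a copy state.  When lines are combined by
DNA mass fractions ``w_i``, the expected VAF of the mixture at that locus is
the template-weighted mean

    E[f] = sum_i(w_i * c_i * f_i) / sum_i(w_i * c_i)

where the copy weight ``c_i`` is 1 for a copy-neutral locus and 0 for a
homozygous deletion (the line contributes no DNA templates there, so its
mass drops out of the denominator).  With all loci copy-neutral this
reduces to the plain w-weighted mean with absent variants counted at 0%.

A serial dilution "1:k" of a mixture into a diluent (e.g. normal placental
DNA) is the two-component special case with mix fraction 1/k; germline
variants private to the diluent are first-class loci and surface in the
diluted expectation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import NoTemplateError, ValidationError
from .variants_io import VariantKey

_W_TOL = 1e-9


class CopyState(str, enum.Enum):
    NORMAL = "normal"
    HOM_DELETION = "hom_deletion"


@dataclass(frozen=True)
class LocusGenotype:
    """Per-locus state of one line: VAF in percent and copy state."""

    freq_pct: float
    copy_state: CopyState = CopyState.NORMAL

    def __post_init__(self):
        if self.copy_state is CopyState.HOM_DELETION:
            if self.freq_pct != 0.0:
                raise ValidationError("hom_deletion locus cannot carry a frequency")
        elif not 0.0 <= self.freq_pct <= 100.0:
            raise ValidationError(f"freq_pct {self.freq_pct} outside [0, 100]")

    @property
    def copy_weight(self) -> float:
        return 0.0 if self.copy_state is CopyState.HOM_DELETION else 1.0


@dataclass
class LineProfile:
    """A cell line's per-locus genotypes.

    Loci absent from ``entries`` are implicitly frequency 0 at normal copy
    state (the line contributes reference templates there).
    """

    line_name: str
    entries: dict[VariantKey, LocusGenotype] = field(default_factory=dict)

    def genotype(self, key: VariantKey) -> LocusGenotype:
        return self.entries.get(key, LocusGenotype(0.0, CopyState.NORMAL))

    def loci(self) -> set[VariantKey]:
        return set(self.entries)


@dataclass
class MixtureSpec:
    """Ordered list of (line_name, mass_fraction); fractions sum to 1."""

    components: Sequence[tuple[str, float]]

    def __post_init__(self):
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate component names in mixture")
        for name, w in self.components:
            if not 0.0 < w <= 1.0:
                raise ValidationError(f"mass fraction {w} for {name} outside (0, 1]")
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > _W_TOL:
            raise ValidationError(f"mass fractions sum to {total}, expected 1")

    @classmethod
    def equal(cls, names: Sequence[str]) -> "MixtureSpec":
        return cls([(n, 1.0 / len(names)) for n in names])


@dataclass
class ExpectedProfile:
    """Expected VAF (percent) per locus for a mixture."""

    values: dict[VariantKey, float] = field(default_factory=dict)

    def __post_init__(self):
        for key, v in self.values.items():
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"expected VAF {v} outside [0, 100] at {key}")

    def __getitem__(self, key: VariantKey) -> float:
        return self.values[key]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()

    def get(self, key, default=None):
        return self.values.get(key, default)


def _resolve(profiles: Mapping[str, LineProfile] | Iterable[LineProfile],
             spec: MixtureSpec) -> list[tuple[LineProfile, float]]:
    if not isinstance(profiles, Mapping):
        profiles = {p.line_name: p for p in profiles}
    resolved = []
    for name, w in spec.components:
        if name not in profiles:
            raise ValidationError(f"no profile for mixture component {name!r}")
        resolved.append((profiles[name], w))
    return resolved


def expected_vaf(key: VariantKey,
                 profiles: Mapping[str, LineProfile] | Iterable[LineProfile],
                 spec: MixtureSpec) -> float:
    """Expected VAF (percent) of one locus in a mixture.

    Raises :class:`NoTemplateError` when every component is homozygously
    deleted at the locus (no DNA templates exist to sequence).
    """
    components = _resolve(profiles, spec)
    num = 0.0
    den = 0.0
    for prof, w in components:
        g = prof.genotype(key)
        num += w * g.copy_weight * g.freq_pct
        den += w * g.copy_weight
    if den <= 0.0:
        raise NoTemplateError(f"all mixture components deleted at {key}")
    return num / den


def mixture_profile(profiles: Mapping[str, LineProfile] | Iterable[LineProfile],
                    spec: MixtureSpec) -> ExpectedProfile:
    """Expected VAFs over the union of loci across all components.

    Loci where every template-contributing component has frequency 0 are
    kept with an expectation of 0 (they are informative negatives).
    """
    components = _resolve(profiles, spec)
    union: set[VariantKey] = set()
    for prof, _ in components:
        union |= prof.loci()
    lookup = {prof.line_name: prof for prof, _ in components}
    return ExpectedProfile({
        key: expected_vaf(key, lookup, spec) for key in sorted(union)
    })


def serial_dilute(profile: ExpectedProfile, diluent: LineProfile,
                  mix_fraction: float) -> ExpectedProfile:
    """Dilute a mixture expectation into a diluent line.

    ``mix_fraction`` is the mass fraction of the original mixture in the
    final sample; a "1:k" dilution corresponds to ``mix_fraction = 1/k``.
    Equivalent to a two-component mixture of the profile (copy-neutral
    pseudo-component) at ``w = mix_fraction`` and the diluent at ``1 - w``,
    so diluent homozygous deletions and diluent-private germline variants
    are both handled.
    """
    if not 0.0 < mix_fraction <= 1.0:
        raise ValidationError(f"mix_fraction {mix_fraction} outside (0, 1]")
    w = mix_fraction
    out: dict[VariantKey, float] = {}
    for key in sorted(set(profile.values) | diluent.loci()):
        g = diluent.genotype(key)
        num = w * profile.get(key, 0.0) + (1.0 - w) * g.copy_weight * g.freq_pct
        den = w + (1.0 - w) * g.copy_weight
        # den >= w > 0 always: the diluted mixture itself contributes templates
        out[key] = num / den
    return ExpectedProfile(out)


def round_expected(value_pct: float, decimals: int = 1) -> float:
    """Round an expectation for reporting (round-half-to-even, 1 decimal)."""
    return round(value_pct, decimals)
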