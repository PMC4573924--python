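"""Exception hierarchy for assayqc.

Every error raised on purpose by the package derives from
:class:`AssayQCError`, so callers can catch one base class at pipeline
boundaries while tests can assert the precise failure mode.
"""


class AssayQCError(Exception):
    """Base class for all assayqc errors."""


class ValidationError(AssayQCError, ValueError):
    """An input value violates a documented domain invariant."""


class ParseError(AssayQCError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class DialectError(ParseError):
    """The file parses but lacks fields the named dialect requires."""


class NoTemplateError(AssayQCError):
    """Every mixture component contributes zero DNA templates at a locus."""


class InsufficientDataError(AssayQCError):
    """Fewer data points than the operation can meaningfully use."""


class UndefinedCorrelationError(AssayQCError):
    """Pearson correlation requested on a zero-variance vector."""


class DegenerateSampleError(AssayQCError):
    """A statistical test was handed a constant (zero-variance) sample."""


class NoUsableTransformError(AssayQCError):
    """Normality rejected on the identity and log10 scales alike."""


class InsufficientBaselineError(AssayQCError):
    """Fewer usable QC-material runs than the configured minimum."""


class MissingSampleError(AssayQCError):
    """Reference samples with no corresponding test call set."""

    def __init__(self, sample_ids):
        self.sample_ids = sorted(sample_ids)
        super().__init__(
            "reference samples missing from test set: " + ", ".join(self.sample_ids)
        )
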