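"""Exception hierarchy for ppskit.

Everything raised on purpose by the package derives from :class:`PpskitError`
so callers (and the CLI) can catch one type.
"""


class PpskitError(Exception):
    """Base class for all ppskit errors."""


class FormatError(PpskitError):
    """A file or cell could not be parsed in the expected dialect."""


class ValidationError(PpskitError):
    """Parsed data violates a structural invariant (duplicates, misalignment)."""


class EmptyPanelError(PpskitError):
    """A filtering step removed every SNP; the derivation cannot proceed."""


class SizeError(PpskitError):
    """An input is too small, or two inputs have mismatched lengths."""


class StateError(PpskitError):
    """An operation was called before a prerequisite stage produced its labels."""


class DegenerateLabelsError(PpskitError):
    """A classification metric was requested with only one class present."""


class ScoringError(PpskitError):
    """A model references SNPs absent from the genotype matrix being scored."""
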