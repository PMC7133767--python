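"""Exception hierarchy for mr2s."""


class MrError(Exception):
    """Base class for all mr2s errors."""


class FormatError(MrError):
    """An input table is malformed (e.g. a required column is missing)."""


class ValidationError(MrError):
    """A value violates a domain invariant (non-positive SE, inverted CI, ...)."""


class InsufficientInstrumentsError(MrError):
    """An estimator was called with fewer SNPs than it requires."""


class UndefinedRatioError(MrError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""
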