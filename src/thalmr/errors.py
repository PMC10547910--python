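"""Exception hierarchy shared across the pipeline stages."""


class ThalmrError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(ThalmrError):
    """Invalid configuration; the message names the offending field."""


class DomainError(ThalmrError, ValueError):
    """Input outside the mathematical domain of an operation."""


class NonEstimableError(ThalmrError):
    """A regression that cannot be fit (constant predictor, single-class outcome, rank deficiency)."""


class UndefinedLDError(ThalmrError):
    """Linkage disequilibrium undefined, e.g. a monomorphic locus."""


class SampleMismatchError(ThalmrError):
    """Genotype and phenotype files do not share the same sample IDs."""
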