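"""Exception hierarchy shared across the pipeline stages."""


class DuogenieError(Exception):
    """Base class for all package errors."""


class FormatError(DuogenieError):
    """A file is missing a required column or is otherwise malformed."""


class ParseError(DuogenieError):
    """A field could not be parsed; carries the offending line number."""


class ValidationError(DuogenieError):
    """A record violates a field invariant (se <= 0, eaf outside [0,1], ...)."""


class IntegrityError(DuogenieError):
    """Duplicate keys or mixed groups where a unique key was required."""


class EmptyJoinError(DuogenieError):
    """An instrument/outcome join produced zero overlapping SNPs."""


class AlleleMismatchError(DuogenieError):
    """Allele sets of two records for the same SNP cannot be reconciled."""


class UnresolvableAlleleError(DuogenieError):
    """A palindromic SNP cannot be oriented (missing or ambiguous frequency)."""


class HarmonizationRequiredError(DuogenieError):
    """Two summary tables disagree on the effect allele for a SNP."""


class PropagationError(DuogenieError):
    """Variance propagation produced a non-positive variance."""


class DegenerateInputError(DuogenieError):
    """Constant vector, zero-variance outcome or degenerate design matrix."""


class InsufficientInputError(DuogenieError):
    """Fewer inputs than the estimator requires (k < 2 for pooling, ...)."""


class ConfigError(DuogenieError):
    """Invalid generator or pipeline configuration."""
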