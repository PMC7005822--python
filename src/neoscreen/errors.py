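"""Exception hierarchy shared across the pipeline.

Every error raised on a user-facing path derives from :class:`NeoscreenError`
so callers (and the CLI) can map failure classes to exit codes.
"""


class NeoscreenError(Exception):
    """Base class for all neoscreen errors."""


class FormatError(NeoscreenError):
    """A file is structurally malformed (bad FASTA/VCF/TSV layout)."""


class ValidationError(NeoscreenError):
    """A record violates a domain invariant (bad base, negative count, ...)."""


class ReferenceMismatchError(ValidationError):
    """A variant's stated reference base disagrees with the sequence."""


class DuplicateKeyError(ValidationError):
    """A table contains conflicting entries for the same key."""


class ConsistencyError(NeoscreenError):
    """Two inputs that must be keyed to the same records are not."""


class ConfigError(NeoscreenError):
    """A configuration value is outside its documented range."""


class CapacityError(NeoscreenError):
    """A generator was asked for more items than the input can supply."""


class MissingPredictionError(NeoscreenError):
    """No affinity is available for a (peptide, allele) pair."""
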