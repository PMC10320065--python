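"""Exception hierarchy shared across the package.

All errors raised by kmersieve derive from :class:`KmerSieveError`, so callers
(and the CLI) can distinguish data/usage problems from genuine bugs.
"""


class KmerSieveError(Exception):
    """Base class for all kmersieve errors."""


class TaxonomyError(KmerSieveError):
    """Structural or lookup problem in a taxonomy tree."""


class IndexCompatibilityError(KmerSieveError):
    """A k-mer index does not match the taxonomy (or configuration) in use."""


class IndexFormatError(KmerSieveError):
    """An index file is corrupt or not a kmersieve index."""


class SequenceFormatError(KmerSieveError):
    """Malformed FASTA/FASTQ input or an impossible output conversion."""


class PairingError(KmerSieveError):
    """Paired read streams disagree in length or identity."""


class ParseError(KmerSieveError):
    """A per-read classification line could not be parsed."""


class UndefinedScoreError(KmerSieveError):
    """A score was requested for a read with zero possible k-mer windows."""


class ConfigError(KmerSieveError):
    """Invalid configuration (thresholds, mixtures, k mismatches...)."""
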