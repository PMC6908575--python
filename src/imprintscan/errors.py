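"""Exception hierarchy.

Exit-code mapping used by the CLI: usage/configuration problems exit 2,
data/parse problems exit 3.
"""


class ImprintscanError(Exception):
    """Base class for all package errors."""


class ConfigError(ImprintscanError, ValueError):
    """Invalid configuration (bad proportions, identical SNP alleles...)."""


class UsageError(ImprintscanError, ValueError):
    """Operation invoked with missing or inconsistent inputs."""


class DataError(ImprintscanError, ValueError):
    """Inconsistent input data (duplicate pairings, unknown species...)."""


class ParseError(ImprintscanError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class MendelianInconsistencyError(DataError):
    """Offspring allele absent from both parental genotypes."""


class ReadRejectedError(ImprintscanError, ValueError):
    """A read was rejected before or during alignment; carries the reason."""
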