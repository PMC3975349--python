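"""Exception hierarchy.

All package errors derive from :class:`PseaacError` so callers can catch
one base class at the CLI boundary.
"""

from __future__ import annotations


class PseaacError(Exception):
    """Base class for all package errors."""


class FastaParseError(PseaacError):
    """Structurally malformed FASTA input (e.g. sequence data before any header)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SequenceValidationError(PseaacError):
    """A sequence contains characters outside the canonical alphabet."""

    def __init__(self, record_id: str, bad_char: str):
        self.record_id = record_id
        self.bad_char = bad_char
        super().__init__(
            f"record {record_id!r}: non-canonical residue {bad_char!r} "
            "(ambiguity policy is 'error')"
        )


class FormatError(PseaacError):
    """A tabular side-input file violates its format contract."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegeneratePropertyError(PseaacError):
    """A physicochemical property is constant over the 20 amino acids and
    cannot be standardized (zero variance)."""


class DegenerateNormalizationError(PseaacError):
    """The pseudo-composition denominator is not positive (possible for
    amphiphilic correlation factors, which may be negative)."""

    def __init__(self, tau_sum: float):
        self.tau_sum = tau_sum
        super().__init__(
            f"non-positive normalization denominator: 1 + w*sum(tau) with "
            f"sum(tau) = {tau_sum:g}; choose a smaller weight w"
        )


class SequenceLengthError(PseaacError):
    """Sequence too short for the requested descriptor parameters."""

    def __init__(self, record_id: str, length: int, minimum: int, why: str):
        self.record_id = record_id
        self.length = length
        self.minimum = minimum
        super().__init__(
            f"record {record_id!r}: length {length} < required minimum "
            f"{minimum} ({why})"
        )


class LagError(PseaacError):
    """Autocorrelation / coupling lag is not smaller than the sequence length."""


class ArgumentError(PseaacError):
    """Invalid argument value outside any file-format context."""


class PluginContractError(PseaacError):
    """A user plugin does not satisfy the mode contract."""


class ConfigurationError(PseaacError):
    """Invalid registry or run configuration (duplicate mode names, missing
    side inputs, unknown parameters...)."""
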