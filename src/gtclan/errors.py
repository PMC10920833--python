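"""Exception hierarchy shared across the package.

Every command-line entry point catches :class:`GtclanError` and maps it to a
single-line ``error-class: message`` report on stderr with a nonzero exit.
"""


class GtclanError(Exception):
    """Base class for all package errors."""

    #: short machine-parseable class tag used by the CLI
    tag = "error"


class InputError(GtclanError):
    tag = "input-error"


class ConfigurationError(GtclanError):
    tag = "configuration-error"


class GlycanParseError(InputError):
    """Malformed glycan string; carries the 0-based character position."""

    tag = "parse-error"

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownResidueError(InputError):
    tag = "unknown-residue-error"


class StructuralError(InputError):
    """Bond list does not form the required tree / path structure."""

    tag = "structural-error"


class StereoTableError(InputError):
    """A (sugar, carbon) pair has no entry in the stereochemistry table."""

    tag = "stereo-table-error"


class UnsupportedInputError(InputError):
    """Input outside the supported range (e.g. single-residue backbones)."""

    tag = "unsupported-input-error"


class UndeterminedMechanismError(InputError):
    """Reaction stereochemistry cannot be inferred (open-chain reducing end)."""

    tag = "undetermined-mechanism-error"


class DegenerateInputError(InputError):
    tag = "degenerate-input-error"
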