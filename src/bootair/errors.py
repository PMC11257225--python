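"""Exception hierarchy shared across the package.

Exit-code contract for the CLI: format errors map to exit code 2,
parameter errors to exit code 3.
"""


class BootairError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BootairError):
    """Malformed or inconsistent input data (files, channel lengths, schemas)."""


class ParameterError(BootairError):
    """An argument outside its admissible range."""


class UndefinedScoreError(BootairError):
    """A score was requested for an empty ground-truth set."""
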