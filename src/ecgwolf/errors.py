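"""Exception types shared across the package."""


class EcgWolfError(Exception):
    """Base class for package errors."""


class FormatError(EcgWolfError):
    """A file could not be parsed as the expected on-disk format."""


class SchemaError(EcgWolfError):
    """A tabular input is missing required columns or has a bad layout."""


class ParseError(EcgWolfError):
    """A cell or token inside an otherwise well-formed file is invalid."""


class DegenerateInputError(EcgWolfError, ValueError):
    """Input is formally valid but mathematically degenerate (e.g. constant)."""


class TrainingError(EcgWolfError):
    """Model training diverged or could not proceed."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
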