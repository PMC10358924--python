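"""Exception hierarchy shared across the pipeline stages."""


class BrainwalkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BrainwalkError, ValueError):
    """Invalid or inconsistent configuration (e.g. non-integer decimation)."""


class TruncationError(BrainwalkError, ValueError):
    """An epoch is shorter than the requested analysis window."""


class DataQualityError(BrainwalkError, ValueError):
    """Input data makes a quantity undefined (e.g. an all-zero channel)."""


class NoWalkError(BrainwalkError, ValueError):
    """A random walk cannot be started (edgeless graph)."""


class IncompleteDataError(BrainwalkError, KeyError):
    """A (player, game) entry required to assemble the dataset is missing."""


class StratificationError(BrainwalkError, ValueError):
    """A class is too small to be split across the requested folds."""


class ParseError(BrainwalkError, ValueError):
    """A text artifact is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
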