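"""Exception hierarchy shared across the toolkit."""


class DrowsikitError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(DrowsikitError):
    """A record violates the landmark/feature schema (wrong count, bad range)."""


class StreamParseError(DrowsikitError):
    """A stream file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StreamOrderError(DrowsikitError):
    """Frame indices or timestamps are not strictly increasing."""


class DegenerateGeometryError(DrowsikitError):
    """A landmark configuration makes a ratio undefined (zero horizontal extent)."""


class EventSpecError(DrowsikitError):
    """A synthetic event schedule is inconsistent (overlap, bad duration)."""


class BalancingError(DrowsikitError):
    """Class rebalancing is impossible (an empty class)."""


class SplitError(DrowsikitError):
    """A stratified split cannot be formed."""


class ModelLayoutError(DrowsikitError):
    """A trained model and a feature matrix disagree on layout/dimension."""
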