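"""Exception types shared across the pipeline."""


class EdlinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EdlinkError):
    """A simulation or linkage configuration violates its invariants."""


class CapacityError(EdlinkError):
    """A generator limit was exceeded (daily CAD range, call-sign registry)."""


class ExtractIOError(EdlinkError):
    """An extract file could not be read at all (missing, empty, unreadable)."""


class ExtractFormatError(EdlinkError):
    """A strict read rejected an extract; carries the validation report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ConsistencyError(EdlinkError):
    """Linkage results and ground truth do not refer to the same extract."""
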