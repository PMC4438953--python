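"""Exception hierarchy shared across the pipeline."""


class MirmintError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirmintError, ValueError):
    """A file does not conform to its declared format."""


class LabelingError(MirmintError, ValueError):
    """A sample could not be assigned a group label."""


class DomainError(MirmintError, ValueError):
    """An input value violates a mathematical precondition."""


class UsageError(MirmintError, ValueError):
    """An operation was invoked with inconsistent or missing arguments."""
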