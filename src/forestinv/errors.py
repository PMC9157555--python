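"""Exception hierarchy shared across the pipeline stages."""


class ForestInvError(Exception):
    """Base class for all package errors."""


class FormatError(ForestInvError):
    """Unreadable or malformed input file."""


class EmptyInputError(ForestInvError):
    """An input that must contain data is empty."""


class InsufficientInputError(ForestInvError):
    """Too few points/rows to run the requested operation."""


class MissingGroundError(ForestInvError):
    """Height normalization requested but no ground points are classified."""


class StateError(ForestInvError):
    """Operation called on a cloud in the wrong normalization state."""


class ParameterError(ForestInvError):
    """Invalid parameter combination."""


class EmptySelectionError(ForestInvError):
    """A filter removed every candidate (e.g. no regional plots survive)."""
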