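"""Exception hierarchy for the planning pipeline.

Every stage raises a subclass of :class:`AcroplanError` so batch drivers can
attribute a failure to a stage and a subject.
"""


class AcroplanError(Exception):
    """Base class for all package errors."""


class FormatError(AcroplanError):
    """Input file unreadable or not in a supported format."""


class DegenerateInputError(AcroplanError):
    """Empty or geometrically meaningless input (empty mesh/volume, flat patch...)."""


class PreconditionError(AcroplanError):
    """An operation's documented precondition was violated (e.g. non-watertight mesh)."""


class NoCorridorError(AcroplanError):
    """No safe screw corridor exists for the requested direction/constraints."""


class FitError(AcroplanError):
    """A screw of the requested radius cannot be contained in the bone."""


class ConfigError(AcroplanError):
    """Invalid run configuration."""
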