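"""Exception hierarchy.

All validation failures raised by the library derive from :class:`OptomapError`
so callers (and the CLI, which maps them to exit code 2) can catch one type.
"""


class OptomapError(Exception):
    """Base class for all optomap errors."""


class InvalidParameterError(OptomapError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive tau)."""


class WindowError(OptomapError, ValueError):
    """An analysis window is empty or falls outside the trace."""


class IncompatibleSweepsError(OptomapError, ValueError):
    """Sweeps with mismatched geometry (dt, length, stimulus) cannot be combined."""


class IncompatibleMapsError(OptomapError, ValueError):
    """Maps in different frames or pixel sizes cannot be averaged."""


class InvalidFrameError(OptomapError, ValueError):
    """Operation requires an aligned coordinate frame."""


class SchemaError(OptomapError, ValueError):
    """A dataset file is malformed or has an unknown schema version."""
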