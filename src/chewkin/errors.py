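"""Exception hierarchy for the kinematics pipeline.

Exit-code mapping used by the CLI: validation problems (bad files, bad
config) exit 2, computation problems (degenerate geometry, undefined
poses) exit 3.
"""


class ChewkinError(Exception):
    """Base class for all package errors."""


class ValidationError(ChewkinError):
    """Malformed input file or configuration (CLI exit code 2)."""


class ConfigurationError(ValidationError):
    """Invalid parameter combination, e.g. filter cutoff at/above Nyquist."""


class ComputationError(ChewkinError):
    """A pipeline stage could not produce a result (CLI exit code 3)."""


class DegenerateGeometryError(ComputationError):
    """Collinear / insufficient points where a 3-D construction needs spread."""


class PoseUndefinedError(ComputationError):
    """Fewer than three usable markers: the frame's pose cannot be estimated."""
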