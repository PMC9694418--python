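"""Exception hierarchy.

The CLI maps these onto distinct exit codes (input 2, config 3, internal 4),
so library code should raise the most specific class that applies.
"""


class ZZDetectError(Exception):
    """Base class for all package errors."""


class InputError(ZZDetectError):
    """Unreadable, malformed, or out-of-range user input."""


class ConfigError(ZZDetectError):
    """Invalid configuration value (e.g. gamma <= 0, p outside (0,1])."""


class MeshError(ZZDetectError):
    """Violation of a mesh invariant (degenerate or non-conforming element)."""


class MetricError(ZZDetectError):
    """A requested metric is undefined for the given confusion counts."""
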