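"""Exception hierarchy.

All readers reject malformed input loudly; nothing is silently repaired.
"""


class CombindError(Exception):
    """Base class for all package errors."""


class FormatError(CombindError):
    """Malformed on-disk input (bad column count, bad coordinates, overlap rules)."""


class ConsistencyError(CombindError):
    """Objects that should agree do not (genome mismatch, row-count mismatch)."""


class ConfigError(CombindError):
    """Invalid or infeasible configuration."""


class QueryError(CombindError):
    """A combination query references unknown experiment or factor labels."""
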