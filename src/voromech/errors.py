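"""Exception hierarchy for voromech."""


class VoromechError(Exception):
    """Base class for all voromech errors."""


class InvalidConfigurationError(VoromechError):
    """A run configuration or parameter set is invalid."""


class DegenerateGeometryError(VoromechError):
    """A geometric construction (circumcenter, tessellation) is degenerate."""


class InvalidPolygonError(VoromechError):
    """A polygon has too few vertices or non-positive area."""


class InvalidStateError(VoromechError):
    """A simulation state violates its invariants."""


class DegenerateShapeError(VoromechError):
    """A shape tensor is too close to singular for the requested statistic."""


class UndefinedStatisticError(VoromechError):
    """A weighted statistic was requested with no usable weight."""
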