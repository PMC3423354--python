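"""Exception hierarchy shared across the package."""


class BindmodeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BindmodeError):
    """A structure/trajectory file violates the expected text format."""


class SelectionError(BindmodeError):
    """An atom-selection expression is malformed or matches nothing."""


class GeometryError(BindmodeError):
    """Degenerate geometry: collinear points, singular systems, bad shapes."""


class NoIntersectionError(GeometryError):
    """A projection line is parallel to the target plane."""


class AnalysisError(BindmodeError):
    """An analysis precondition is violated (empty window, constant series...)."""
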