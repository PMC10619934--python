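"""Exception types raised by the norvle pipeline."""


class NorvleError(Exception):
    """Base class for all norvle-specific errors."""


class ParameterError(NorvleError, ValueError):
    """A parameter is outside its documented domain."""


class OrientationConflictError(NorvleError):
    """A read contains gene-unit anchors on both strands (likely chimera)."""


class AdjacencyConflictError(NorvleError):
    """Spanning reads disagree on the distance between two landmarks."""


class AmbiguousAdjacencyError(NorvleError):
    """A landmark has two distinct right-neighbours at comparable support."""

    def __init__(self, landmark_pattern, candidates):
        self.landmark_pattern = landmark_pattern
        self.candidates = candidates
        super().__init__(
            f"landmark {landmark_pattern!r} has ambiguous right-neighbours: "
            f"{candidates!r}"
        )


class CoverageGapError(NorvleError):
    """An array position is covered by no read and is not a declared join."""


class NoJoinError(NorvleError):
    """Facing contig ends do not share the same homogeneous subtype."""


class ConfigError(NorvleError, ValueError):
    """A simulation configuration is over-constrained or inconsistent."""


class VcfParseError(NorvleError, ValueError):
    """A variant-table record could not be parsed."""

    def __init__(self, line_number, line, reason):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {reason}: {line!r}")
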