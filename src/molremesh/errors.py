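"""Exception hierarchy for molremesh."""


class MolRemeshError(Exception):
    """Base class for all package errors."""


class MeshFormatError(MolRemeshError):
    """A mesh file could not be parsed as the requested dialect."""


class UnsupportedElementError(MeshFormatError):
    """The file contains non-triangle faces."""


class NonManifoldError(MolRemeshError):
    """An edge has more than two incident faces."""


class NotClosedError(MolRemeshError):
    """Operation requires a closed (watertight) mesh."""


class DegenerateFaceError(MolRemeshError):
    """A face has a zero-length edge; carries the face index."""

    def __init__(self, face: int, message: str | None = None):
        self.face = face
        super().__init__(message or f"degenerate face {face}")


class IsolatedVertexError(MolRemeshError):
    """A vertex has no incident faces."""


class DegenerateRingError(MolRemeshError):
    """A vertex one-ring is too small or degenerate for the operation."""


class CurvatureUndefinedError(MolRemeshError):
    """Mixed Voronoi area vanished; curvature cannot be estimated here."""


class PQRParseError(MolRemeshError):
    """A PQR record is malformed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class EmptySurfaceError(MolRemeshError):
    """The requested isovalue produces an empty level set."""


class RecipeError(MolRemeshError):
    """A defect recipe cannot be realized on the given mesh."""


class InvalidHoleError(MolRemeshError):
    """A hole boundary loop is too short or inconsistent."""


class RepairIncompleteError(MolRemeshError):
    """Surface repair could not remove all self-intersections; carries the count left."""

    def __init__(self, remaining: int):
        self.remaining = remaining
        super().__init__(f"{remaining} self-intersecting pairs remain after repair")


class AngleBoundError(MolRemeshError):
    """Pipeline retries exhausted without reaching the target angle bound.

    Carries the final mesh and quality report so partial results survive.
    """

    def __init__(self, mesh, report):
        self.mesh = mesh
        self.report = report
        super().__init__(
            f"angle bound not met: theta_min={report.theta_min:.3f}, "
            f"theta_max={report.theta_max:.3f}, pct_below_30={report.pct_below_30:.3f}"
        )
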