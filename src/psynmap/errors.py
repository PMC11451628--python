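"""Exception hierarchy for psynmap.

All package-specific failures derive from :class:`PsynmapError` so callers
can catch the whole family at the pipeline boundary.
"""


class PsynmapError(Exception):
    """Base class for all psynmap errors."""


# --- geometry / cell table ---------------------------------------------------

class MalformedPolygonError(PsynmapError):
    """Polygon has fewer than 3 vertices, zero area, or self-intersects."""


class DuplicateCellIdError(PsynmapError):
    """Two cells in the same sample share a cell_id."""


# --- count matrix ------------------------------------------------------------

class DimensionMismatchError(PsynmapError):
    """Sidecar row/column counts disagree with the matrix header."""


class NonIntegerCountError(PsynmapError):
    """Count matrix contains non-integer or negative entries."""


# --- affine transforms -------------------------------------------------------

class SingularTransformError(PsynmapError):
    """The 2x2 linear block of an affine transform is singular."""


class SpaceMismatchError(PsynmapError):
    """Points tagged with one coordinate space passed to a transform expecting another."""


# --- synthetic data ----------------------------------------------------------

class DensityInfeasibleError(PsynmapError):
    """Requested cell density cannot be met at the minimum nucleus spacing."""


class BlobOutOfBoundsError(PsynmapError):
    """A rendered inclusion center falls outside the image canvas."""


# --- expression --------------------------------------------------------------

class ZeroLibrarySizeError(PsynmapError):
    """A cell has zero library size over non-negative-probe genes."""


class EmptyGroupError(PsynmapError):
    """A grouping label has no member cells."""


class NoSharedGenesError(PsynmapError):
    """Fewer than 3 genes shared between query and reference profiles."""


# --- statistics --------------------------------------------------------------

class InsufficientReplicatesError(PsynmapError):
    """Fewer than 2 groups with >=2 sample-level replicates each."""


class AllZeroUnitError(PsynmapError):
    """A pseudo-bulk unit has zero total counts; size factor undefined."""


class PipelineStageError(PsynmapError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
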