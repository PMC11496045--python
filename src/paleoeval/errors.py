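"""Exception hierarchy for paleoeval.

All package-specific failures derive from :class:`PaleoEvalError` so callers
can catch one base class at pipeline boundaries.
"""


class PaleoEvalError(Exception):
    """Base class for all paleoeval errors."""


class ConfigurationError(PaleoEvalError):
    """A required column, option or plugin is missing or inconsistent."""


class EmptyInputError(PaleoEvalError):
    """An input table or raster contained no usable rows/cells."""


class AlignmentError(PaleoEvalError):
    """Rasters in a stack do not share a common geotransform."""


class NoValidCellError(PaleoEvalError):
    """A grid operation required at least one valid (non-nodata) cell."""


class EmptyEvaluationError(PaleoEvalError):
    """No observation survived slicing/snapping, nothing to evaluate."""


class MissingSliceError(PaleoEvalError):
    """Records were assigned to a time slice with no suitability raster."""


class InfeasibleSampleError(PaleoEvalError):
    """Fewer eligible cells than requested pseudoabsence points."""

    def __init__(self, requested: int, eligible: int):
        self.requested = requested
        self.eligible = eligible
        super().__init__(
            f"requested {requested} pseudoabsence points but only "
            f"{eligible} eligible cells are available"
        )


class MissingPluginError(PaleoEvalError):
    """A task references a modelling algorithm with no registered plugin."""


class PluginContractError(PaleoEvalError):
    """A model plugin returned suitabilities outside [0, 1]."""
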