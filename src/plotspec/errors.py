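"""Exception hierarchy for the plotspec pipeline."""


class PlotspecError(Exception):
    """Base class for all plotspec errors."""


class InvalidConfigError(PlotspecError, ValueError):
    """A configuration value violates its contract."""


class UnitsError(PlotspecError, ValueError):
    """An operation received a raster in the wrong radiometric units."""


class GeometryError(PlotspecError, ValueError):
    """Vector/raster geometries are inconsistent or out of extent."""


class ExtractionError(PlotspecError, ValueError):
    """Zonal/panel extraction found no qualifying pixels."""


class EmptyZoneError(ExtractionError):
    """A plot zone contained zero usable pixels after masking/buffering."""


class DegenerateFitError(PlotspecError, ValueError):
    """A fit is not identifiable from the data provided."""


class CollinearityError(DegenerateFitError):
    """Design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design; offending columns: {self.columns}")


class UndefinedTraitError(PlotspecError, ValueError):
    """A NUE trait was requested for an unfertilized (N=0) plot."""


class PairingError(PlotspecError, ValueError):
    """One or more fertilized plots could not be matched to an N0 control."""

    def __init__(self, unmatched, message=None):
        self.unmatched = list(unmatched)
        super().__init__(message or f"no N0 pair for plots: {self.unmatched}")


class StageError(PlotspecError, KeyError):
    """Unknown growth-stage label."""


class SplitError(PlotspecError, ValueError):
    """A stratified train/test split cannot be formed."""
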