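"""Exception hierarchy shared across the package."""


class GiantCellError(Exception):
    """Base class for package errors."""


class ConfigError(GiantCellError):
    """Invalid configuration or parameter value."""


class FormatError(GiantCellError):
    """Input file does not match the expected format."""


class DegenerateInputError(GiantCellError):
    """Input is structurally valid but degenerate (e.g. empty raster)."""


class PlacementError(GiantCellError):
    """A cell could not be placed during randomization."""


class GeometryError(GiantCellError):
    """Polygon/mesh geometry became invalid."""


class UndefinedStatisticError(GiantCellError):
    """A statistic is undefined for the given inputs (e.g. no countable cells)."""
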