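"""Exception hierarchy shared across the pipeline stages."""


class PlastmarkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PlastmarkError):
    """Malformed or empty input file."""


class AlignmentShapeError(PlastmarkError):
    """Sequences of unequal length where a rectangular matrix is required."""


class LabelError(PlastmarkError):
    """Duplicate, unknown or unmapped taxon/accession label."""


class TaxaMismatchError(PlastmarkError):
    """Alignments with different taxon sets where identical sets are required."""


class CoordinateError(PlastmarkError):
    """Column coordinate outside the alignment bounds."""


class InsufficientDataError(PlastmarkError):
    """Too few observations for the requested statistic."""


class RegionError(PlastmarkError):
    """Invalid or overlapping region definition."""


class DistanceError(PlastmarkError):
    """No comparable sites between a pair of sequences."""


class SaturationError(PlastmarkError):
    """Substitution saturation: model distance undefined (p >= 3/4)."""


class MatrixError(PlastmarkError):
    """Distance matrix violates symmetry or finiteness."""


class RootingError(PlastmarkError):
    """Requested outgroup is not monophyletic / not a bipartition side."""


class DegenerateTreeError(PlastmarkError):
    """Tree has no measurable branches for likelihood computation."""


class SizeError(PlastmarkError):
    """Problem too large for an exhaustive method."""


class TreeMismatchError(PlastmarkError):
    """Objects derived from different trees were combined."""


class ConfigurationError(PlastmarkError):
    """Invalid run configuration value; message names the offending field."""
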