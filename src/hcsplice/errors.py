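"""Exception hierarchy.

``ConfigError`` covers malformed layouts and invalid parameter bundles
(CLI exit code 2); ``DataError`` covers inputs that are structurally valid
but not analysable (CLI exit code 3).
"""


class HcspliceError(Exception):
    """Base class for all package errors."""


class ConfigError(HcspliceError):
    """Invalid configuration (layout file, parameter bundle)."""


class DataError(HcspliceError):
    """Input data cannot be analysed as requested."""


class LayoutError(ConfigError):
    """Plate-layout schema violation (duplicate well, unknown role, ...)."""


class PlacementError(DataError):
    """Cell placement failed: field too crowded for non-overlapping nuclei."""


class InsufficientBackgroundError(DataError):
    """Cell-free area too small to estimate background."""


class GatingError(DataError):
    """Transfection gates cannot be derived (missing/too few control cells)."""


class CalibrationError(DataError):
    """Ladder calibration impossible (too few rungs, non-monotone positions)."""


class BandAssignmentError(DataError):
    """Band-to-amplicon assignment failed (missing actin, ambiguous bands)."""
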