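"""Labelled error types raised across the pipeline."""


class SclsettleError(Exception):
    """Base class for all package errors."""


class UnknownGroupError(SclsettleError, ValueError):
    """Group label is not one of the supported corneal morphologies."""


class LensTouchError(SclsettleError, ValueError):
    """Lens back surface touches or crosses the cornea inside the 12-mm disc."""


class FieldOfViewError(SclsettleError, ValueError):
    """Rendered boundaries fall outside the image rows (field of view too small)."""


class SegmentationError(SclsettleError, ValueError):
    """Frame rejected: fewer than two detectable boundary ridges."""


class ReconstructionError(SclsettleError, ValueError):
    """Profile set cannot be assembled into a polar map."""


class RegionSchemeError(SclsettleError, ValueError):
    """Point outside the region scheme, or malformed scheme."""


class SettlingFitError(SclsettleError, ValueError):
    """Settling series too degenerate to fit or summarize."""


class AnovaDesignError(SclsettleError, ValueError):
    """Repeated-measures design too small or unbalanced to analyze."""


class ConfigError(SclsettleError, ValueError):
    """Inconsistent or incomplete run configuration."""
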