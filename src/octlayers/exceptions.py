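"""Exception hierarchy for the octlayers toolkit.

Every stage raises a subclass of :class:`OCTLayersError` so callers (and the
CLI) can distinguish toolkit failures from programming errors.
"""


class OCTLayersError(Exception):
    """Base class for all octlayers errors."""


class GeometryMismatchError(OCTLayersError):
    """Raw file size does not match the geometry the device profile implies."""


class UnsupportedFormatError(OCTLayersError):
    """File is not in the expected export format (e.g. bad magic string)."""


class CorruptFileError(OCTLayersError):
    """File header and body are internally inconsistent."""


class MissingMetadataError(OCTLayersError):
    """A required metadata field (e.g. scan quality) is absent."""


class ValidationError(OCTLayersError):
    """An in-memory object violates its invariants."""


class LowSignalError(OCTLayersError):
    """Too many A-scans carry no detectable retinal signal."""


class InfeasibleConstraintsError(OCTLayersError):
    """Surface separation/smoothness constraints admit no solution."""


class FoveaOutOfToleranceError(OCTLayersError):
    """Detected fovea lies more than 1 mm from the scan centre."""


class InsufficientDataError(OCTLayersError):
    """Too few observations (or clusters) for the requested statistic."""


class FeatureRecipeMismatchError(OCTLayersError):
    """A trained classifier was built with an incompatible feature recipe."""


class TrainingError(OCTLayersError):
    """Classifier training could not proceed (e.g. an unlabelled class)."""


class ManualCorrectionError(OCTLayersError):
    """A manual surface edit would violate surface ordering constraints."""
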