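"""Exception hierarchy for the vesselct pipeline.

Every error raised on bad configuration, bad input data or a violated
measurement protocol derives from :class:`VesselCTError`, so callers can
catch pipeline problems without masking programming errors.
"""


class VesselCTError(Exception):
    """Base class for all vesselct errors."""


class ConfigurationError(VesselCTError, ValueError):
    """A spec/config object violates one of its invariants."""


class InputError(VesselCTError, ValueError):
    """An input array, path or argument is unusable (wrong shape, empty, out of bounds)."""


class FormatError(VesselCTError, ValueError):
    """An on-disk dataset is malformed (e.g. inconsistent slice shapes)."""


class MetadataError(VesselCTError, ValueError):
    """Image metadata is unusable (e.g. zero rescale slope)."""


class SeedError(VesselCTError, ValueError):
    """A region-growing seed does not satisfy its precondition."""


class ProtocolError(VesselCTError, ValueError):
    """A measurement protocol requirement is not met (missing ROIs/slices)."""


class PlacementError(VesselCTError, ValueError):
    """Automatic ROI placement could not satisfy its geometric constraints."""


class MeasurementError(VesselCTError, ValueError):
    """A measurement is undefined for the given data (e.g. empty tissue ROI)."""


class DegenerateImageError(VesselCTError, ValueError):
    """An image histogram is degenerate for the requested operation (e.g. Otsu on a constant image)."""


class DataError(VesselCTError, ValueError):
    """A per-sample record is invalid (e.g. non-positive tissue volume)."""


class DegenerateDataError(DataError):
    """A statistic is undefined for the data (e.g. zero variance)."""


class SampleSizeError(DataError):
    """Too few observations for the requested statistic."""


class PairingError(DataError):
    """CT and histology records cannot be paired one-to-one."""
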