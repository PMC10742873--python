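"""Exception hierarchy for the toolkit.

Every anticipated failure mode raises a subclass of :class:`SenolyticaError`
so callers (and the CLI) can distinguish toolkit errors from programming bugs.
"""


class SenolyticaError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SenolyticaError):
    """A file could not be read in the expected format."""


class ChannelMappingError(SenolyticaError):
    """A channel map references a plane index that does not exist."""


class WavelengthAxisError(SenolyticaError):
    """Wavelength axis is inconsistent with the number of image planes."""


class SchemaError(SenolyticaError):
    """A tabular input is missing required columns."""


class PlacementError(SenolyticaError):
    """Non-touching object placement failed at the requested density."""


class DegenerateThresholdError(SenolyticaError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class ChannelError(SenolyticaError):
    """A requested channel is not present in the field."""


class UndefinedBaselineError(SenolyticaError):
    """Vehicle baseline is zero; fold change is undefined."""


class InsufficientReplicationError(SenolyticaError):
    """Fewer than two replicates where a test requires them."""


class EmptyROIError(SenolyticaError):
    """A region of interest contains no pixels."""


class GroupingError(SenolyticaError):
    """A required (condition, compartment) group is absent."""


class EmptyInputError(SenolyticaError):
    """An operation received an empty table."""


class UndefinedPercentageError(SenolyticaError):
    """Percentage requested over zero total cells."""
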