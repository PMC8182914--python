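"""Exception hierarchy shared across the pipeline."""


class MarEvalkitError(Exception):
    """Base class for all package errors."""


class FormatError(MarEvalkitError):
    """A file could not be read or written in the requested format."""


class GeometryError(MarEvalkitError):
    """Inconsistent or physically invalid acquisition geometry."""


class AlignmentError(MarEvalkitError):
    """Two volumes/masks do not share shape, spacing and origin."""


class ValidationError(MarEvalkitError):
    """An input violates a documented contract."""


class ConfigurationError(MarEvalkitError):
    """A configuration is internally inconsistent or out of range."""


class MetricError(MarEvalkitError):
    """A metric is undefined for the given inputs (e.g. empty ROI)."""


class PluginContractError(MarEvalkitError):
    """A MAR plugin violated the correction contract."""
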