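"""Exception hierarchy for brachytrack."""


class BrachytrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BrachytrackError):
    """Invalid system configuration (specs, layouts, config files)."""


class GeometryError(BrachytrackError):
    """Geometrically impossible request (e.g. projection plane behind the detector)."""


class MetricError(BrachytrackError):
    """Image-quality metric cannot be computed on the given data."""
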