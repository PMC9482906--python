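"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class SteroQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(SteroQuantError):
    """Invalid configuration: schema violation, bad parameter, unknown stage."""


class PanelReferenceError(ConfigError):
    """An internal-standard or surrogate reference does not resolve in the panel."""


class DataError(SteroQuantError):
    """Invalid or inconsistent input data."""


class MissingInternalStandardError(DataError):
    """Internal-standard area is zero or missing; the response ratio is undefined."""


class CalibrationError(DataError):
    """A calibration curve could not be fitted or was rejected."""
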