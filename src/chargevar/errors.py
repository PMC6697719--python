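"""Exception hierarchy.

``ChargevarError`` is the base for everything this package raises on
purpose; ``ValidationError`` covers bad inputs/parameters (CLI exit
code 1), anything else escaping is treated as internal (exit code 2).
"""


class ChargevarError(Exception):
    """Base class for all package errors."""


class ValidationError(ChargevarError):
    """Invalid parameters, malformed input files, or schema mismatches."""


class CalibrationError(ValidationError):
    """Unusable area-vs-mass calibration (e.g. non-positive slope)."""


class NoPeaksError(ValidationError):
    """No product peaks detected where a distribution was requested."""
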