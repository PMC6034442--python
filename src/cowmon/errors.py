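"""Exception hierarchy for cowmon.

Every error raised by the library derives from :class:`CowmonError`, so
callers (and the CLI) can distinguish validation problems from genuine
bugs with a single ``except``.
"""


class CowmonError(Exception):
    """Base class for all cowmon errors."""


class FormatError(CowmonError):
    """A file exists but is not in the expected dialect (e.g. wrong PNG bit depth)."""


class RangeError(CowmonError, ValueError):
    """A value cannot be represented in the requested encoding (e.g. depth > 65535 mm)."""


class ValidationError(CowmonError, ValueError):
    """Inputs violate a precondition (shape mismatch, empty manifest, ...)."""


class DegenerateInputError(CowmonError):
    """The input is technically valid but too degenerate for the operation
    (e.g. fewer than two pixels survive a threshold, ball larger than mask)."""


class CalibrationError(CowmonError):
    """A body-condition calibration could not be fitted (too few points or
    a physically implausible positive slope)."""


class SessionUnusableError(CowmonError):
    """No frame in the session survived quality control for a given trait."""
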