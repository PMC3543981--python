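"""Exception hierarchy.

``DataError`` covers malformed or empty inputs (CLI exit code 1);
``ParameterError`` covers invalid arguments (CLI exit code 2 when raised
during option handling, otherwise 1).
"""


class AdmixkitError(Exception):
    """Base class for all package errors."""


class DataError(AdmixkitError):
    """Input data is unreadable, empty, or inconsistent."""


class ParameterError(AdmixkitError, ValueError):
    """An argument is outside its documented domain."""
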