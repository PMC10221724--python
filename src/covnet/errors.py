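"""Exception hierarchy.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2);
anything else raised during a run maps to exit code 3.
"""


class CovnetError(Exception):
    """Base class for package errors."""


class ValidationError(CovnetError, ValueError):
    """Invalid input data or configuration."""
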