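"""Package-wide exception types.

Every error raised deliberately by thyrisk carries a short machine-parsable
``code`` so that the command-line layer can emit one-line diagnostics.
"""

from __future__ import annotations


class ThyriskError(Exception):
    """Base class for all errors raised by thyrisk.

    Parameters
    ----------
    code
        Short stable identifier, e.g. ``"weight-out-of-range"``.
    message
        Human-readable description.
    """

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(message)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"[{self.code}] {super().__str__()}"


class ValidationError(ThyriskError):
    """Invalid value for a domain object (weight out of range, bad enum...)."""


class ParseError(ThyriskError):
    """Malformed input file; ``row`` is the offending 1-based line when known."""

    def __init__(self, code: str, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(code, message)
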