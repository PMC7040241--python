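"""ATA sonographic patterns and the annotated ultrasound score X_US.

The five ATA ultrasound risk categories map to a fixed numeric score equal to
the upper bound of the guideline malignancy-risk band for the pattern:

====================  =====
pattern               X_US
====================  =====
benign                0
very low suspicion    0
low suspicion         0.1
intermediate          0.2
high suspicion        0.9
====================  =====

The mapping is total and deterministic; its image is exactly {0, 0.1, 0.2, 0.9}.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ParseError


class AtaPattern(str, Enum):
    BENIGN = "BENIGN"
    VERY_LOW = "VERY_LOW"
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


_XUS: dict[AtaPattern, float] = {
    AtaPattern.BENIGN: 0.0,
    AtaPattern.VERY_LOW: 0.0,
    AtaPattern.LOW: 0.1,
    AtaPattern.INTERMEDIATE: 0.2,
    AtaPattern.HIGH: 0.9,
}

#: The four values X_US can take.
XUS_VALUES: tuple[float, ...] = (0.0, 0.1, 0.2, 0.9)


def xus_from_pattern(pattern: AtaPattern) -> float:
    """Annotated ultrasound score for an ATA pattern."""
    if not isinstance(pattern, AtaPattern):
        raise ParseError("bad-pattern", f"not an ATA pattern: {pattern!r}")
    return _XUS[pattern]


_ALIASES = {
    "BENIGN": AtaPattern.BENIGN,
    "VERY_LOW": AtaPattern.VERY_LOW,
    "VERY_LOW_SUSPICION": AtaPattern.VERY_LOW,
    "VERYLOW": AtaPattern.VERY_LOW,
    "LOW": AtaPattern.LOW,
    "LOW_SUSPICION": AtaPattern.LOW,
    "INTERMEDIATE": AtaPattern.INTERMEDIATE,
    "INTERMEDIATE_SUSPICION": AtaPattern.INTERMEDIATE,
    "HIGH": AtaPattern.HIGH,
    "HIGH_SUSPICION": AtaPattern.HIGH,
}

# Numeric encodings seen in cohort files. 0 is ambiguous between the benign
# and very-low patterns (identical score); it parses as VERY_LOW.
_NUMERIC = {"0": AtaPattern.VERY_LOW, "0.0": AtaPattern.VERY_LOW,
            "0.1": AtaPattern.LOW, "0.2": AtaPattern.INTERMEDIATE,
            "0.9": AtaPattern.HIGH}


def parse_pattern(text: str | float) -> AtaPattern:
    """Parse an ATA pattern from a category name or a numeric X_US value.

    Case-insensitive; spaces and hyphens are treated as underscores. Accepts
    the numeric scores 0, 0.1, 0.2, 0.9 as used in some cohort files.
    """
    s = str(text).strip()
    if s in _NUMERIC:
        return _NUMERIC[s]
    key = s.upper().replace("-", "_").replace(" ", "_")
    if key in _ALIASES:
        return _ALIASES[key]
    try:
        return _NUMERIC[str(float(s))]
    except (ValueError, KeyError):
        raise ParseError("bad-pattern", f"unrecognized ATA pattern {text!r}") from None


@dataclass(frozen=True)
class UltrasoundAssessment:
    """A nodule's ATA pattern and its annotated score."""

    nodule_id: str
    pattern: AtaPattern

    @property
    def x_us(self) -> float:
        return xus_from_pattern(self.pattern)
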