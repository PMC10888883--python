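"""Reference-side data types used by the annotators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ..errors import ValidationError


@dataclass
class RefSpectrum:
    """A reference MS2 spectrum with known compound identity."""

    compound_name: str
    precursor_mz: Optional[float]
    peaks: list  # (mz, intensity), sorted ascending
    source_library: str = ""
    is_authentic_standard: bool = False
    formula: str = ""
    identifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peaks = sorted(((float(m), float(i)) for m, i in self.peaks),
                            key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValidationError(f"{self.compound_name}: negative intensity in reference")

    @property
    def indexable(self):
        return self.precursor_mz is not None


@dataclass
class StandardEntry:
    """An authentic chemical standard measured on the user's method."""

    compound_name: str
    mz: float
    rtime: float
    identifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mz <= 0:
            raise ValidationError(f"{self.compound_name}: mz must be > 0")
        if self.rtime < 0:
            raise ValidationError(f"{self.compound_name}: rtime must be >= 0")


@dataclass
class SpectralMatch:
    """Outcome of scoring one query spectrum against one reference."""

    query_id: str
    reference: RefSpectrum
    score: float
    n_matched_peaks: int

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValidationError(f"score {self.score} outside [0, 1]")
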