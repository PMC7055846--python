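"""The universal estimator output record."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["RichnessEstimate", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RichnessEstimate:
    """A point estimate of species richness.

    ``point`` is the raw (real-valued) estimate; ``point_rounded`` is the
    nearest-integer report value (ties half-up), which is what richness
    tables print.  ``inputs`` summarises the tallies the estimate was
    computed from.
    """

    estimator: str
    point: float
    inputs: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.point):
            raise ValueError(f"{self.estimator}: non-finite estimate {self.point}")

    @property
    def point_rounded(self) -> int:
        return round_half_up(self.point)

    def __repr__(self) -> str:  # compact, table-friendly
        return f"RichnessEstimate({self.estimator}: {self.point:.3f} ~ {self.point_rounded})"
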