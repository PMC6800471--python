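"""Shared result containers for tail estimation."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

__all__ = ["TailBoundaries", "TailEstimate"]


@dataclass(frozen=True)
class TailBoundaries:
    """Rough and refined tail boundaries in 0-based, half-open raw-sample coordinates."""

    rough_start: int = 0
    rough_end: int = 0
    precise_start: int = 0
    precise_end: int = 0
    found: bool = False

    def __post_init__(self) -> None:
        if self.found and not (
            self.rough_start <= self.precise_start < self.precise_end <= self.rough_end
        ):
            raise ValueError(
                "precise boundaries must nest inside rough boundaries: "
                f"{self.rough_start} <= {self.precise_start} < {self.precise_end}"
                f" <= {self.rough_end}"
            )


@dataclass
class TailEstimate:
    """One output row: per-read tail call with everything needed to recompute it."""

    read_id: str
    file_path: str = ""
    read_type: str = "invalid"  # polyA | polyT | rna | invalid
    found: bool = False
    failure_reason: str = ""
    tail_start: int | None = None
    tail_end: int | None = None
    samples_per_nt: float | None = None
    tail_length_nt: float | None = None
    basecall_model: str = ""

    def __post_init__(self) -> None:
        if self.found:
            expected = (self.tail_end - self.tail_start) / self.samples_per_nt
            if abs(expected - self.tail_length_nt) > 1e-9:
                raise ValueError("tail_length_nt inconsistent with boundaries and rate")

    def as_row(self) -> dict[str, Any]:
        return asdict(self)
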