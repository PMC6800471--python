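"""Read-specific nucleotide translocation rate (samples per nucleotide).

A tail measured in raw samples is converted to nucleotides by dividing by
the read's average dwell per nucleotide. For standard-model base-calling
the geometric mean of samples-per-single-move is used; flip-flop
base-calling tends to over-segment homopolymers, so its rate is instead
the arithmetic mean after discarding the 5% largest dwells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

from .fast5 import BasecallModel, Fast5ReadError, TranslocationTable

if TYPE_CHECKING:  # pragma: no cover
    from .fast5 import ReadRecord

__all__ = [
    "RateMethod",
    "TranslocationRate",
    "samples_per_single_move",
    "rate_geometric_mean",
    "rate_trimmed_mean",
    "select_rate",
]


class RateMethod(str, Enum):
    GEOMETRIC_MEAN = "geometric_mean"
    TRIMMED_ARITHMETIC_MEAN = "trimmed_arithmetic_mean"


@dataclass(frozen=True)
class TranslocationRate:
    samples_per_nt: float
    method: RateMethod
    n_moves_used: int

    def __post_init__(self) -> None:
        if not self.samples_per_nt > 0:
            raise ValueError("samples_per_nt must be positive")


def samples_per_single_move(table: TranslocationTable) -> np.ndarray:
    """Expand a translocation table into one dwell entry per single move.

    A block with move m > 1 (a translocation the base-caller detected but
    could not resolve into separate events) emits m equal entries of n/m
    samples each; entries are kept fractional. Move-0 dwell has already been
    merged into its neighbouring move by the FAST5 reader.
    """
    if table.total_moves == 0:
        raise Fast5ReadError("no_moves")
    out: list[float] = []
    for n, m in table.blocks:
        if m == 0:
            # defensively fold unmerged move-0 dwell into the previous entry
            if out:
                out[-1] += float(n)
            continue
        out.extend([n / m] * m)
    return np.asarray(out, dtype=float)


def rate_geometric_mean(dwells: np.ndarray) -> TranslocationRate:
    """Geometric mean of per-move dwells: exp(mean(log(dwells)))."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("empty dwell vector")
    if np.any(d <= 0):
        raise ValueError("dwells must be positive")
    rate = float(np.exp(np.mean(np.log(d))))
    return TranslocationRate(rate, RateMethod.GEOMETRIC_MEAN, int(d.size))


def rate_trimmed_mean(dwells: np.ndarray, trim_fraction: float = 0.05) -> TranslocationRate:
    """Arithmetic mean after discarding the ceil(trim_fraction*n) largest dwells."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("empty dwell vector")
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must be in [0, 1)")
    k = math.ceil(trim_fraction * d.size)
    if k >= d.size:
        raise ValueError("all entries trimmed")
    kept = np.sort(d)[: d.size - k] if k else d
    rate = float(np.mean(kept))
    return TranslocationRate(rate, RateMethod.TRIMMED_ARITHMETIC_MEAN, int(kept.size))


def select_rate(record: "ReadRecord", trim_fraction: float = 0.05) -> TranslocationRate:
    """Pick the rate estimator that matches the read's base-calling model."""
    dwells = samples_per_single_move(record.translocation)
    if record.basecall_model is BasecallModel.FLIPFLOP:
        return rate_trimmed_mean(dwells, trim_fraction)
    return rate_geometric_mean(dwells)
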