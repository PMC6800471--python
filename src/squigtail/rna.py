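"""Poly(A) tail estimation for native RNA nanopore reads.

RNA translocates the pore 3'->5', so the raw trace begins with the
sequencing-adapter signal, immediately followed by the poly(A) tail and
then the transcript body. The estimator z-normalises and clips the raw
trace, smooths it with forward and backward moving averages merged by
point-wise maximum, segments the smoothed trace at a fixed threshold to
locate the adapter->tail pattern, refines the tail boundaries from the
slope of non-overlapping window means, and converts the tail span from
samples to nucleotides with the read-specific translocation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fast5 import BasecallModel, ReadRecord
from .rate import select_rate
from .result import TailBoundaries, TailEstimate

__all__ = [
    "RnaConfig",
    "znormalize_clip",
    "bidirectional_smooth",
    "find_rough_polya",
    "refine_polya",
    "estimate_rna_tail",
]


@dataclass
class RnaConfig:
    znorm_clip: float = 3.0
    smooth_window: int = 400
    smooth_stride: int = 1
    segment_threshold: float = 0.3
    refine_window: int = 25
    refine_stride: int = 25
    slope_bound: float = 0.3
    #: accept flip-flop tables for RNA (not produced by current base-callers)
    allow_flipflop: bool = False

    def __post_init__(self) -> None:
        if min(self.znorm_clip, self.smooth_window, self.refine_window) <= 0:
            raise ValueError("window and clip parameters must be positive")
        if not 0 < self.segment_threshold < 1:
            raise ValueError("segment_threshold must lie in (0, 1)")


def znormalize_clip(raw: np.ndarray, clip: float = 3.0) -> np.ndarray:
    """(x - mean) / sd per sample (population sd), clipped to [-clip, +clip]."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short to normalize")
    sd = float(x.std())
    if sd == 0:
        raise ValueError("flat_signal")
    z = (x - x.mean()) / sd
    return np.clip(z, -clip, clip)


def _directional_mean(signal: np.ndarray, window: int, backward: bool) -> np.ndarray:
    """Moving average with stride 1, windows truncated at the signal edges.

    Forward: mean of the trailing window ending at i. Backward: mean of the
    leading window starting at i (the forward average of the reversed signal,
    reversed back).
    """
    x = signal[::-1] if backward else signal
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    out = (c[idx] - c[lo]) / (idx - lo)
    return out[::-1] if backward else out


def bidirectional_smooth(signal: np.ndarray, window: int = 400, stride: int = 1) -> np.ndarray:
    """Point-wise maximum of forward and backward moving averages."""
    x = np.asarray(signal, dtype=float)
    if x.size < window:
        raise ValueError("read_too_short")
    if stride != 1:
        raise NotImplementedError("only stride 1 is supported for smoothing")
    return np.maximum(
        _directional_mean(x, window, backward=False),
        _directional_mean(x, window, backward=True),
    )


def _segments(above: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length segmentation of a boolean vector into (state, start, end)."""
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [above.size]))
    return [(bool(above[s]), int(s), int(e)) for s, e in zip(bounds[:-1], bounds[1:])]


def find_rough_polya(
    smoothed: np.ndarray, threshold: float = 0.3
) -> tuple[int, int] | None:
    """Locate rough tail bounds from the adapter's above/below signature.

    The adapter produces one above-threshold and one below-threshold segment
    at the read start; the next above-threshold segment is the tail. A
    below-threshold segment at the very start of the trace (signal captured
    before the adapter) is skipped.
    """
    x = np.asarray(smoothed, dtype=float)
    if x.size == 0:
        return None
    segs = _segments(x > threshold)
    i = 0
    if segs and not segs[0][0]:
        i = 1
    # need above (adapter top), below (adapter bottom), above (tail)
    if len(segs) < i + 3:
        return None
    if not (segs[i][0] and not segs[i + 1][0] and segs[i + 2][0]):
        return None
    return segs[i + 2][1], segs[i + 2][2]


def refine_polya(
    normalized: np.ndarray,
    rough: tuple[int, int],
    window: int = 25,
    stride: int = 25,
    slope_bound: float = 0.3,
) -> tuple[int, int] | None:
    """Refine tail bounds to the longest low-slope stretch of window means.

    The clipped normalized signal inside the rough bounds is reduced to
    non-overlapping window means; the slope is the difference between
    consecutive means. The longest run of |slope| <= slope_bound gives the
    precise bounds (earliest run on ties), mapped back to sample
    coordinates, end inclusive of the final window.
    """
    if stride != window:
        raise NotImplementedError("refinement uses non-overlapping windows")
    start, end = rough
    span = normalized[start:end]
    n_win = span.size // window
    if n_win < 2:
        return None
    means = span[: n_win * window].reshape(n_win, window).mean(axis=1)
    slopes = np.diff(means)
    ok = np.abs(slopes) <= slope_bound
    if not ok.any():
        return None
    # longest run of consecutive qualifying slopes; slope k joins windows k, k+1
    best_len, best_start = 0, -1
    run_start = None
    for k, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = k
        elif not flag and run_start is not None:
            if k - run_start > best_len:
                best_len, best_start = k - run_start, run_start
            run_start = None
    if best_start < 0:
        return None
    first_win = best_start
    last_win = best_start + best_len  # slopes [best_start, best_start+best_len)
    precise_start = start + first_win * window
    precise_end = min(start + (last_win + 1) * window, end)
    return precise_start, precise_end


def estimate_rna_tail(record: ReadRecord, config: RnaConfig | None = None) -> TailEstimate:
    """Full RNA pipeline: normalise, smooth, segment, refine, convert to nt."""
    config = config or RnaConfig()
    est = TailEstimate(
        read_id=record.read_id,
        file_path=record.source_path,
        read_type="rna",
        basecall_model=record.basecall_model.value,
    )
    if record.basecall_model is BasecallModel.FLIPFLOP and not config.allow_flipflop:
        est.failure_reason = "flipflop_rna_unsupported"
        return est
    try:
        z = znormalize_clip(record.raw_signal, config.znorm_clip)
    except ValueError as exc:
        est.failure_reason = str(exc)
        return est
    try:
        smoothed = bidirectional_smooth(z, config.smooth_window, config.smooth_stride)
    except ValueError:
        est.failure_reason = "read_too_short"
        return est
    rough = find_rough_polya(smoothed, config.segment_threshold)
    if rough is None:
        est.failure_reason = "no_adapter_pattern"
        return est
    precise = refine_polya(
        z, rough, config.refine_window, config.refine_stride, config.slope_bound
    )
    if precise is None:
        est.failure_reason = "no_low_slope_run"
        return est
    bounds = TailBoundaries(rough[0], rough[1], precise[0], precise[1], found=True)
    try:
        rate = select_rate(record)
    except Exception as exc:  # noqa: BLE001 - recorded in the row, not raised
        est.failure_reason = f"rate_error:{exc}"
        return est
    est.found = True
    est.tail_start = bounds.precise_start
    est.tail_end = bounds.precise_end
    est.samples_per_nt = rate.samples_per_nt
    est.tail_length_nt = (bounds.precise_end - bounds.precise_start) / rate.samples_per_nt
    return est
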