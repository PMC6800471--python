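"""Poly(A)/poly(T) tail estimation for DNA (cDNA/PCR) nanopore reads.

DNA is double-stranded, so a read carries its homopolymer tail either as
poly(A) near the 3' end or as poly(T) near the 5' end. The read is first
oriented from the adapter primer motifs in its base-called sequence; the
signal of poly(A) reads is index-reversed so the tail always lies near the
signal start. The adapter end-primer alignment anchors a rough tail start
through the move table; precise boundaries are then found inside a bounded
search window on the absolute z-normalised signal, using per-window mean
and slope thresholds with tolerance for short non-tail signal spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import (
    ClassificationResult,
    DnaReadType,
    PrimerConfig,
    classify_dna_read,
    local_align,
    reverse_complement,
)
from .fast5 import ReadRecord
from .rate import select_rate
from .result import TailEstimate
from .rna import znormalize_clip

__all__ = [
    "DnaConfig",
    "base_to_sample",
    "prepare_dna_signal",
    "find_precise_dna_tail",
    "estimate_dna_tail",
]


@dataclass
class DnaConfig:
    search_window: int = 3000  # raw samples scanned downstream of the rough start
    mean_window: int = 10
    mean_stride: int = 10
    slope_bound: float = 0.2
    polyT_mean_bound: float = 0.3  # window means of |z| must stay in (0, bound)
    polyA_mean_bound: float = 0.6
    min_tail_run: int = 60  # samples of tail-like signal needed to bridge a spike
    max_gap_nt: float = 120.0  # largest bridgeable spike, in nucleotides
    znorm_clip: float = 3.0
    iterative_bridging: bool = True

    def __post_init__(self) -> None:
        if min(self.search_window, self.mean_window, self.min_tail_run) <= 0:
            raise ValueError("window parameters must be positive")
        if not 0 < self.polyT_mean_bound <= self.polyA_mean_bound:
            raise ValueError("mean bounds must be ordered and positive")


def base_to_sample(record: ReadRecord, base_index: int) -> int:
    """Raw-sample coordinate at which a called base starts.

    The sample index is where the cumulative move count first reaches
    ``base_index + 1``, offset by the translocation table's start sample.
    Bases merged into one multi-move block share that block's start.
    """
    table = record.translocation
    if not 0 <= base_index < table.total_moves:
        raise IndexError(f"base index {base_index} outside 0..{table.total_moves - 1}")
    cum_moves = 0
    cum_samples = 0
    for n, m in table.blocks:
        if cum_moves + m > base_index:
            return table.start_sample + cum_samples
        cum_moves += m
        cum_samples += n
    raise IndexError(base_index)  # pragma: no cover - guarded above


@dataclass
class PreparedSignal:
    """Absolute z-normalised signal with the tail near its start."""

    signal: np.ndarray  # |z|, index-reversed for poly(A) reads
    rough_start: int  # in the (possibly reversed) coordinate system
    reversed: bool


def prepare_dna_signal(
    record: ReadRecord, read_type: DnaReadType, primers: PrimerConfig,
    clip: float = 3.0,
) -> PreparedSignal | None:
    """Normalise the signal and anchor the rough tail start from the primer.

    For poly(T) reads the adapter end primer at the read start is aligned
    and its tail-adjacent end mapped to a sample through the move table.
    For poly(A) reads the reverse-complemented end primer near the read end
    anchors the tail end in raw coordinates; the signal is index-reversed
    (z-normalisation commutes with reversal) so the tail again follows the
    rough start.
    """
    seq = record.sequence
    z = np.abs(znormalize_clip(record.raw_signal, clip))
    if read_type is DnaReadType.POLYT:
        hit = local_align(primers.end_primer, seq[: primers.primer_prefix])
        if hit.score <= 0:
            return None
        b = hit.subject_span[1]  # first base after the primer = first tail base
        if b >= record.translocation.total_moves:
            return None
        rough = base_to_sample(record, b)
        return PreparedSignal(z, rough, reversed=False)
    if read_type is DnaReadType.POLYA:
        suffix = seq[-primers.end_check_suffix :]
        offset = len(seq) - len(suffix)
        hit = local_align(reverse_complement(primers.end_primer), suffix)
        if hit.score <= 0:
            return None
        b = offset + hit.subject_span[0]  # first primer base, just after the tail
        if b >= record.translocation.total_moves:
            b = record.translocation.total_moves - 1
        tail_end_raw = base_to_sample(record, b)
        rough = record.raw_signal.size - tail_end_raw
        return PreparedSignal(z[::-1], max(rough, 0), reversed=True)
    raise ValueError(f"cannot prepare signal for read type {read_type}")


def find_precise_dna_tail(
    signal: np.ndarray,
    rough_start: int,
    read_type: DnaReadType,
    rate: float,
    config: DnaConfig | None = None,
) -> tuple[int, int] | None:
    """Precise tail bounds inside the search window after the rough start.

    Window means (and their consecutive differences as slopes) are computed
    over the search region. The precise start is the first window whose
    slope lies within +/- slope_bound and whose mean lies inside the
    tail-level band; the tentative end is the first later window violating
    either. Because short non-tail spikes occur, the scan continues: if
    another tail-like stretch of at least ``min_tail_run`` samples starts
    within ``max_gap_nt * rate`` samples of the tentative end, the end is
    moved past the spike (repeatedly, if configured).
    """
    config = config or DnaConfig()
    bound = (
        config.polyA_mean_bound if read_type is DnaReadType.POLYA else config.polyT_mean_bound
    )
    region = np.asarray(signal[rough_start : rough_start + config.search_window], dtype=float)
    w = config.mean_window
    n_win = region.size // w
    if n_win < 1:
        return None
    means = region[: n_win * w].reshape(n_win, w).mean(axis=1)
    # slope of window k is the step from window k-1; the first window has none
    slopes = np.concatenate(([0.0], np.diff(means)))
    ok = (np.abs(slopes) <= config.slope_bound) & (means > 0) & (means < bound)
    qualifying = np.flatnonzero(ok)
    if qualifying.size == 0:
        return None
    i0 = int(qualifying[0])
    run_needed = max(1, -(-config.min_tail_run // w))  # ceil in windows
    max_gap_win = (config.max_gap_nt * rate) / w

    def run_end(start: int) -> int:
        j = start
        while j < n_win and ok[j]:
            j += 1
        return j

    j_end = run_end(i0)
    while True:
        # next tail-like run of sufficient length after the tentative end
        j2 = j_end
        found = None
        while j2 < n_win:
            if ok[j2]:
                e = run_end(j2)
                if e - j2 >= run_needed:
                    found = (j2, e)
                    break
                j2 = e
            else:
                j2 += 1
        if found is None or (found[0] - j_end) > max_gap_win:
            break
        j_end = found[1]
        if not config.iterative_bridging:
            break
    return rough_start + i0 * w, rough_start + j_end * w


def estimate_dna_tail(
    record: ReadRecord,
    config: DnaConfig | None = None,
    primers: PrimerConfig | None = None,
    classification: ClassificationResult | None = None,
) -> TailEstimate:
    """Full DNA pipeline: classify, anchor, refine boundaries, convert to nt."""
    config = config or DnaConfig()
    if primers is None:
        from .defaults import default_primer_config

        primers = default_primer_config()
    est = TailEstimate(
        read_id=record.read_id,
        file_path=record.source_path,
        basecall_model=record.basecall_model.value,
    )
    cls = classification or classify_dna_read(record, primers)
    est.read_type = cls.read_type.value
    if cls.read_type is DnaReadType.TRUNCATED:
        est.failure_reason = "truncated"
        return est
    if cls.read_type is DnaReadType.UNCLASSIFIED:
        est.failure_reason = "unclassified"
        return est
    try:
        prep = prepare_dna_signal(record, cls.read_type, primers, config.znorm_clip)
    except ValueError as exc:
        est.failure_reason = str(exc)
        return est
    if prep is None:
        est.failure_reason = "primer_unmappable"
        return est
    try:
        rate = select_rate(record)
    except Exception as exc:  # noqa: BLE001 - recorded in the row, not raised
        est.failure_reason = f"rate_error:{exc}"
        return est
    bounds = find_precise_dna_tail(
        prep.signal, prep.rough_start, cls.read_type, rate.samples_per_nt, config
    )
    if bounds is None or bounds[1] <= bounds[0]:
        est.failure_reason = "no_tail_signal"
        return est
    start, end = bounds
    if prep.reversed:  # map back to the original raw-signal coordinates
        n = record.raw_signal.size
        start, end = n - bounds[1], n - bounds[0]
    est.found = True
    est.tail_start = int(start)
    est.tail_end = int(end)
    est.samples_per_nt = rate.samples_per_nt
    est.tail_length_nt = (est.tail_end - est.tail_start) / rate.samples_per_nt
    return est
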