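"""Reading base-called FAST5 (HDF5) files.

A base-called FAST5 file stores, per read, the raw current trace (integer
DAC counts), the base-called nucleotide sequence, and a table linking raw
samples to called bases: either a per-event table (standard model
base-calling; variable-length signal blocks, each annotated with a move
count) or a fixed-stride 0/1 move vector (flip-flop model base-calling).
This module normalises both layouts into a single :class:`TranslocationTable`
and tolerates the single-read and multi-read HDF5 dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "BasecallModel",
    "ExperimentType",
    "TranslocationTable",
    "ReadRecord",
    "Fast5ReadError",
    "read_fast5",
    "unify_flipflop_moves",
]


class BasecallModel(str, Enum):
    STANDARD = "standard"
    FLIPFLOP = "flipflop"


class ExperimentType(str, Enum):
    RNA = "rna"
    DNA = "dna"


class Fast5ReadError(Exception):
    """A single read could not be extracted; carries a machine-readable reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class TranslocationTable:
    """Ordered (n_samples, move) blocks linking raw samples to called bases.

    Blocks are contiguous in signal order; ``start_sample`` is the 0-based
    raw-signal index of the first block (the un-base-called adapter/leader
    signal precedes it). All coordinates are half-open.
    """

    blocks: tuple[tuple[int, int], ...]
    start_sample: int = 0

    def __post_init__(self) -> None:
        for n, m in self.blocks:
            if n <= 0:
                raise ValueError(f"block with non-positive sample count: {n}")
            if m < 0:
                raise ValueError(f"negative move count: {m}")

    @property
    def total_samples(self) -> int:
        return int(sum(n for n, _ in self.blocks))

    @property
    def total_moves(self) -> int:
        return int(sum(m for _, m in self.blocks))

    def sample_lengths(self) -> np.ndarray:
        return np.asarray([n for n, _ in self.blocks], dtype=float)

    def moves(self) -> np.ndarray:
        return np.asarray([m for _, m in self.blocks], dtype=int)


@dataclass
class ReadRecord:
    """One sequencing read as extracted from a FAST5 file."""

    read_id: str
    raw_signal: np.ndarray
    sequence: str
    translocation: TranslocationTable
    basecall_model: BasecallModel
    experiment_type: ExperimentType
    source_path: str = ""
    sampling_rate: float = 0.0

    def __post_init__(self) -> None:
        self.raw_signal = np.asarray(self.raw_signal)
        if self.raw_signal.size < 1:
            raise ValueError("empty raw signal")
        if len(self.sequence) < 1:
            raise ValueError("empty sequence")
        if self.translocation.total_moves != len(self.sequence):
            raise ValueError(
                "translocation move count "
                f"({self.translocation.total_moves}) does not match sequence "
                f"length ({len(self.sequence)})"
            )
        covered = self.translocation.start_sample + self.translocation.total_samples
        if covered > self.raw_signal.size:
            raise ValueError(
                f"translocation table covers {covered} samples but signal has "
                f"only {self.raw_signal.size}"
            )


def unify_flipflop_moves(
    move_vector: Sequence[int] | np.ndarray, block_stride: int
) -> TranslocationTable:
    """Collapse a fixed-stride 0/1 move vector into per-base dwell blocks.

    Each output block holds the total samples dwelt since the previous move
    (move-0 stride blocks are merged into the following move's dwell), with
    move=1. Leading blocks before the first move are attached to the first
    emitted block, so total signal coverage is conserved:
    ``block_stride * len(move_vector)`` samples.
    """
    moves = np.asarray(move_vector, dtype=int)
    if moves.size == 0:
        raise Fast5ReadError("no_moves", "empty move vector")
    if block_stride < 1:
        raise ValueError("block_stride must be >= 1")
    hit = np.flatnonzero(moves > 0)
    if hit.size == 0:
        raise Fast5ReadError("no_moves", "all-zero move vector")
    # dwell for move i spans from the previous move's block to just before
    # the next move's block; the tail of the vector belongs to the last move
    starts = np.concatenate(([0], hit[1:]))
    ends = np.concatenate((hit[1:], [moves.size]))
    blocks = tuple(
        (int((e - s) * block_stride), int(moves[h])) for s, e, h in zip(starts, ends, hit)
    )
    return TranslocationTable(blocks=blocks)


# candidate HDF5 paths, probed in order (paths varied across base-caller
# versions; the list is overridable by callers)
_BASECALL_GROUP_CANDIDATES = ("Analyses",)
_DEFAULT_RAW_SCALE = 1.0


def _decode(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def _fastq_sequence(fastq: str) -> str:
    lines = fastq.splitlines()
    if len(lines) < 2:
        raise Fast5ReadError("malformed_fastq")
    return lines[1].strip().upper().replace("U", "T")


def _find_basecall_group(analyses: h5py.Group, which: str | None = None) -> h5py.Group:
    names = sorted(n for n in analyses if n.startswith("Basecall_1D_"))
    if not names:
        raise Fast5ReadError("no_basecall_group")
    if which is not None:
        if which not in analyses:
            raise Fast5ReadError("no_basecall_group", which)
        return analyses[which]
    return analyses[names[-1]]  # highest-numbered group by default


def _events_to_table(events: np.ndarray, start_sample: int) -> TranslocationTable:
    if "length" not in events.dtype.names or "move" not in events.dtype.names:
        raise Fast5ReadError("no_translocation_table", "events table lacks length/move")
    lengths = np.asarray(events["length"], dtype=int)
    moves = np.asarray(events["move"], dtype=int)
    if moves.sum() == 0:
        raise Fast5ReadError("no_moves")
    # merge move-0 events into the preceding move's dwell (same convention as
    # unify_flipflop_moves) so every block carries >= 1 move and total time is
    # conserved; leading move-0 events attach to the first move's block
    blocks: list[tuple[int, int]] = []
    pending = 0
    for n, m in zip(lengths, moves):
        if m == 0:
            if blocks:
                pn, pm = blocks[-1]
                blocks[-1] = (pn + int(n), pm)
            else:
                pending += int(n)
        else:
            blocks.append((pending + int(n), int(m)))
            pending = 0
    return TranslocationTable(blocks=tuple(blocks), start_sample=start_sample)


def _extract_read(
    grp: h5py.Group,
    path: str,
    experiment_type: ExperimentType | None,
    basecall_group: str | None,
) -> ReadRecord:
    """Extract one read from its per-read HDF5 group (either dialect)."""
    # raw signal
    if "Raw" in grp and "Signal" in grp["Raw"]:
        raw_grp = grp["Raw"]
    elif "Raw" in grp and "Reads" in grp["Raw"]:
        reads = grp["Raw/Reads"]
        raw_grp = reads[next(iter(reads))]
    else:
        raise Fast5ReadError("no_raw_signal")
    signal = np.asarray(raw_grp["Signal"])
    read_id = _decode(raw_grp.attrs.get("read_id", grp.name.rsplit("/", 1)[-1]))

    sampling_rate = 0.0
    for cand in ("channel_id", "UniqueGlobalKey/channel_id"):
        if cand in grp:
            sampling_rate = float(grp[cand].attrs.get("sampling_rate", 0.0))
            break

    if "Analyses" not in grp:
        raise Fast5ReadError("no_basecall_group")
    analyses = grp["Analyses"]
    bc = _find_basecall_group(analyses, basecall_group)
    if "BaseCalled_template" not in bc:
        raise Fast5ReadError("no_basecall_group", "no BaseCalled_template")
    tmpl = bc["BaseCalled_template"]
    if "Fastq" not in tmpl:
        raise Fast5ReadError("no_basecall_group", "no Fastq dataset")
    sequence = _fastq_sequence(_decode(tmpl["Fastq"][()]))

    start_sample = 0
    for seg in sorted(n for n in analyses if n.startswith("Segmentation_")):
        summ = analyses[seg].get("Summary/segmentation")
        if summ is not None:
            start_sample = int(summ.attrs.get("first_sample_template", 0))

    if "Move" in tmpl:
        stride = None
        summ = bc.get("Summary/basecall_1d_template")
        if summ is not None and "block_stride" in summ.attrs:
            stride = int(summ.attrs["block_stride"])
        if stride is None:
            stride = int(bc.attrs.get("block_stride", 0)) or None
        if stride is None:
            raise Fast5ReadError("no_translocation_table", "Move vector without stride")
        table = unify_flipflop_moves(np.asarray(tmpl["Move"]), stride)
        table = TranslocationTable(blocks=table.blocks, start_sample=start_sample)
        model = BasecallModel.FLIPFLOP
    elif "Events" in tmpl:
        table = _events_to_table(np.asarray(tmpl["Events"]), start_sample)
        model = BasecallModel.STANDARD
    else:
        raise Fast5ReadError("no_translocation_table")

    if experiment_type is None:
        tag = None
        for cand in ("context_tags", "UniqueGlobalKey/context_tags"):
            if cand in grp:
                tag = grp[cand].attrs.get("experiment_type")
                break
        experiment_type = (
            ExperimentType(_decode(tag)) if tag is not None else ExperimentType.DNA
        )

    return ReadRecord(
        read_id=read_id,
        raw_signal=signal,
        sequence=sequence,
        translocation=table,
        basecall_model=model,
        experiment_type=experiment_type,
        source_path=path,
        sampling_rate=sampling_rate,
    )


@dataclass
class ReadFailure:
    """A read that could not be extracted, with its machine-readable reason."""

    read_id: str
    source_path: str
    reason: str


def _iter_read_groups(f: h5py.File) -> Iterator[tuple[str, h5py.Group]]:
    multi = [k for k in f if k.startswith("read_")]
    if multi:
        for k in sorted(multi):
            yield k[len("read_") :], f[k]
    else:
        # single-read layout: the file root plays the role of the read group
        yield f.filename, f["/"]


def read_fast5(
    path: str | Path,
    experiment_type: ExperimentType | str | None = None,
    basecall_group: str | None = None,
    failures: list[ReadFailure] | None = None,
) -> list[ReadRecord]:
    """Read every base-called read from a single- or multi-read FAST5 file.

    Reads that cannot be extracted (missing raw signal, base-call group or
    translocation data) are skipped with a logged warning; their reasons are
    appended to ``failures`` when a list is supplied.
    """
    path = str(path)
    if experiment_type is not None and not isinstance(experiment_type, ExperimentType):
        experiment_type = ExperimentType(experiment_type)
    records: list[ReadRecord] = []
    with h5py.File(path, "r") as f:
        for rid, grp in _iter_read_groups(f):
            try:
                records.append(_extract_read(grp, path, experiment_type, basecall_group))
            except Fast5ReadError as exc:
                log.warning("skipping read %s in %s: %s", rid, path, exc)
                if failures is not None:
                    failures.append(ReadFailure(rid, path, exc.reason))
    return records
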