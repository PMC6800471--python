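"""Synthetic nanopore squiggle generation with known ground truth.

The simulator emits reads with the structural elements the estimators key
on: an un-base-called adapter/leader signal block, a low-variance
homopolymer tail block at a characteristic normalized level, a
heterogeneous per-base body, per-nucleotide dwell times with stochastic
stalling, and a translocation table consistent with the signal (standard
events table or flip-flop move vector). Base-caller behaviour over
homopolymers is emulated by undercalling the tail: only a fraction of tail
nucleotides are "called", each carrying a proportionally inflated dwell,
exactly the effect that motivates translocation-rate normalization.

Signal levels are designed in z-units and converted to integer DAC counts;
the non-tail called levels are affinely adjusted per read so that the full
trace has zero mean and unit variance (noise included), which pins the
adapter and tail blocks at their nominal z-levels after the estimator's
own z-normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .align import DnaReadType, reverse_complement
from .defaults import (
    BARCODES,
    DNA_LEVELS,
    END_PRIMER,
    FRONT_PRIMER,
    REFERENCE_BODY,
    RNA_LEVELS,
)
from .fast5 import (
    BasecallModel,
    ExperimentType,
    ReadRecord,
    TranslocationTable,
    unify_flipflop_moves,
)

__all__ = ["SimParams", "SyntheticTruth", "simulate_read", "write_fixture_fast5", "simulate_cohort"]

SAMPLING_RATE = {"rna": 3012.0, "dna": 4000.0}

# adapter/leader signal blocks preceding the base-called region, as
# (n_samples, z_level); the RNA adapter shows the above/below-threshold
# signature the rough segmentation matches
RNA_ADAPTER = ((1500, 1.2), (1500, -1.5))
DNA_LEADER = ((800, -1.8),)


@dataclass
class SimParams:
    """Study conditions for one simulated read. Defaults are the realistic
    operating point; tests for ideal reads override the noise knobs."""

    tail_length_nt: int = 100
    experiment_type: ExperimentType = ExperimentType.RNA
    strand: DnaReadType = DnaReadType.POLYA  # DNA only
    rate_mean: float | None = None  # samples/nt; None -> 35 (RNA) or 8.5 (DNA)
    dwell_cv: float = 0.3  # per-nucleotide dwell variability (log-normal)
    noise_sd: float = 5.0  # per-sample Gaussian noise, raw DAC units
    stall_prob: float = 0.01  # chance a nucleotide stalls in the pore
    stall_scale: float = 5.0  # dwell multiplier when stalled
    tail_level_z: float | None = None  # None -> 0.89 RNA / 0.45 poly(A) / 0.15 poly(T)
    tail_call_fraction: float = 0.25  # fraction of tail nts the base-caller calls
    basecall_model: BasecallModel = BasecallModel.STANDARD
    barcode: str = "BC01"
    body_length: int = 750
    move2_prob: float = 0.03  # standard model: unresolved double translocations
    overseg_prob: float = 0.2  # flip-flop: extra move inside tail/long dwells
    flipflop_stride: int = 2
    raw_scale: float = 25.0  # DAC counts per z-unit
    raw_offset: float = 450.0
    seed: int = 0

    def resolved(self) -> "SimParams":
        p = replace(self)
        if not isinstance(p.experiment_type, ExperimentType):
            p.experiment_type = ExperimentType(p.experiment_type)
        if not isinstance(p.strand, DnaReadType):
            p.strand = DnaReadType(p.strand)
        if not isinstance(p.basecall_model, BasecallModel):
            p.basecall_model = BasecallModel(p.basecall_model)
        if p.rate_mean is None:
            p.rate_mean = 35.0 if p.experiment_type is ExperimentType.RNA else 8.5
        if p.tail_level_z is None:
            if p.experiment_type is ExperimentType.RNA:
                p.tail_level_z = 0.89
            else:
                p.tail_level_z = 0.45 if p.strand is DnaReadType.POLYA else 0.15
        if p.rate_mean <= 0:
            raise ValueError("rate_mean must be positive")
        return p


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each simulated read."""

    read_id: str
    true_tail_start: int  # raw-sample coordinates of the tail block
    true_tail_end: int
    true_tail_length_nt: int
    true_rate: float  # realized tail samples per nucleotide
    barcode: str
    read_type: str  # rna | polyA | polyT
    short_tail_warning: bool = False


@dataclass
class _Call:
    base: str
    dwell: int  # samples
    in_tail: bool


def _draw_dwells(rng: np.random.Generator, n: int, p: SimParams, min_dwell: int) -> np.ndarray:
    """Integer per-nucleotide dwells: rate * LogNormal(0, sigma) with stalls.

    sigma is chosen so the log-normal's coefficient of variation equals
    dwell_cv; its geometric mean is exactly 1, so the realized geometric
    mean dwell matches rate_mean (the quantity the estimator recovers).
    """
    if n == 0:
        return np.zeros(0, dtype=int)
    if p.dwell_cv > 0:
        sigma = math.sqrt(math.log(1.0 + p.dwell_cv**2))
        mult = rng.lognormal(0.0, sigma, size=n)
    else:
        mult = np.ones(n)
    if p.stall_prob > 0:
        stalled = rng.random(n) < p.stall_prob
        mult = np.where(stalled, mult * p.stall_scale, mult)
    d = np.maximum(np.rint(p.rate_mean * mult).astype(int), min_dwell)
    return d


def _partition(total: int, k: int, minimum: int) -> list[int]:
    """Split ``total`` samples into k near-equal integer parts >= minimum."""
    base_part = total // k
    parts = [base_part] * k
    for i in range(total - base_part * k):
        parts[i] += 1
    if base_part < minimum:  # degenerate, extremely short tails
        parts = [max(x, minimum) for x in parts]
    return parts


def _build_calls(p: SimParams, rng: np.random.Generator) -> tuple[list[_Call], int, str]:
    """Per-called-base (base, dwell) list in SIGNAL order, plus tail span.

    Returns (calls, tail_span_samples, read_type). The tail block's true
    span is drawn from the full tail_length_nt dwells; the undercalled tail
    bases partition that span so total time is conserved.
    """
    # flip-flop tables need one stride block per call; DNA dwells are short
    min_dwell = 2 if p.experiment_type is ExperimentType.DNA else 1
    if p.basecall_model is BasecallModel.FLIPFLOP:
        min_dwell = max(min_dwell, p.flipflop_stride)
    body = REFERENCE_BODY[: p.body_length]
    barcode = BARCODES[p.barcode] if p.barcode in BARCODES else p.barcode
    L = p.tail_length_nt
    true_dwells = _draw_dwells(rng, L, p, min_dwell)
    tail_span = int(true_dwells.sum())
    k_called = max(1, round(p.tail_call_fraction * L)) if L > 0 else 0
    tail_parts = _partition(tail_span, k_called, min_dwell) if k_called else []

    def calls_for(seq: str) -> list[_Call]:
        dw = _draw_dwells(rng, len(seq), p, min_dwell)
        return [_Call(b, int(d), False) for b, d in zip(seq, dw)]

    if p.experiment_type is ExperimentType.RNA:
        # sequence 5'->3' is barcode+body+A^k but RNA translocates 3'->5':
        # signal order is tail first, then body reversed, then barcode reversed
        tail_calls = [_Call("A", d, True) for d in tail_parts]
        rest = calls_for((barcode + body)[::-1])
        return tail_calls + rest, tail_span, "rna"
    # DNA: signal order equals sequence order
    if p.strand is DnaReadType.POLYA:
        head = calls_for(FRONT_PRIMER + barcode + body)
        tail_calls = [_Call("A", d, True) for d in tail_parts]
        end = calls_for(reverse_complement(END_PRIMER))
        return head + tail_calls + end, tail_span, "polyA"
    head = calls_for(END_PRIMER)
    tail_calls = [_Call("T", d, True) for d in tail_parts]
    rest = calls_for(reverse_complement(FRONT_PRIMER + barcode + body))
    return head + tail_calls + rest, tail_span, "polyT"


def _render_standard(
    calls: list[_Call], p: SimParams, rng: np.random.Generator
) -> tuple[list[_Call], TranslocationTable]:
    """Standard-model table with occasional unresolved move-2 translocations.

    Blocks are kept in the unified form (every block carries its move); the
    FAST5 writer re-splits long blocks into move-0 events for the on-disk
    events-table dialect.
    """
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < len(calls):
        dwell, move = calls[i].dwell, 1
        if (
            i + 1 < len(calls)
            and p.move2_prob > 0
            and rng.random() < p.move2_prob
            and not calls[i].in_tail
            and not calls[i + 1].in_tail
        ):
            dwell += calls[i + 1].dwell
            move = 2
            i += 1
        blocks.append((dwell, move))
        i += 1
    return calls, TranslocationTable(blocks=tuple(blocks))


def _render_flipflop(
    calls: list[_Call], p: SimParams, rng: np.random.Generator
) -> tuple[list[_Call], np.ndarray]:
    """Flip-flop move vector; over-segmentation duplicates homopolymer calls.

    Extra moves are inserted inside tail calls and unusually long dwells
    (the base-caller "sees" additional translocations there), which adds the
    corresponding duplicate bases to the called sequence.
    """
    stride = p.flipflop_stride
    out: list[_Call] = []
    for c in calls:
        split = (
            c.dwell >= 2 * stride
            and p.overseg_prob > 0
            and (c.in_tail or c.dwell > 1.5 * p.rate_mean)
            and rng.random() < p.overseg_prob
        )
        if split:
            d1 = c.dwell // 2
            out.append(_Call(c.base, d1, c.in_tail))
            out.append(_Call(c.base, c.dwell - d1, c.in_tail))
        else:
            out.append(c)
    total = sum(c.dwell for c in out)
    pad = (-total) % stride
    if pad:  # keep total dwell an exact number of stride blocks
        out[-1] = _Call(out[-1].base, out[-1].dwell + pad, out[-1].in_tail)
        total += pad
    n_blocks = total // stride
    moves = np.zeros(n_blocks, dtype=np.uint8)
    pos = 0
    for c in out:
        blk = min(pos // stride, n_blocks - 1)
        while blk < n_blocks and moves[blk]:  # two starts in one block: carry on
            blk += 1
        if blk >= n_blocks:
            raise ValueError("dwells shorter than the flip-flop stride")
        moves[blk] = 1
        pos += c.dwell
    return out, moves


def _design_signal(
    calls: list[_Call],
    tail_span: int,
    p: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Assemble the z-space trace and convert to DAC counts.

    Returns (raw int16 signal, tail_start, tail_end) in raw coordinates.
    Adapter and tail blocks keep their nominal z-levels; the remaining
    called levels are affinely adjusted so the whole trace (noise included)
    has zero mean and unit variance.
    """
    levels = RNA_LEVELS if p.experiment_type is ExperimentType.RNA else DNA_LEVELS
    adapter = RNA_ADAPTER if p.experiment_type is ExperimentType.RNA else DNA_LEADER
    pieces: list[tuple[int, float, bool]] = [(n, lv, True) for n, lv in adapter]
    tail_seen = False
    tail_start = sum(n for n, _ in adapter)
    pos = tail_start
    for c in calls:
        if c.in_tail:
            if not tail_seen:
                tail_start = pos
                tail_seen = True
            pieces.append((c.dwell, p.tail_level_z, True))
        else:
            pieces.append((c.dwell, levels[c.base], False))
        pos += c.dwell
    tail_end = tail_start + tail_span if tail_seen else tail_start

    n_total = sum(n for n, _, _ in pieces)
    nf = sum(n for n, _, f in pieces if f)
    sf = sum(n * lv for n, lv, f in pieces if f)
    qf = sum(n * lv * lv for n, lv, f in pieces if f)
    na = n_total - nf
    sa = sum(n * lv for n, lv, f in pieces if not f)
    qa = sum(n * lv * lv for n, lv, f in pieces if not f)
    noise_z = p.noise_sd / p.raw_scale
    target = n_total * max(1.0 - noise_z**2, 0.1)
    a, b = 1.0, 0.0
    if na > 0:
        var_a = qa - sa * sa / na
        num = target - qf - sf * sf / na
        if var_a > 1e-9 and num > 0:
            a = math.sqrt(num / var_a)
            b = -(sf + a * sa) / na
        else:  # degenerate composition: only centre the trace
            b = -(sf + sa) / na

    z = np.empty(n_total)
    pos = 0
    for n, lv, f in pieces:
        z[pos : pos + n] = lv if f else a * lv + b
        pos += n
    if noise_z > 0:
        z = z + rng.normal(0.0, noise_z, size=n_total)
    raw = np.rint(z * p.raw_scale + p.raw_offset)
    raw = np.clip(raw, np.iinfo(np.int16).min, np.iinfo(np.int16).max).astype(np.int16)
    return raw, tail_start, tail_end


def simulate_read(params: SimParams) -> tuple[ReadRecord, SyntheticTruth]:
    """Generate one read and its ground truth, fully determined by the seed."""
    p = params.resolved()
    ss = np.random.SeedSequence(p.seed)
    core_rng, table_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    calls, tail_span, read_type = _build_calls(p, core_rng)
    if p.basecall_model is BasecallModel.FLIPFLOP:
        calls, moves = _render_flipflop(calls, p, table_rng)
        table = None
    else:
        calls, table = _render_standard(calls, p, table_rng)
        moves = None
    raw, tail_start, tail_end = _design_signal(calls, tail_span, p, core_rng)

    adapter_len = sum(n for n, _ in (RNA_ADAPTER if p.experiment_type is ExperimentType.RNA else DNA_LEADER))
    if table is not None:
        table = TranslocationTable(blocks=table.blocks, start_sample=adapter_len)
    else:
        table = unify_flipflop_moves(moves, p.flipflop_stride)
        table = TranslocationTable(blocks=table.blocks, start_sample=adapter_len)

    signal_order = "".join(c.base for c in calls)
    sequence = signal_order[::-1] if p.experiment_type is ExperimentType.RNA else signal_order
    read_id = f"sim-{p.seed:08d}-{read_type}-{p.tail_length_nt}"
    record = ReadRecord(
        read_id=read_id,
        raw_signal=raw,
        sequence=sequence,
        translocation=table,
        basecall_model=p.basecall_model,
        experiment_type=p.experiment_type,
        sampling_rate=SAMPLING_RATE[p.experiment_type.value],
    )
    mean_window = 25 if p.experiment_type is ExperimentType.RNA else 10
    truth = SyntheticTruth(
        read_id=read_id,
        true_tail_start=tail_start,
        true_tail_end=tail_end,
        true_tail_length_nt=p.tail_length_nt,
        true_rate=tail_span / p.tail_length_nt if p.tail_length_nt else float("nan"),
        barcode=p.barcode,
        read_type=read_type,
        short_tail_warning=0 < tail_span < mean_window,
    )
    return record, truth


def write_fixture_fast5(
    items: Sequence[tuple[ReadRecord, SyntheticTruth]],
    path: str | Path,
    layout: str = "multi",
) -> Path:
    """Write reads to a minimal FAST5 dialect plus a truth CSV sidecar.

    ``layout`` selects the multi-read dialect (one ``read_<id>`` group per
    read) or the legacy single-read dialect (one read per file; additional
    reads then go to numbered sibling files).
    """
    if not items:
        raise ValueError("no reads to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def write_read(root: h5py.Group, rec: ReadRecord, single: bool) -> None:
        if single:
            raw = root.create_group("Raw/Reads/Read_0")
            keys = root.create_group("UniqueGlobalKey")
            chan = keys.create_group("channel_id")
            ctx = keys.create_group("context_tags")
        else:
            raw = root.create_group("Raw")
            chan = root.create_group("channel_id")
            ctx = root.create_group("context_tags")
        raw.create_dataset("Signal", data=rec.raw_signal.astype(np.int16))
        raw.attrs["read_id"] = rec.read_id
        chan.attrs["sampling_rate"] = float(rec.sampling_rate)
        ctx.attrs["experiment_type"] = rec.experiment_type.value
        analyses = root.create_group("Analyses")
        seg = analyses.create_group("Segmentation_000/Summary/segmentation")
        seg.attrs["first_sample_template"] = rec.translocation.start_sample
        bc = analyses.create_group("Basecall_1D_000")
        tmpl = bc.create_group("BaseCalled_template")
        fastq = f"@{rec.read_id}\n{rec.sequence}\n+\n{'!' * len(rec.sequence)}\n"
        tmpl.create_dataset("Fastq", data=fastq)
        if rec.basecall_model is BasecallModel.FLIPFLOP:
            # the largest stride consistent with the dwell blocks round-trips
            stride = math.gcd(*[n for n, _ in rec.translocation.blocks])
            moves = np.concatenate(
                [[1] + [0] * (n // stride - 1) for n, _ in rec.translocation.blocks]
            ).astype(np.uint8)
            tmpl.create_dataset("Move", data=moves)
            summ = bc.create_group("Summary/basecall_1d_template")
            summ.attrs["block_stride"] = stride
        else:
            # on disk, long dwell blocks become several events whose trailing
            # rows carry move 0, as standard-model base-callers emit them;
            # the reader merges these back into unified blocks
            chunk = 25
            lengths: list[int] = []
            mv: list[int] = []
            for n, m in rec.translocation.blocks:
                n_ev = max(1, math.ceil(n / chunk))
                sizes = _partition(n, n_ev, 1)
                lengths.extend(sizes)
                mv.extend([m] + [0] * (n_ev - 1))
            starts = rec.translocation.start_sample + np.concatenate(
                ([0], np.cumsum(lengths)[:-1])
            )
            events = np.zeros(
                len(lengths),
                dtype=[("start", "<u8"), ("length", "<u4"), ("move", "u1")],
            )
            events["start"] = starts
            events["length"] = lengths
            events["move"] = mv
            tmpl.create_dataset("Events", data=events)

    if layout == "multi":
        with h5py.File(path, "w") as f:
            for rec, _ in items:
                write_read(f.create_group(f"read_{rec.read_id}"), rec, single=False)
        paths = [path]
    elif layout == "single":
        paths = []
        for i, (rec, _) in enumerate(items):
            p_i = path if i == 0 else path.with_name(f"{path.stem}_{i}{path.suffix}")
            with h5py.File(p_i, "w") as f:
                write_read(f["/"], rec, single=True)
            paths.append(p_i)
    else:
        raise ValueError(f"unknown layout: {layout}")

    truth = pd.DataFrame([t.__dict__ for _, t in items])
    truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def simulate_cohort(
    groups: Sequence[tuple[int, int]] | Sequence[tuple[int, int, dict]],
    seed: int = 0,
    out_dir: str | Path | None = None,
    fasta: bool = True,
    **base_params,
) -> tuple[list[ReadRecord], list[SyntheticTruth]]:
    """Simulate a cohort of (tail_length, n[, overrides]) groups.

    Barcodes cycle through the default set per group (mirroring a barcoded
    spike-in pool). When ``out_dir`` is given, one FAST5 per group, a truth
    CSV per file and a combined FASTA are written.
    """
    records: list[ReadRecord] = []
    truths: list[SyntheticTruth] = []
    barcode_names = list(BARCODES)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    fasta_lines: list[str] = []
    for g, spec in enumerate(groups):
        length, n = spec[0], spec[1]
        overrides = dict(spec[2]) if len(spec) > 2 else {}
        group_items = []
        for i in range(n):
            kw = dict(base_params)
            kw.update(overrides)
            kw.setdefault("barcode", barcode_names[g % len(barcode_names)])
            p = SimParams(
                tail_length_nt=length,
                seed=int((seed * 1_000_003 + g * 7919 + i) % (2**31 - 1)),
                **kw,
            )
            rec, tr = simulate_read(p)
            rec.read_id = f"{rec.read_id}-g{g}r{i}"
            tr.read_id = rec.read_id
            group_items.append((rec, tr))
            fasta_lines.append(f">{rec.read_id}\n{rec.sequence}")
        if out_dir is not None:
            write_fixture_fast5(group_items, out_dir / f"group_{g}_len{length}.fast5")
        records.extend(r for r, _ in group_items)
        truths.extend(t for _, t in group_items)
    if out_dir is not None and fasta:
        (out_dir / "sequences.fasta").write_text("\n".join(fasta_lines) + "\n")
    return records, truths
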