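"""Local alignment, read-type classification and barcode demultiplexing.

All alignments use Smith–Waterman local alignment with match +1, mismatch
−1 and a linear gap model (gap opening 0, gap extension 1, so a gap of
length k costs k). Scores are normalised by the query length, giving a
value in [0, 1] that is comparable across queries; alignments below a
configurable threshold (default 0.6) are treated as unspecific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

if TYPE_CHECKING:  # pragma: no cover
    from .fast5 import ReadRecord

__all__ = [
    "AlignmentResult",
    "PrimerConfig",
    "DnaReadType",
    "DemuxResult",
    "local_align",
    "reverse_complement",
    "classify_dna_read",
    "demux_barcode_rna",
    "demux_barcode_dna",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# substitution matrix over ACGTN: +1 on ACGT identity, -1 otherwise.
# N (and any letter mapped onto it) mismatches everything, including itself.
_ALPHABET = "ACGTN"
_MATRIX = substitution_matrices.Array(_ALPHABET, dims=2, data=np.full((5, 5), -1.0))
for _i, _b in enumerate("ACGT"):
    _MATRIX[_b, _b] = 1.0

_KEEP = set(_ALPHABET)


def _sanitize(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= _KEEP:
        seq = "".join(c if c in _KEEP else "N" for c in seq)
    return seq


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one local alignment of ``query`` against ``subject``."""

    score: float
    normalized_score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (alphabet ACGTN, U -> A)."""
    return _sanitize(seq).translate(_COMPLEMENT)[::-1]


def local_align(query: str, subject: str) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment of query against subject.

    The normalised score divides the raw score by the query length. A pair
    with no positive-scoring local alignment yields score 0 with empty spans.
    """
    if not query or not subject:
        raise ValueError("empty_sequence")
    q, s = _sanitize(query), _sanitize(subject)
    score = float(_ALIGNER.score(q, s))
    if score <= 0:  # no positive-scoring local alignment exists
        return AlignmentResult(0.0, 0.0, (0, 0), (0, 0))
    best = _ALIGNER.align(q, s)[0]
    # align(q, s) -> aligned coordinate blocks come back as (first, second)
    q_blocks, s_blocks = best.aligned
    query_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    subject_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return AlignmentResult(score, score / len(q), query_span, subject_span)


@dataclass
class PrimerConfig:
    """Primer, probe and barcode sequences plus alignment thresholds.

    ``probe`` is a short anchor (for the original spike-in design, the first
    29 bases of the reference insert) used to locate the insert start for
    demultiplexing. ``score_threshold`` gates all specific alignments;
    ``orientation_threshold`` gates the DNA orientation call.
    """

    front_primer: str
    end_primer: str
    probe: str
    barcodes: dict[str, str] = field(default_factory=dict)
    score_threshold: float = 0.6
    orientation_threshold: float = 0.5
    primer_prefix: int = 100
    end_check_suffix: int = 50
    probe_search_prefix: int = 250

    def __post_init__(self) -> None:
        self.front_primer = _sanitize(self.front_primer)
        self.end_primer = _sanitize(self.end_primer)
        self.probe = _sanitize(self.probe)
        self.barcodes = {k: _sanitize(v) for k, v in self.barcodes.items()}
        if not 0 < self.score_threshold <= 1 or not 0 < self.orientation_threshold <= 1:
            raise ValueError("thresholds must lie in (0, 1]")

    @classmethod
    def from_files(
        cls, fasta_path: str | Path, thresholds: Mapping[str, float] | None = None
    ) -> "PrimerConfig":
        """Load sequences from a FASTA file plus optional threshold overrides.

        Records named ``front_primer``, ``end_primer`` and ``probe`` fill the
        corresponding fields; every other record is taken as a barcode.
        """
        seqs: dict[str, str] = {}
        name = None
        parts: list[str] = []
        for line in Path(fasta_path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
        if name is not None:
            seqs[name] = "".join(parts)
        special = {"front_primer", "end_primer", "probe"}
        missing = special - set(seqs)
        if missing:
            raise ValueError(f"primer FASTA lacks records: {sorted(missing)}")
        barcodes = {k: v for k, v in seqs.items() if k not in special}
        kwargs = dict(thresholds or {})
        return cls(
            front_primer=seqs["front_primer"],
            end_primer=seqs["end_primer"],
            probe=seqs["probe"],
            barcodes=barcodes,
            **kwargs,
        )


class DnaReadType(str, Enum):
    POLYA = "polyA"
    POLYT = "polyT"
    TRUNCATED = "truncated"
    UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationResult:
    read_type: DnaReadType
    front_score: float
    end_score: float
    end_check_score: float | None = None
    short_read: bool = False


def classify_dna_read(record: "ReadRecord", config: PrimerConfig) -> ClassificationResult:
    """Decide whether a DNA read carries its tail as poly(A) or poly(T).

    The two adapter primers are aligned against the read's first
    ``primer_prefix`` bases: whichever wins with a normalised score above the
    threshold sets the orientation (front primer -> poly(A), end primer ->
    poly(T)). Poly(A) candidates must additionally show the
    reverse-complemented end primer within their last ``end_check_suffix``
    bases; otherwise the tail was not captured and the read is truncated.
    """
    seq = _sanitize(record.sequence)
    short = len(seq) < config.primer_prefix
    head = seq[: config.primer_prefix]
    front = local_align(config.front_primer, head)
    end = local_align(config.end_primer, head)
    thr = config.score_threshold
    if front.normalized_score > end.normalized_score and front.normalized_score > thr:
        tail_probe = reverse_complement(config.end_primer)
        suffix = seq[-config.end_check_suffix :]
        check = local_align(tail_probe, suffix)
        if check.normalized_score < thr:
            return ClassificationResult(
                DnaReadType.TRUNCATED,
                front.normalized_score,
                end.normalized_score,
                check.normalized_score,
                short,
            )
        return ClassificationResult(
            DnaReadType.POLYA,
            front.normalized_score,
            end.normalized_score,
            check.normalized_score,
            short,
        )
    if end.normalized_score > front.normalized_score and end.normalized_score > thr:
        return ClassificationResult(
            DnaReadType.POLYT, front.normalized_score, end.normalized_score, None, short
        )
    return ClassificationResult(
        DnaReadType.UNCLASSIFIED, front.normalized_score, end.normalized_score, None, short
    )


@dataclass
class DemuxResult:
    barcode: str | None
    reason: str = ""
    probe_score: float = 0.0
    barcode_score: float = 0.0
    read_type: DnaReadType | None = None


def _assign_barcode(region: str, config: PrimerConfig) -> DemuxResult:
    """Pick the best-scoring barcode in a region; exact ties are ambiguous."""
    if not region:
        return DemuxResult(None, reason="no_barcode_region")
    scored = sorted(
        ((local_align(bc, region).normalized_score, name) for name, bc in config.barcodes.items()),
        reverse=True,
    )
    if not scored or scored[0][0] <= config.score_threshold:
        return DemuxResult(None, reason="no_barcode", barcode_score=scored[0][0] if scored else 0.0)
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return DemuxResult(None, reason="ambiguous", barcode_score=scored[0][0])
    return DemuxResult(scored[0][1], barcode_score=scored[0][0])


def demux_barcode_rna(record: "ReadRecord", config: PrimerConfig) -> DemuxResult:
    """Assign a barcode to an RNA read.

    The probe is located within the read's first ``probe_search_prefix``
    bases; barcodes are then aligned against the subsequence preceding the
    probe hit, and the best one above the threshold wins.
    """
    seq = _sanitize(record.sequence)
    head = seq[: config.probe_search_prefix]
    probe_hit = local_align(config.probe, head)
    if probe_hit.normalized_score <= config.score_threshold:
        return DemuxResult(None, reason="no_probe", probe_score=probe_hit.normalized_score)
    region = seq[: probe_hit.subject_span[0]]
    res = _assign_barcode(region, config)
    res.probe_score = probe_hit.normalized_score
    return res


def demux_barcode_dna(record: "ReadRecord", config: PrimerConfig) -> DemuxResult:
    """Assign a barcode to a DNA read, resolving its strand first.

    Orientation is decided by aligning the probe and its reverse complement
    against the first ``probe_search_prefix`` bases (threshold
    ``orientation_threshold``). For inserts long enough that a poly(T)
    read's reverse-complemented probe lies beyond that prefix, the reverse
    complement is additionally sought in the last ``probe_search_prefix``
    bases. Poly(T) reads are then reverse-complemented and demultiplexed
    through the poly(A) path, which makes the assignment strand-symmetric.
    """
    seq = _sanitize(record.sequence)
    head = seq[: config.probe_search_prefix]
    fwd = local_align(config.probe, head)
    rc_probe = reverse_complement(config.probe)
    rev = local_align(rc_probe, head)
    thr = config.orientation_threshold
    read_type: DnaReadType | None = None
    if fwd.normalized_score > rev.normalized_score and fwd.normalized_score > thr:
        read_type = DnaReadType.POLYA
    elif rev.normalized_score > fwd.normalized_score and rev.normalized_score > thr:
        read_type = DnaReadType.POLYT
    else:
        tail250 = seq[-config.probe_search_prefix :]
        rev_tail = local_align(rc_probe, tail250)
        if rev_tail.normalized_score > thr:
            read_type = DnaReadType.POLYT
            rev = rev_tail
    if read_type is None:
        return DemuxResult(
            None,
            reason="no_orientation",
            probe_score=max(fwd.normalized_score, rev.normalized_score),
        )

    oriented = seq if read_type is DnaReadType.POLYA else reverse_complement(seq)
    head = oriented[: config.probe_search_prefix]
    probe_hit = local_align(config.probe, head)
    if probe_hit.normalized_score <= thr:
        # probe should be near the start in poly(A) orientation; for
        # reverse-complemented reads it may sit slightly deeper
        probe_hit = local_align(config.probe, oriented)
    if probe_hit.normalized_score <= thr:
        return DemuxResult(
            None,
            reason="no_probe",
            probe_score=probe_hit.normalized_score,
            read_type=read_type,
        )
    upstream = oriented[: probe_hit.subject_span[0]]
    primer_hit = local_align(config.front_primer, upstream) if upstream else None
    if primer_hit is None or primer_hit.normalized_score <= config.score_threshold:
        return DemuxResult(
            None,
            reason="no_front_primer",
            probe_score=probe_hit.normalized_score,
            read_type=read_type,
        )
    region = upstream[primer_hit.subject_span[1] :]
    res = _assign_barcode(region, config)
    res.probe_score = probe_hit.normalized_score
    res.read_type = read_type
    return res
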