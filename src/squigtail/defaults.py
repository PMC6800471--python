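"""Shipped default sequence set and signal-level tables.

The original spike-in experiments used proprietary adapter primers and an
eGFP carrier; those exact sequences are experiment-specific configuration,
so the package ships a synthetic but structurally equivalent default set: a
front and end adapter primer, six well-separated 8-nt barcodes, and a
750-nt reference insert whose first 29 bases serve as the demultiplexing
probe. The simulator uses the same set, so demultiplexing and estimation
are testable end to end. All sequences were generated once from a fixed
seed and are frozen here.
"""

from __future__ import annotations

from .align import PrimerConfig

__all__ = [
    "FRONT_PRIMER",
    "END_PRIMER",
    "BARCODES",
    "REFERENCE_BODY",
    "PROBE",
    "RNA_LEVELS",
    "DNA_LEVELS",
    "default_primer_config",
]

FRONT_PRIMER = "ACGCTCTGCTTTATCCATTGATAA"
END_PRIMER = "TCTACTATGTCACAGCTTACCTAT"

#: six barcodes, pairwise Hamming distance >= 5
BARCODES = {
    "BC01": "GGCCGCAC",
    "BC02": "TTATGTAT",
    "BC03": "AAAAATAG",
    "BC04": "TGGAGCGG",
    "BC05": "CAGGGGCA",
    "BC06": "CGACATTT",
}

#: synthetic 750-nt reference insert (no A homopolymer longer than 4, so the
#: insert body never mimics a poly(A) tail in simulated RNA signal)
REFERENCE_BODY = (
    "CAGCATGACCAGTGAGAGATAACGGCAAATGCTGGTTGAACGTTTTAGGAGTACTCCTGC"
    "CCGCTGCTGGTCTGTTAGGGTTCTCATGTCAATCCTCGCGTCGTTCGGCCACTTCACGCA"
    "CGCACGTAGGATGGTAGAGGCTTTCAATTGCTTGAGTTGTATTACGTTGGGACCACGACT"
    "ACACGTGCTGGATCCAAGCTAGTCGCAGACGCTATTACCCAGGAAGGAGAGTGGCGCTCG"
    "GAAAGCTGCGACTGGTCAGTCTCAAGACAAGTCCCTAAAACAGCATGGTATCTTTGCCGG"
    "GTCAATTTGCAACCACCGCCAGGTAATATTCGCCCACGTGTTACTCGACTCAACACCCCA"
    "AAGAACAGTTAGACTAGTTCATGGTTTATGCGGCGCAGGGAAACGCTTGACTAATCAAGG"
    "AAATAGGAAACAAAATAGAAATGTAAGAGAAAGTATGTGCCGCACGGGCTGCAATGTATA"
    "TAGGGGTGATAACAATATGAACACATTGTGTGGCCTAAGGCAACGCGGGTTAGAAATTGT"
    "AAGGCGATTATCGGTCGATGGACTTCGGATTACATTTACCCCTCTTGGTCGATGTACAAC"
    "GCACAGGTCGGGCCGCTTGGAATTGACGTCCGCGACGCATGTGGCGGGCAATGGACGCGA"
    "ATCGGTCTTAGGTTTGACTTGCCAATTTCCGACCCTGAAGAACCTAACTCGACGCCGGTG"
    "GGCGGCCTAGTTGTAGCTCTAAGACTGGGC"
)

PROBE = REFERENCE_BODY[:29]

#: per-base normalized (z-unit) current levels used by the RNA simulator;
#: the A level matches the expected homopolymer-A level of 0.89, and any two
#: levels differ by >= 0.8 so base steps break low-slope runs
RNA_LEVELS = {"A": 0.89, "G": 0.05, "C": -0.75, "T": -1.55}

#: DNA pore chemistry differs from RNA; all DNA body levels lie outside the
#: |z| < 0.6 tail acceptance band so non-tail sequence never looks tail-like
DNA_LEVELS = {"A": 1.2, "G": -1.0, "C": 0.8, "T": -1.4}


def default_primer_config(**overrides) -> PrimerConfig:
    """PrimerConfig for the shipped default sequence set."""
    kwargs = dict(
        front_primer=FRONT_PRIMER,
        end_primer=END_PRIMER,
        probe=PROBE,
        barcodes=dict(BARCODES),
    )
    kwargs.update(overrides)
    return PrimerConfig(**kwargs)
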