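# Methods

This note describes, in the package's own terms, how `squigtail` turns a
raw nanopore current trace into a poly(A)/poly(T) tail length, and how the
synthetic cohorts used for validation are constructed.

## 1. Signal model

A nanopore read is a vector of integer DAC counts sampled while a molecule
translocates the pore. A homopolymer tail produces a long, flat segment at
a characteristic current level, because every nucleotide in the pore is
identical. Base-callers undercall such segments, so the tail length must be
measured in the signal domain:

```
tail_length_nt = (tail_end_sample − tail_start_sample) / samples_per_nt
```

where `samples_per_nt` is a read-specific translocation rate. Everything
below is about finding the two boundaries and the rate robustly.

## 2. FAST5 extraction (`squigtail.fast5`)

Both the multi-read layout (`read_<id>/Raw/Signal`, `read_<id>/Analyses/…`)
and the legacy single-read layout (`Raw/Reads/Read_0/Signal`,
`UniqueGlobalKey/…`) are supported. From the highest-numbered
`Basecall_1D_*` group the called sequence (FASTQ, U→T) and the
signal-to-sequence mapping are read:

- **standard model** — an events table of variable-length signal blocks,
  each annotated with a move count (0, 1 or 2). Move-0 rows continue the
  preceding base and are merged into it.
- **flip-flop model** — a 0/1 move vector over fixed-stride signal blocks
  (detected via the `block_stride` attribute). Runs are unified to one
  block per called base; leading zero blocks attach to the first base.

Both dialects normalize to the same in-memory `TranslocationTable`
(`(n_samples, move)` blocks plus the segmentation start sample), so all
downstream code is dialect-agnostic. Unreadable reads become failure rows,
never exceptions.

## 3. Translocation rate (`squigtail.rate`)

The per-base dwell list is obtained by expanding each table block: a block
of `n` samples carrying `m` moves contributes `m` dwells of `n/m` (a
move-of-two splits its block in half). The rate is then:

- **standard tables**: the geometric mean of dwells. Dwell times are
  heavy-tailed (approximately log-normal); the geometric mean is the
  natural location parameter and resists stall outliers.
- **flip-flop tables**: a trimmed arithmetic mean discarding the
  `ceil(5%)` largest dwells. Flip-flop base-calling over-segments
  homopolymers (extra moves shorten apparent dwells) while stalls still
  inflate a few dwells; trimming the top tail corrects the asymmetry.

## 4. RNA pipeline (`squigtail.rna`)

1. **Normalize**: z-normalize the full trace (population SD) and clip to
   ±3 to bound outlier influence.
2. **Smooth**: moving averages with window 400 and stride 1, computed
   forward (trailing window) and backward (leading window), truncated at
   the edges, merged by point-wise maximum. The max-merge keeps plateau
   edges sharp on whichever side the window would otherwise smear.
3. **Rough segmentation**: threshold the smoothed trace at 0.3. The RNA
   adapter yields one above-threshold then one below-threshold segment at
   the trace start (an optional leading below-threshold stretch is
   skipped); the next above-threshold segment is the tail candidate.
4. **Refine**: inside the rough bounds, reduce the clipped z-signal to
   non-overlapping 25-sample window means; slopes are differences of
   consecutive means. The longest run with |slope| ≤ 0.3 (earliest run on
   ties) gives the precise bounds, end-inclusive of the final window.
5. **Convert** using the geometric-mean rate.

Flip-flop RNA is rejected by default (`flipflop_rna_unsupported`) because
current RNA base-callers emit events tables; `RnaConfig.allow_flipflop`
exists for future use.

## 5. DNA pipeline (`squigtail.dna`)

1. **Classify** (`squigtail.align.classify_dna_read`): align both adapter
   primers against the read's first 100 bases. Front primer wins →
   poly(A) candidate; end primer wins → poly(T). A poly(A) candidate must
   also show the reverse-complemented end primer within its last 50 bases,
   otherwise the tail was not sequenced (`truncated`). No specific hit →
   `unclassified`.
2. **Anchor**: for poly(T), the end-primer alignment's last base maps
   through the move table (`base_to_sample`, cumulative move counts) to a
   rough tail start. For poly(A) the reverse-complemented end primer near
   the read end anchors the tail *end*; the signal is index-reversed so
   the tail always follows the rough start (z-normalization commutes with
   reversal).
3. **Refine**: on the absolute clipped z-signal, scan a 3000-sample window
   after the rough start in non-overlapping 10-sample windows. A window is
   tail-like when |slope| ≤ 0.2 (the first window's slope counts as 0) and
   its mean lies in (0, 0.3) for poly(T) or (0, 0.6) for poly(A) — the
   wider band reflects the higher A-homopolymer level. The tail runs from
   the first qualifying window to the first violation.
4. **Spike bridging**: short non-tail spikes (current jumps) can split a
   real tail. If another tail-like run of ≥ 60 samples begins within
   `120 nt × rate` samples of the tentative end, the end moves past the
   spike; with `iterative_bridging` (default) this repeats.
5. **Convert** with the model-appropriate rate; poly(A) bounds are mapped
   back to original raw coordinates.

## 6. Demultiplexing (`squigtail.align`)

All alignments are Smith–Waterman with match +1, mismatch −1 and linear
gap cost (open 0, extend 1), over the alphabet ACGTN where N mismatches
everything (including itself). Scores are normalized by query length;
hits below 0.6 (0.5 for orientation decisions) are unspecific.

RNA: locate the probe (first 29 bases of the reference insert) in the first
250 bases; align every barcode against the subsequence before the probe
hit; best above-threshold barcode wins, exact ties are `ambiguous`.
DNA: orientation comes from probe vs reverse-complemented probe in the
first 250 bases; for long inserts, where a poly(T) read's probe copy sits
near the read *end*, the reverse complement is additionally sought in the
last 250 bases. Poly(T) reads are then reverse-complemented and pass
through the poly(A) path (front primer, then barcode between primer end
and probe start), making the assignment strand-symmetric by construction.

## 7. Simulator (`squigtail.sim`)

The simulator defines the study conditions; its parameters were fixed
before the estimators were evaluated and are never tuned to test outcomes.

Per read: per-nucleotide dwells are log-normal with geometric mean exactly
`rate_mean` (35 samples/nt RNA, 8.5 DNA) and CV `dwell_cv` (0.3), with
stalls (probability 0.01, ×5 dwell). Tail undercalling is modelled by
calling only `tail_call_fraction` (0.25) of tail nucleotides, the called
bases partitioning the true tail span so total dwell time is conserved —
exactly the effect that motivates rate normalization. Signal levels are
designed in z-units (RNA tail 0.89; DNA 0.45 poly(A) / 0.15 poly(T), i.e.
inside the detector's mean bands; adapter/leader and per-base body levels
fixed); the non-tail, non-adapter levels are affinely adjusted per read in
closed form so the full trace has mean 0 and variance 1 after noise
(Gaussian, 5 DAC counts at 25 counts/z), which pins adapter and tail
blocks at their nominal z-levels after the estimator's own normalization.
Standard rendering merges occasional neighbouring calls into move-2 blocks
(probability 0.03); flip-flop rendering over-segments tail/long dwells
(probability 0.2, duplicating called bases) and emits a stride-2 move
vector. Both renderings of one seed share the same underlying trace.
Fixture writing produces both FAST5 layouts plus a ground-truth CSV
sidecar and a FASTA of called sequences.

Deliberately out of scope: physically realistic k-mer pore models and
base-caller error models beyond what demultiplexing tests need.

## 8. Failure reasons

`file_error`, `no_raw_signal`, `no_basecall_group`, `malformed_fastq`,
`no_translocation_table`, `no_moves` (extraction);
`flipflop_rna_unsupported`, `flat_signal`,
`read_too_short`, `no_adapter_pattern`, `no_low_slope_run` (RNA);
`truncated`, `unclassified`, `primer_unmappable`, `no_tail_signal` (DNA);
`rate_error:<detail>` (either pipeline). Demultiplexing reports
`no_probe`, `no_barcode`, `no_barcode_region`, `no_front_primer`,
`no_orientation`, `ambiguous`.

## 9. Numerical and design decisions

- Population (not sample) SD in z-normalization: the trace is the full
  population of interest; the distinction is negligible at trace lengths
  anyway.
- Distribution mode in summaries: Gaussian-KDE argmax with Silverman
  bandwidth on a 512-point grid (median fallback for < 3 values or zero
  range); bandwidth is configurable.
- Estimates are not capped by default; `--cap` exists as a plotting
  convention only.
- Batch output is sorted by (file, read id), so serial and parallel runs
  are byte-identical.
- "Noise-free" in tests and the acceptance script means: no dwell
  variability, no signal noise, no stalls, fully called tails, no move-2
  merges, no over-segmentation — i.e. a perfectly base-called read. Under
  these conditions the estimators are exact up to boundary-window
  quantization (≤ one refinement window: 25 samples RNA, 10 DNA).
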