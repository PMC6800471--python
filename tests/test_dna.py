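"""DNA tail pipeline: coordinate mapping, anchoring, precise-boundary search."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from squigtail.align import DnaReadType
from squigtail.defaults import default_primer_config
from squigtail.dna import (
    DnaConfig,
    base_to_sample,
    estimate_dna_tail,
    find_precise_dna_tail,
    prepare_dna_signal,
)
from squigtail.fast5 import (
    BasecallModel,
    ExperimentType,
    ReadRecord,
    TranslocationTable,
)
from squigtail.sim import SimParams, simulate_read
from tests.conftest import ideal_params


def base_to_sample_oracle(blocks, start_sample, base_index):
    """Naive expansion: list each base's start sample, then index into it."""
    starts = []
    pos = start_sample
    for n, m in blocks:
        starts.extend([pos] * m)  # bases merged in one block share its start
        pos += n
    return starts[base_index]


def _record(blocks, start_sample=0, signal_len=None, sequence=None):
    table = TranslocationTable(blocks=tuple(blocks), start_sample=start_sample)
    n_moves = table.total_moves
    seq = sequence if sequence is not None else "A" * n_moves
    size = signal_len if signal_len is not None else start_sample + table.total_samples
    return ReadRecord(
        read_id="r",
        raw_signal=np.zeros(size, dtype=np.int16),
        sequence=seq,
        translocation=table,
        basecall_model=BasecallModel.STANDARD,
        experiment_type=ExperimentType.DNA,
    )


class TestBaseToSample:
    def test_hand_worked_example(self):
        rec = _record([(8, 1), (20, 2), (5, 1)], start_sample=100)
        assert base_to_sample(rec, 0) == 100
        assert base_to_sample(rec, 1) == 108  # first base of the move-2 block
        assert base_to_sample(rec, 2) == 108  # second base shares its start
        assert base_to_sample(rec, 3) == 128

    def test_out_of_range_rejected(self):
        rec = _record([(8, 1)])
        with pytest.raises(IndexError):
            base_to_sample(rec, 1)
        with pytest.raises(IndexError):
            base_to_sample(rec, -1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(1, 30), st.integers(1, 3)), min_size=1, max_size=20),
        st.integers(0, 500),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_expansion_oracle(self, blocks, start, seed):
        rec = _record(blocks, start_sample=start)
        total = rec.translocation.total_moves
        b = int(np.random.default_rng(seed).integers(0, total))
        assert base_to_sample(rec, b) == base_to_sample_oracle(blocks, start, b)


class TestPrepareDnaSignal:
    primers = default_primer_config()

    def test_polyt_anchor_hits_true_tail_start(self):
        rec, truth = simulate_read(
            ideal_params(experiment_type="dna", strand="polyT", tail_length_nt=60, seed=1)
        )
        prep = prepare_dna_signal(rec, DnaReadType.POLYT, self.primers)
        assert prep is not None and not prep.reversed
        assert prep.rough_start == truth.true_tail_start
        assert prep.signal.min() >= 0  # absolute z

    def test_polya_anchor_reversed_coordinates(self):
        rec, truth = simulate_read(
            ideal_params(experiment_type="dna", strand="polyA", tail_length_nt=60, seed=2)
        )
        prep = prepare_dna_signal(rec, DnaReadType.POLYA, self.primers)
        assert prep is not None and prep.reversed
        # in reversed coordinates the rough start is the mirrored true tail end
        assert prep.rough_start == rec.raw_signal.size - truth.true_tail_end
        assert prep.signal.size == rec.raw_signal.size

    def test_unmappable_primer_returns_none(self):
        # N mismatches everything, so no positive-scoring primer hit exists
        rec = _record([(5, 1)] * 200, sequence="N" * 200)
        rec.raw_signal = np.random.default_rng(0).integers(0, 100, 1000).astype(np.int16)
        assert prepare_dna_signal(rec, DnaReadType.POLYT, self.primers) is None


class TestFindPrecise:
    rate = 8.5

    def test_clean_tail(self):
        x = np.concatenate([np.full(500, 0.15), np.full(600, 1.0)])
        res = find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate)
        assert res == (0, 500)

    def test_polya_band_is_wider(self):
        x = np.concatenate([np.full(500, 0.45), np.full(600, 1.0)])
        assert find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate) is None
        assert find_precise_dna_tail(x, 0, DnaReadType.POLYA, self.rate) == (0, 500)

    def test_spike_is_bridged(self):
        # 400 tail samples, an 80-sample non-tail spike, 500 more tail samples
        x = np.concatenate(
            [np.full(400, 0.15), np.full(80, 1.0), np.full(500, 0.15), np.full(600, 1.0)]
        )
        res = find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate)
        assert res == (0, 980)

    def test_gap_beyond_limit_not_bridged(self):
        # the gap exceeds max_gap_nt * rate samples, so the tail ends before it
        gap = int(120 * self.rate) + 200
        x = np.concatenate(
            [np.full(400, 0.15), np.full(gap, 1.0), np.full(500, 0.15)]
        )
        res = find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate)
        assert res == (0, 400)

    def test_short_run_after_spike_not_bridged(self):
        # the stretch after the spike is shorter than min_tail_run samples
        x = np.concatenate(
            [np.full(400, 0.15), np.full(80, 1.0), np.full(40, 0.15), np.full(600, 1.0)]
        )
        res = find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate)
        assert res == (0, 400)

    def test_iterative_bridging_crosses_two_spikes(self):
        piece = [np.full(300, 0.15), np.full(60, 1.0)]
        x = np.concatenate(piece + piece + [np.full(300, 0.15), np.full(600, 1.0)])
        res = find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate)
        assert res == (0, 1020)
        one_hop = find_precise_dna_tail(
            x, 0, DnaReadType.POLYT, self.rate, DnaConfig(iterative_bridging=False)
        )
        assert one_hop == (0, 660)

    def test_no_tail_signal_returns_none(self):
        x = np.full(1000, 1.0)
        assert find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate) is None

    def test_search_confined_to_window(self):
        # tail-like signal starting beyond the search window is never found
        x = np.concatenate([np.full(3200, 1.0), np.full(500, 0.15)])
        assert find_precise_dna_tail(x, 0, DnaReadType.POLYT, self.rate) is None


class TestEstimateDnaTail:
    @pytest.mark.parametrize("strand", ["polyA", "polyT"])
    @pytest.mark.parametrize("length", [30, 60, 150])
    def test_noise_free_read_exact(self, strand, length):
        rec, truth = simulate_read(
            ideal_params(
                experiment_type="dna", strand=strand, tail_length_nt=length, seed=length
            )
        )
        est = estimate_dna_tail(rec)
        assert est.found and est.read_type == strand
        assert est.tail_length_nt == pytest.approx(length)
        assert est.tail_start == truth.true_tail_start
        assert est.tail_end == truth.true_tail_end

    def test_long_tail_fits_search_window(self):
        # 350 nt at ~8 samples/nt stays inside the 3000-sample search window
        rec, _ = simulate_read(
            ideal_params(experiment_type="dna", strand="polyA", tail_length_nt=350, seed=9)
        )
        est = estimate_dna_tail(rec)
        assert est.found and est.tail_length_nt == pytest.approx(350)

    def test_truncated_read_reported(self):
        from squigtail.defaults import FRONT_PRIMER, REFERENCE_BODY

        seq = FRONT_PRIMER + REFERENCE_BODY[:400]
        rec = _record([(5, 1)] * len(seq), sequence=seq)
        est = estimate_dna_tail(rec)
        assert not est.found and est.failure_reason == "truncated"
        assert est.read_type == "truncated"

    def test_unclassified_read_reported(self):
        from squigtail.defaults import REFERENCE_BODY

        seq = REFERENCE_BODY[:400]
        rec = _record([(5, 1)] * len(seq), sequence=seq)
        est = estimate_dna_tail(rec)
        assert not est.found and est.failure_reason == "unclassified"

    def test_strands_agree_on_noisy_reads(self):
        ests = {}
        for strand in ("polyA", "polyT"):
            lens = []
            for seed in range(20):
                rec, _ = simulate_read(
                    SimParams(
                        experiment_type="dna", strand=strand, tail_length_nt=100, seed=seed
                    )
                )
                est = estimate_dna_tail(rec)
                if est.found:
                    lens.append(est.tail_length_nt)
            assert len(lens) >= 15
            ests[strand] = float(np.median(lens))
        assert abs(ests["polyA"] - ests["polyT"]) / 100 < 0.15

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DnaConfig(search_window=0)
        with pytest.raises(ValueError):
            DnaConfig(polyT_mean_bound=0.7, polyA_mean_bound=0.6)
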