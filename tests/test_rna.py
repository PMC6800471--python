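"""RNA tail pipeline: normalization, smoothing, segmentation, refinement."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from squigtail.rna import (
    RnaConfig,
    bidirectional_smooth,
    estimate_rna_tail,
    find_rough_polya,
    refine_polya,
    znormalize_clip,
)
from squigtail.sim import simulate_read
from tests.conftest import ideal_params


def smooth_oracle(x: np.ndarray, w: int) -> np.ndarray:
    """Brute-force bidirectional smoothing: per index, the max of the mean of
    the trailing window ending there and the leading window starting there,
    both truncated at the signal edges."""
    n = x.size
    out = np.empty(n)
    for i in range(n):
        fwd = np.mean(x[max(0, i - w + 1) : i + 1])
        bwd = np.mean(x[i : min(n, i + w)])
        out[i] = max(fwd, bwd)
    return out


def refine_oracle(normalized, rough, window, bound):
    """Brute-force refinement: longest run of low-slope window means."""
    start, end = rough
    span = normalized[start:end]
    n_win = span.size // window
    if n_win < 2:
        return None
    means = span[: n_win * window].reshape(n_win, window).mean(axis=1)
    slopes = np.diff(means)
    best = None  # (length, first_slope_index)
    for i in range(slopes.size):
        if abs(slopes[i]) > bound:
            continue
        j = i
        while j < slopes.size and abs(slopes[j]) <= bound:
            j += 1
        if best is None or j - i > best[0]:
            best = (j - i, i)
    if best is None:
        return None
    length, first = best
    last_win = first + length
    return start + first * window, min(start + (last_win + 1) * window, end)


class TestZnormalize:
    def test_zero_mean_unit_sd_without_clipping(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 2, 1000)
        z = znormalize_clip(x, clip=50)  # clip far outside the data range
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z) == pytest.approx(1, abs=1e-12)

    def test_clipping_caps_extremes(self):
        x = np.array([0.0] * 99 + [1000.0])
        z = znormalize_clip(x, clip=3.0)
        assert z.max() == 3.0 and z.min() >= -3.0

    def test_flat_signal_raises(self):
        with pytest.raises(ValueError, match="flat_signal"):
            znormalize_clip(np.full(100, 7.0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.5, 20), st.floats(-100, 100), st.integers(0, 2**31 - 1))
    def test_affine_invariance(self, a, b, seed):
        """z-normalization is invariant to positive affine rescaling."""
        x = np.random.default_rng(seed).normal(0, 1, 200)
        assert np.allclose(znormalize_clip(a * x + b), znormalize_clip(x))


class TestBidirectionalSmooth:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 0.7)
        assert np.allclose(bidirectional_smooth(x, 400), 0.7)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="read_too_short"):
            bidirectional_smooth(np.zeros(399), 400)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for w in (5, 17, 60):
            x = rng.normal(0, 1, 300)
            assert np.allclose(bidirectional_smooth(x, w), smooth_oracle(x, w))

    def test_step_edge_is_held_up_by_max_merge(self):
        """At a falling step the backward (leading) mean drops early while the
        forward (trailing) mean drops late; the max keeps the plateau value up
        to the step itself."""
        x = np.concatenate([np.ones(200), np.zeros(200)])
        s = bidirectional_smooth(x, 50)
        assert np.all(s[:200] == 1.0)
        assert s[200] < 1.0


class TestFindRoughPolya:
    def make(self, *segs):
        return np.concatenate([np.full(n, v) for n, v in segs])

    def test_canonical_pattern(self):
        # adapter top, adapter bottom, tail, body
        s = self.make((100, 1.0), (150, -1.0), (300, 0.9), (200, -0.5))
        assert find_rough_polya(s, 0.3) == (250, 550)

    def test_leading_below_segment_skipped(self):
        s = self.make((40, 0.0), (100, 1.0), (150, -1.0), (300, 0.9), (200, -0.5))
        assert find_rough_polya(s, 0.3) == (290, 590)

    def test_tail_at_trace_end(self):
        s = self.make((100, 1.0), (150, -1.0), (300, 0.9))
        assert find_rough_polya(s, 0.3) == (250, 550)

    def test_missing_adapter_returns_none(self):
        assert find_rough_polya(self.make((400, 0.9), (200, -0.5)), 0.3) is None
        assert find_rough_polya(self.make((400, -0.9),), 0.3) is None
        assert find_rough_polya(np.zeros(0), 0.3) is None


class TestRefinePolya:
    def test_hand_worked_example(self):
        # window means by construction: [0, 3, .9, .9, .9, .9, -1, -1]
        means = [0.0, 3.0, 0.9, 0.9, 0.9, 0.9, -1.0, -1.0]
        x = np.repeat(means, 25)
        # qualifying slopes join windows 2..5 (and 6..7); longest run wins
        assert refine_polya(x, (0, 200), 25, 25, 0.3) == (50, 150)

    def test_tie_broken_towards_earliest_run(self):
        means = [0.0, 3.0, 0.9, 0.9, 3.0, 0.2, 0.2, -3.0]
        x = np.repeat(means, 25)
        # two runs of one low slope each (2->3 and 5->6): earliest wins
        assert refine_polya(x, (0, 200), 25, 25, 0.3) == (50, 100)

    def test_end_clamped_to_rough_end(self):
        x = np.full(230, 0.9)
        res = refine_polya(x, (0, 230), 25, 25, 0.3)
        assert res == (0, 225)  # 9 full windows; end inclusive of last window

    def test_no_low_slope_returns_none(self):
        x = np.repeat([0.0, 3.0, -3.0, 3.0], 25)
        assert refine_polya(x, (0, 100), 25, 25, 0.3) is None

    def test_too_few_windows_returns_none(self):
        assert refine_polya(np.ones(30), (0, 30), 25, 25, 0.3) is None

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 40))
    def test_matches_brute_force_oracle(self, seed, n_win):
        rng = np.random.default_rng(seed)
        # window means drawn directly, expanded to samples
        means = rng.normal(0, 1.0, n_win)
        x = np.repeat(means, 25) + rng.normal(0, 0.01, n_win * 25)
        rough = (0, x.size)
        assert refine_polya(x, rough, 25, 25, 0.3) == refine_oracle(x, rough, 25, 0.3)


class TestEstimateRnaTail:
    @pytest.mark.parametrize("length", [40, 100, 150])
    def test_noise_free_read_within_one_window(self, length):
        rec, truth = simulate_read(ideal_params(tail_length_nt=length, seed=length))
        est = estimate_rna_tail(rec)
        assert est.found
        # boundary quantization to 25-sample refinement windows bounds the
        # noise-free error by one window's worth of nucleotides
        assert abs(est.tail_length_nt - length) <= 25 / est.samples_per_nt + 1e-9
        assert abs(est.tail_start - truth.true_tail_start) <= 2 * 25
        assert abs(est.tail_end - truth.true_tail_end) <= 2 * 25

    def test_precise_bounds_inside_signal(self):
        rec, _ = simulate_read(ideal_params(tail_length_nt=60, seed=2))
        est = estimate_rna_tail(rec)
        assert est.found
        assert 0 <= est.tail_start < est.tail_end <= rec.raw_signal.size

    def test_noisy_read_within_tolerance(self):
        from squigtail.sim import SimParams

        rec, truth = simulate_read(SimParams(tail_length_nt=100, seed=7))
        est = estimate_rna_tail(rec)
        assert est.found
        assert abs(est.tail_length_nt - 100) / 100 < 0.25

    def test_flipflop_rejected_by_default(self):
        rec, _ = simulate_read(
            ideal_params(tail_length_nt=50, basecall_model="flipflop", seed=3)
        )
        est = estimate_rna_tail(rec)
        assert not est.found and est.failure_reason == "flipflop_rna_unsupported"

    def test_flat_signal_reported(self):
        rec, _ = simulate_read(ideal_params(tail_length_nt=50, seed=4))
        rec.raw_signal = np.full_like(rec.raw_signal, 450)
        est = estimate_rna_tail(rec)
        assert not est.found and est.failure_reason == "flat_signal"

    def test_short_signal_reported(self):
        from squigtail.fast5 import (
            BasecallModel,
            ExperimentType,
            ReadRecord,
            TranslocationTable,
        )

        rng = np.random.default_rng(5)
        rec = ReadRecord(
            read_id="short",
            raw_signal=rng.integers(0, 100, 300).astype(np.int16),
            sequence="A",
            translocation=TranslocationTable(blocks=((1, 1),)),
            basecall_model=BasecallModel.STANDARD,
            experiment_type=ExperimentType.RNA,
        )
        est = estimate_rna_tail(rec)
        assert not est.found and est.failure_reason == "read_too_short"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RnaConfig(segment_threshold=1.5)
        with pytest.raises(ValueError):
            RnaConfig(smooth_window=0)
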