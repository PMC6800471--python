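"""Shared fixtures: ideal (noise-free) and realistic simulation parameters."""

from __future__ import annotations

import pytest

from squigtail.sim import SimParams


def ideal_params(**kw) -> SimParams:
    """A perfectly base-called, noise-free read: no dwell variability, no
    signal noise, no stalls, the full tail called, no move-2 merges."""
    base = dict(
        dwell_cv=0.0,
        noise_sd=0.0,
        stall_prob=0.0,
        tail_call_fraction=1.0,
        move2_prob=0.0,
        overseg_prob=0.0,
    )
    base.update(kw)
    return SimParams(**base)


@pytest.fixture
def make_ideal_params():
    return ideal_params
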