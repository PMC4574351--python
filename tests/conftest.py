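"""Shared builders for the test suite.

All fixtures are programmatic: piecewise-linear traces with known phase
structure serve as classifier oracles, and minimal per-microtubule
statistics records feed the aggregation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tbckit.dynamics_stats import MTDynamics
from tbckit.synthetic_data import GROWTH, PAUSE, SHRINK, LengthTrace


def make_piecewise_trace(
    legs, dt: float = 4.0, l0: float = 0.0, cell_id: str = "c0", mt_id: str = "m0"
) -> LengthTrace:
    """Noiseless trace from legs of (kind, n_intervals, speed um/min).

    Each leg spans ``n_intervals`` sampling intervals at constant speed
    (positive for growth, negative for shrink, zero for pause); leg
    boundaries fall exactly on samples.
    """
    lengths = [l0]
    for _, n, v in legs:
        for _ in range(n):
            lengths.append(lengths[-1] + v / 60.0 * dt)
    lengths = np.asarray(lengths)
    times = np.arange(lengths.size) * dt
    return LengthTrace(cell_id=cell_id, mt_id=mt_id, times=times, lengths=lengths)


def expected_events(kinds) -> tuple[int, int]:
    """Ground-truth (catastrophes, rescues) from an ordered leg-kind list."""
    n_cat = n_res = 0
    for a, b in zip(kinds, kinds[1:]):
        if b == SHRINK and a in (GROWTH, PAUSE):
            n_cat += 1
        elif b == GROWTH and a in (SHRINK, PAUSE):
            n_res += 1
    return n_cat, n_res


def random_oracle_legs(rng: np.random.Generator, dt: float = 4.0):
    """Random super-threshold piecewise legs with no same-kind adjacency.

    Growth/shrink legs produce |net change| >= 0.6 um (above the 0.5 um
    event threshold); pauses span at least 4 samples. Suitable as an exact
    oracle for noiseless classification.
    """
    legs = []
    prev = None
    for _ in range(int(rng.integers(3, 8))):
        options = [k for k in (GROWTH, SHRINK, PAUSE) if k != prev]
        kind = options[int(rng.integers(len(options)))]
        if kind == PAUSE:
            n, v = int(rng.integers(3, 9)), 0.0
        else:
            n = int(rng.integers(3, 10))
            v_min = 0.6 * 60.0 / (n * dt)
            v = float(rng.uniform(v_min * 1.05, v_min * 3))
            if kind == SHRINK:
                v = -v
        legs.append((kind, n, v))
        prev = kind
    return legs


def make_dynamics(
    cell_id: str = "c0", mt_id: str = "m0", **overrides
) -> MTDynamics:
    """MTDynamics record with neutral defaults, overridable per statistic."""
    base = dict(
        cell_id=cell_id,
        mt_id=mt_id,
        mean_length=1.0,
        assembly_rate=1.0,
        assembly_duration=30.0,
        disassembly_rate=2.0,
        disassembly_duration=20.0,
        catastrophe_freq=1.0,
        rescue_freq=1.0,
        pause_duration=15.0,
        n_catastrophes=1,
        n_rescues=1,
        n_pauses=1,
        t_assembly=60.0,
        t_disassembly=30.0,
        t_pause=15.0,
    )
    base.update(overrides)
    return MTDynamics(**base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
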