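"""Segmentation of microtubule length traces into dynamic-instability phases.

A sampled length trace is partitioned into assembly, disassembly, pause and
undetermined phases following the event definitions used for astral
microtubules in budding yeast:

* assembly / disassembly: a continuous monotone phase producing a net length
  change of at least 0.5 um with a linear fit quality of at least 0.85;
* pause: at least four consecutive data points (12 s at 4-s sampling)
  without significant length change;
* catastrophe: a transition from assembly or pause into disassembly;
* rescue: a transition from disassembly or pause into assembly.

Phases are represented over inclusive sample-index ranges in which
consecutive phases share their boundary sample (the transition sample
belongs to both flanking intervals), so phase durations telescope exactly
to the trace duration. Samples in no classified phase form undetermined
phases; catastrophes and rescues are still recorded across undetermined
gaps of at most ``max_gap_points`` interior samples, so that one or two
noisy samples cannot erase an event.

The segmentation is greedy and fully deterministic: monotone candidate runs
are built from inter-sample displacement signs (absorbing single-sample
sign flips smaller than the pause flatness), promoted to events by the net
change and fit-quality thresholds, and the remaining stretches are scanned
left-to-right for flat pause windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import LengthTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ASSEMBLY",
    "DISASSEMBLY",
    "PAUSE_PHASE",
    "UNDETERMINED",
    "ClassifierConfig",
    "Phase",
    "Transition",
    "PhaseSegmentation",
    "classify_trace",
    "phase_table",
    "transition_table",
    "write_phase_table",
    "read_phase_table",
]

ASSEMBLY = "assembly"
DISASSEMBLY = "disassembly"
PAUSE_PHASE = "pause"
UNDETERMINED = "undetermined"

CATASTROPHE = "catastrophe"
RESCUE = "rescue"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the phase-classification procedure.

    ``min_net_change`` (um) and ``min_fit_quality`` (magnitude of the linear
    correlation of length against time) gate assembly/disassembly events;
    ``min_pause_points`` and ``pause_flatness`` (um, maximal excursion)
    define pauses; ``max_gap_points`` is the largest undetermined gap (in
    interior samples) across which a transition is still recorded.
    """

    min_net_change: float = 0.5
    min_fit_quality: float = 0.85
    min_pause_points: int = 4
    pause_flatness: float = 0.25
    max_gap_points: int = 2

    def __post_init__(self) -> None:
        if not self.min_net_change > 0:
            raise ValueError("min_net_change must be positive")
        if not 0 < self.min_fit_quality <= 1:
            raise ValueError("min_fit_quality must lie in (0, 1]")
        if self.min_pause_points < 2:
            raise ValueError("min_pause_points must be >= 2")
        if not self.pause_flatness < self.min_net_change:
            raise ValueError("pause_flatness must be smaller than min_net_change")
        if self.max_gap_points < 0:
            raise ValueError("max_gap_points must be >= 0")


@dataclass(frozen=True)
class Phase:
    """One classified phase over an inclusive 0-based sample range.

    ``rate`` is the least-squares slope of length against time over the
    phase in um/min (0 for pauses, NaN for undetermined stretches);
    ``net_change`` is the signed length change across the phase.
    """

    kind: str
    start_index: int
    end_index: int
    rate: float  # um/min
    duration: float  # s
    net_change: float  # um

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("a phase must span at least one sampling interval")


@dataclass(frozen=True)
class Transition:
    """A catastrophe or rescue at a given sample index."""

    kind: str
    index: int
    time_s: float


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ordered phases tiling a trace, plus the catastrophe/rescue events."""

    cell_id: str
    mt_id: str
    dt: float
    phases: tuple[Phase, ...]
    transitions: tuple[Transition, ...]

    def phases_of(self, kind: str) -> list[Phase]:
        return [p for p in self.phases if p.kind == kind]

    @property
    def n_catastrophes(self) -> int:
        return sum(1 for t in self.transitions if t.kind == CATASTROPHE)

    @property
    def n_rescues(self) -> int:
        return sum(1 for t in self.transitions if t.kind == RESCUE)


def _smooth_signs(d: np.ndarray, flat: float) -> np.ndarray:
    """Absorb single-sample sign flips smaller than ``flat`` into their context."""
    signs = np.sign(d).astype(int)
    n = signs.size
    out = signs.copy()
    i = 0
    while i < n:
        j = i
        while j + 1 < n and signs[j + 1] == signs[i]:
            j += 1
        if (
            j == i
            and 0 < i < n - 1
            and abs(d[i]) < flat
            and signs[i - 1] == signs[j + 1]
            and signs[i - 1] != 0
            and signs[i] != signs[i - 1]
        ):
            out[i] = signs[i - 1]
        i = j + 1
    return out


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, end_inclusive, value) over an int array."""
    runs = []
    i = 0
    n = labels.size
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        runs.append((i, j, int(labels[i])))
        i = j + 1
    return runs


def _linear_fit(times: np.ndarray, lengths: np.ndarray) -> tuple[float, float]:
    """OLS slope (um/s) and |correlation| of length vs time."""
    t = times - times.mean()
    l = lengths - lengths.mean()
    stt = float(t @ t)
    sll = float(l @ l)
    if stt == 0:
        return 0.0, 0.0
    slope = float(t @ l) / stt
    if sll == 0:
        return slope, 0.0
    r = float(t @ l) / np.sqrt(stt * sll)
    return slope, abs(r)


def classify_trace(
    trace: LengthTrace, config: ClassifierConfig | None = None
) -> PhaseSegmentation:
    """Segment one length trace into phases and detect catastrophes/rescues.

    Deterministic for a fixed input. Raises on non-uniform sampling or a
    trace shorter than ``min_pause_points`` samples.
    """
    cfg = config or ClassifierConfig()
    times, lengths = trace.times, trace.lengths
    n = times.size
    if n < cfg.min_pause_points:
        raise ValueError(
            f"trace has {n} samples, fewer than min_pause_points={cfg.min_pause_points}"
        )
    steps = np.diff(times)
    if np.ptp(steps) > 1e-9:
        raise ValueError("classification requires uniformly sampled traces")
    dt = float(steps[0])

    d = np.diff(lengths)
    signs = _smooth_signs(d, cfg.pause_flatness)

    # step 2: promote monotone candidate runs to assembly/disassembly events
    events: list[tuple[int, int, str]] = []  # displacement ranges
    for i, j, s in _runs(signs):
        if s == 0:
            continue
        net = lengths[j + 1] - lengths[i]
        if abs(net) < cfg.min_net_change:
            continue
        _, quality = _linear_fit(times[i : j + 2], lengths[i : j + 2])
        if quality < cfg.min_fit_quality:
            continue
        events.append((i, j, ASSEMBLY if net > 0 else DISASSEMBLY))

    # step 3: flat pause windows in the remaining stretches
    assigned = np.zeros(d.size, dtype=bool)
    for i, j, _ in events:
        assigned[i : j + 1] = True
    pauses: list[tuple[int, int, str]] = []
    for a, b, val in _runs(assigned.astype(int)):
        if val == 1:
            continue
        # free displacements a..b correspond to samples a..b+1
        u = a
        while u <= b:
            v = u
            lo = hi = lengths[u]
            while v + 1 <= b + 1:
                cand_lo = min(lo, lengths[v + 1])
                cand_hi = max(hi, lengths[v + 1])
                if cand_hi - cand_lo > cfg.pause_flatness:
                    break
                v += 1
                lo, hi = cand_lo, cand_hi
            if v - u + 1 >= cfg.min_pause_points:
                pauses.append((u, v - 1, PAUSE_PHASE))
                u = v
            else:
                u += 1

    # assemble the ordered phase list, filling gaps with undetermined phases
    classified = sorted(events + pauses)
    ranges: list[tuple[int, int, str]] = []
    cursor = 0
    for i, j, kind in classified:
        if i > cursor:
            ranges.append((cursor, i - 1, UNDETERMINED))
        ranges.append((i, j, kind))
        cursor = j + 1
    if cursor < d.size:
        ranges.append((cursor, d.size - 1, UNDETERMINED))

    phases = []
    for i, j, kind in ranges:
        seg_t, seg_l = times[i : j + 2], lengths[i : j + 2]
        if kind in (ASSEMBLY, DISASSEMBLY):
            slope, _ = _linear_fit(seg_t, seg_l)
            rate = slope * 60.0
        elif kind == PAUSE_PHASE:
            rate = 0.0
        else:
            rate = float("nan")
        phases.append(
            Phase(
                kind=kind,
                start_index=i,
                end_index=j + 1,
                rate=rate,
                duration=(j + 1 - i) * dt,
                net_change=float(lengths[j + 1] - lengths[i]),
            )
        )

    # transitions between consecutive classified phases, bridging short
    # undetermined gaps
    transitions = []
    informative = [p for p in phases if p.kind != UNDETERMINED]
    for prev, nxt in zip(informative, informative[1:]):
        gap = nxt.start_index - prev.end_index - 1
        if gap > cfg.max_gap_points:
            continue
        kind = None
        if nxt.kind == DISASSEMBLY and prev.kind in (ASSEMBLY, PAUSE_PHASE):
            kind = CATASTROPHE
        elif nxt.kind == ASSEMBLY and prev.kind in (DISASSEMBLY, PAUSE_PHASE):
            kind = RESCUE
        if kind is not None:
            transitions.append(
                Transition(kind=kind, index=nxt.start_index,
                           time_s=float(times[nxt.start_index]))
            )

    return PhaseSegmentation(
        cell_id=trace.cell_id,
        mt_id=trace.mt_id,
        dt=dt,
        phases=tuple(phases),
        transitions=tuple(transitions),
    )


def phase_table(
    segs: PhaseSegmentation | Iterable[PhaseSegmentation],
) -> pd.DataFrame:
    """One row per phase: ``cell_id mt_id kind t_start_s t_end_s duration_s
    rate_um_min net_um``."""
    if isinstance(segs, PhaseSegmentation):
        segs = [segs]
    rows = []
    for seg in segs:
        for p in seg.phases:
            rows.append(
                {
                    "cell_id": seg.cell_id,
                    "mt_id": seg.mt_id,
                    "kind": p.kind,
                    "t_start_s": p.start_index * seg.dt,
                    "t_end_s": p.end_index * seg.dt,
                    "duration_s": p.duration,
                    "rate_um_min": p.rate,
                    "net_um": p.net_change,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "mt_id", "kind", "t_start_s", "t_end_s",
            "duration_s", "rate_um_min", "net_um",
        ],
    )


def transition_table(
    segs: PhaseSegmentation | Iterable[PhaseSegmentation],
) -> pd.DataFrame:
    """One row per catastrophe/rescue: ``cell_id mt_id kind time_s``."""
    if isinstance(segs, PhaseSegmentation):
        segs = [segs]
    rows = [
        {"cell_id": s.cell_id, "mt_id": s.mt_id, "kind": t.kind, "time_s": t.time_s}
        for s in segs
        for t in s.transitions
    ]
    return pd.DataFrame(rows, columns=["cell_id", "mt_id", "kind", "time_s"])


def write_phase_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phase_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
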