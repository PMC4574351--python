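"""Per-microtubule and per-condition dynamic-instability statistics.

Statistics mirror the standard astral-microtubule report: mean length,
assembly/disassembly rates and mean phase durations, catastrophe and rescue
frequencies, and mean pause duration. Frequencies are computed per
microtubule as events divided by the time available for that event:
catastrophes over the total time in assembly and pause, rescues over the
total time in disassembly and pause (in minutes). Undetermined samples are
excluded from these denominators: by definition they are neither assembly,
disassembly nor pause. Per-microtubule values are then averaged across
microtubules (mean +/- SEM), and conditions are compared statistic by
statistic with Welch's two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phase_classifier import (
    ASSEMBLY,
    DISASSEMBLY,
    PAUSE_PHASE,
    PhaseSegmentation,
)
from .synthetic_data import LengthTrace

logger = logging.getLogger(__name__)

__all__ = [
    "MTDynamics",
    "ConditionSummary",
    "STATISTICS",
    "summarize_mt",
    "summarize_condition",
    "compare_conditions",
    "dynamics_long_table",
    "condition_table",
]

#: The per-microtubule statistics reported for each condition, in table order.
STATISTICS = (
    "mean_length",
    "assembly_rate",
    "assembly_duration",
    "disassembly_rate",
    "disassembly_duration",
    "catastrophe_freq",
    "rescue_freq",
    "pause_duration",
)


@dataclass(frozen=True)
class MTDynamics:
    """Dynamics statistics of a single microtubule.

    Rates in um/min (disassembly reported as a positive speed), durations
    in seconds, frequencies in min^-1. A frequency whose denominator is
    zero is NaN ("undefined-marked") and is dropped per-statistic during
    aggregation. Phase times ``t_*`` are in seconds.
    """

    cell_id: str
    mt_id: str
    mean_length: float
    assembly_rate: float
    assembly_duration: float
    disassembly_rate: float
    disassembly_duration: float
    catastrophe_freq: float
    rescue_freq: float
    pause_duration: float
    n_catastrophes: int
    n_rescues: int
    n_pauses: int
    t_assembly: float
    t_disassembly: float
    t_pause: float


@dataclass(frozen=True)
class ConditionSummary:
    """Mean +/- SEM of each statistic over the microtubules of one condition."""

    label: str
    n_mts: int
    n_cells: int
    mean: dict[str, float]
    sem: dict[str, float]
    n: dict[str, int]  # per-statistic count after dropping undefined values

    def row(self) -> dict[str, object]:
        out: dict[str, object] = {"condition": self.label}
        for s in STATISTICS:
            m, e = self.mean[s], self.sem[s]
            out[s] = (
                f"{m:.3g} ± {e:.2g}" if math.isfinite(e) else f"{m:.3g} ± NA"
            )
        out["n_mts"] = self.n_mts
        out["n_cells"] = self.n_cells
        return out


def _weighted_rate(phases) -> float:
    """Duration-weighted mean slope over phases of one kind (um/min)."""
    if not phases:
        return float("nan")
    w = np.array([p.duration for p in phases])
    r = np.array([p.rate for p in phases])
    return float(np.sum(w * r) / np.sum(w))


def summarize_mt(seg: PhaseSegmentation, trace: LengthTrace) -> MTDynamics:
    """Per-microtubule statistics from a segmentation and its trace.

    ``mean_length`` is the time average of the sampled lengths over the
    whole trace (undetermined spans included). Rates are duration-weighted
    means over phases of that kind; durations are means per phase.
    """
    if (seg.cell_id, seg.mt_id) != (trace.cell_id, trace.mt_id):
        raise ValueError("segmentation does not reference the given trace")

    asm = seg.phases_of(ASSEMBLY)
    dis = seg.phases_of(DISASSEMBLY)
    pauses = seg.phases_of(PAUSE_PHASE)
    t_asm = sum(p.duration for p in asm)
    t_dis = sum(p.duration for p in dis)
    t_pause = sum(p.duration for p in pauses)

    cat_denom_min = (t_asm + t_pause) / 60.0
    res_denom_min = (t_dis + t_pause) / 60.0
    if cat_denom_min > 0:
        cat_freq = seg.n_catastrophes / cat_denom_min
    else:
        cat_freq = float("nan")
        logger.info(
            "%s/%s: no assembly or pause time; catastrophe frequency undefined",
            seg.cell_id, seg.mt_id,
        )
    if res_denom_min > 0:
        res_freq = seg.n_rescues / res_denom_min
    else:
        res_freq = float("nan")
        logger.info(
            "%s/%s: no disassembly or pause time; rescue frequency undefined",
            seg.cell_id, seg.mt_id,
        )

    return MTDynamics(
        cell_id=seg.cell_id,
        mt_id=seg.mt_id,
        mean_length=float(np.mean(trace.lengths)),
        assembly_rate=_weighted_rate(asm),
        assembly_duration=t_asm / len(asm) if asm else float("nan"),
        disassembly_rate=abs(_weighted_rate(dis)),
        disassembly_duration=t_dis / len(dis) if dis else float("nan"),
        catastrophe_freq=cat_freq,
        rescue_freq=res_freq,
        pause_duration=t_pause / len(pauses) if pauses else float("nan"),
        n_catastrophes=seg.n_catastrophes,
        n_rescues=seg.n_rescues,
        n_pauses=len(pauses),
        t_assembly=t_asm,
        t_disassembly=t_dis,
        t_pause=t_pause,
    )


def _stat_values(dyn: Sequence[MTDynamics], stat: str) -> np.ndarray:
    vals = np.array([getattr(d, stat) for d in dyn], dtype=float)
    return vals[np.isfinite(vals)]


def summarize_condition(
    dyn: Sequence[MTDynamics], label: str, min_cells: int = 5
) -> ConditionSummary:
    """Mean and SEM of every statistic over a cohort of microtubules.

    Undefined (NaN) values are dropped per statistic with the surviving
    count reported; a statistic left with fewer than two values gets an
    undefined SEM. Fewer than ``min_cells`` distinct cells triggers a
    warning (the conventional design images at least five cells), not an
    error.
    """
    if len(dyn) < 2:
        raise ValueError("a condition summary needs at least 2 microtubules")
    n_cells = len({d.cell_id for d in dyn})
    if n_cells < min_cells:
        logger.warning(
            "condition %r has %d distinct cells (< %d)", label, n_cells, min_cells
        )
    mean, sem, n = {}, {}, {}
    for s in STATISTICS:
        vals = _stat_values(dyn, s)
        n[s] = int(vals.size)
        mean[s] = float(np.mean(vals)) if vals.size else float("nan")
        sem[s] = (
            float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            if vals.size > 1
            else float("nan")
        )
    return ConditionSummary(
        label=label, n_mts=len(dyn), n_cells=n_cells, mean=mean, sem=sem, n=n
    )


def compare_conditions(
    a: Sequence[MTDynamics],
    b: Sequence[MTDynamics],
    alpha: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
) -> pd.DataFrame:
    """Welch two-sample t-test per statistic between two cohorts.

    Returns one row per statistic with both means, the t statistic, the
    two-sided p-value and a significance flag at ``alpha``. Degenerate
    zero-variance pairs are reported as an exact comparison of means
    (p = 0 or 1) with a warning.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both cohorts need at least 2 microtubules")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for s in STATISTICS:
        va, vb = _stat_values(a, s), _stat_values(b, s)
        if va.size < 2 or vb.size < 2:
            t, p = float("nan"), float("nan")
        elif np.var(va) == 0 and np.var(vb) == 0:
            p = 1.0 if va[0] == vb[0] else 0.0
            t = float("nan")
            logger.warning(
                "statistic %r has zero variance in both cohorts; p set by "
                "exact comparison of means", s,
            )
        else:
            t, p = sps.ttest_ind(va, vb, equal_var=False)
            t, p = float(t), float(p)
        rows.append(
            {
                "statistic": s,
                f"mean_{label_a}": float(np.mean(va)) if va.size else float("nan"),
                f"mean_{label_b}": float(np.mean(vb)) if vb.size else float("nan"),
                "t": t,
                "p_value": p,
                "significant": bool(p < alpha) if math.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def dynamics_long_table(
    cohorts: dict[str, Sequence[MTDynamics]]
) -> pd.DataFrame:
    """Machine-readable long table: one row per microtubule and condition."""
    rows = []
    for label, dyn in cohorts.items():
        for d in dyn:
            row = {"condition": label}
            for f in fields(MTDynamics):
                row[f.name] = getattr(d, f.name)
            rows.append(row)
    return pd.DataFrame(rows)


def condition_table(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Report-shaped table: rows = conditions, columns = ``mean +/- SEM``."""
    return pd.DataFrame([s.row() for s in summaries])
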