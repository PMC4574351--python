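"""Synthetic microtubule traces and GTPase titrations with known ground truth.

Microtubule dynamic instability is modelled as a three-state continuous-time
Markov chain over growth, shrink and pause, the minimal generative model
consistent with the catastrophe/rescue transition definitions used for
astral-microtubule analysis (catastrophe: growth or pause -> shrink; rescue:
shrink or pause -> growth). Length changes linearly at +v_g during growth,
-v_s during shrink and is constant during pause; dwell times are exponential
with the supplied hazard rates. The exact piecewise-linear path is sampled
on a uniform grid (4 or 5 s, as in time-lapse imaging) and additive Gaussian
measurement noise is applied per sample.

The module also inverts observable summary statistics (phase rates, mean
dwell times, catastrophe and rescue frequencies) into chain hazards, so that
cohorts can be simulated directly at published per-condition dynamics values,
and generates Michaelis-Menten titrations and phosphate standard series for
the malachite-green assay pipeline.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .gtpase_kinetics import StandardSeries, TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GROWTH",
    "SHRINK",
    "PAUSE",
    "HazardSet",
    "SimParams",
    "LengthTrace",
    "SummaryTargets",
    "KineticGroundTruth",
    "HazardSolution",
    "DYNAMICS_REFERENCE_TARGETS",
    "simulate_path",
    "simulate_trace",
    "simulate_cohort",
    "hazards_from_summary",
    "solve_hazards",
    "stationary_distribution",
    "path_statistics",
    "simulate_titration",
    "simulate_standard_series",
    "write_traces",
    "read_traces",
    "write_ground_truth",
    "read_ground_truth",
]

GROWTH = "growth"
SHRINK = "shrink"
PAUSE = "pause"
_STATES = (GROWTH, SHRINK, PAUSE)


@dataclass(frozen=True)
class HazardSet:
    """Transition hazards (min^-1) of the growth/shrink/pause chain.

    Naming: ``gs`` = growth->shrink (catastrophe from growth), ``pg`` =
    pause->growth (rescue from pause), etc. A state with zero total exit
    hazard is absorbing; that is permitted (dwell is then infinite) but the
    simulator rejects the degenerate absorbing-shrink-at-zero-length case.
    """

    gs: float = 0.0
    gp: float = 0.0
    sg: float = 0.0
    sp: float = 0.0
    ps: float = 0.0
    pg: float = 0.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"hazard {name} must be finite and >= 0, got {value}")

    def exit_rate(self, state: str) -> float:
        """Total exit hazard (min^-1) of a state."""
        if state == GROWTH:
            return self.gs + self.gp
        if state == SHRINK:
            return self.sg + self.sp
        if state == PAUSE:
            return self.ps + self.pg
        raise ValueError(f"unknown state {state!r}")

    def generator_matrix(self) -> np.ndarray:
        """3x3 generator Q (min^-1) ordered growth, shrink, pause."""
        q = np.array(
            [
                [-(self.gs + self.gp), self.gs, self.gp],
                [self.sg, -(self.sg + self.sp), self.sp],
                [self.pg, self.ps, -(self.ps + self.pg)],
            ]
        )
        return q


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated length trace.

    Speeds are in um/min, times in seconds, lengths in um. ``noise_sd`` is
    the additive per-sample measurement noise (sub-pixel localisation scale
    by default). ``initial_state`` of None draws from the stationary
    distribution of the chain. ``zero_boundary`` controls what happens when
    a shrinking microtubule reaches zero length: ``"renucleate"`` forces a
    transition to growth, ``"truncate"`` ends the trace there.
    """

    v_g: float
    v_s: float
    hazards: HazardSet
    dt: float = 4.0  # s
    duration: float = 600.0  # s
    noise_sd: float = 0.05  # um
    l0: float = 0.9  # um
    seed: int = 0
    initial_state: str | None = None
    zero_boundary: Literal["renucleate", "truncate"] = "renucleate"

    def __post_init__(self) -> None:
        if not self.v_g > 0 or not self.v_s > 0:
            raise ValueError("v_g and v_s must be positive")
        if self.dt not in (4, 5, 4.0, 5.0):
            raise ValueError("sampling interval must be 4 or 5 s")
        if self.duration < 4 * self.dt:
            raise ValueError("duration must cover at least 4 sampling intervals")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.l0 < 0:
            raise ValueError("initial length must be >= 0")
        if self.initial_state is not None and self.initial_state not in _STATES:
            raise ValueError(f"initial_state must be one of {_STATES}")
        if self.zero_boundary not in ("renucleate", "truncate"):
            raise ValueError("zero_boundary must be 'renucleate' or 'truncate'")


@dataclass(frozen=True)
class LengthTrace:
    """One microtubule's sampled length time series (times s, lengths um)."""

    cell_id: str
    mt_id: str
    times: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if self.times.shape != self.lengths.shape or self.times.ndim != 1:
            raise ValueError("times and lengths must be 1-d arrays of equal length")
        if self.times.size < 4:
            raise ValueError("a trace needs at least 4 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValueError("sampling must be uniform (spacing constant to 1e-9 s)")
        if np.any(self.lengths < 0):
            raise ValueError("lengths must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class SummaryTargets:
    """Per-condition dynamics statistics used as simulation targets.

    Rates in um/min, frequencies in min^-1, durations in seconds.
    ``pause_duration=None`` disables the pause state entirely (two-state
    catastrophe/rescue chain); the dwell-duration targets are then implied
    by the frequencies and ignored.
    """

    assembly_rate: float
    disassembly_rate: float
    catastrophe_freq: float
    rescue_freq: float
    pause_duration: float | None
    assembly_duration: float
    disassembly_duration: float

    def __post_init__(self) -> None:
        for name in (
            "assembly_rate",
            "disassembly_rate",
            "catastrophe_freq",
            "rescue_freq",
            "assembly_duration",
            "disassembly_duration",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.pause_duration is not None and not self.pause_duration > 0:
            raise ValueError("pause_duration must be positive or None")


#: Published per-condition astral-microtubule dynamics for wild-type yeast
#: and cells expressing the GTP-locked Arl2 Q73L mutant (mean values).
DYNAMICS_REFERENCE_TARGETS: dict[str, SummaryTargets] = {
    "wild_type": SummaryTargets(
        assembly_rate=1.4,
        disassembly_rate=3.06,
        catastrophe_freq=0.90,
        rescue_freq=1.5,
        pause_duration=18.0,
        assembly_duration=46.0,
        disassembly_duration=27.0,
    ),
    "wild_type_plus_Q73L_90min": SummaryTargets(
        assembly_rate=1.4,
        disassembly_rate=1.56,
        catastrophe_freq=0.66,
        rescue_freq=0.48,
        pause_duration=36.0,
        assembly_duration=58.0,
        disassembly_duration=53.0,
    ),
    "Q73L": SummaryTargets(
        assembly_rate=1.5,
        disassembly_rate=3.00,
        catastrophe_freq=0.78,
        rescue_freq=0.66,
        pause_duration=37.0,
        assembly_duration=41.0,
        disassembly_duration=24.0,
    ),
}


@dataclass(frozen=True)
class KineticGroundTruth:
    """Ground-truth Michaelis-Menten parameters for titration synthesis.

    ``noise_cv`` is multiplicative rate noise (fraction of the true rate);
    ``noise_sd_rate`` is additive noise in uM/min. Both default to the
    standard assay design: 1 uM enzyme, ten GTP levels spanning 0-800 uM,
    3% multiplicative noise.
    """

    Km: float  # uM
    kcat: float  # min^-1 per uM enzyme
    enzyme_conc: float = 1.0  # uM
    substrate_grid: tuple[float, ...] = (
        0.0, 25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 650.0, 800.0,
    )
    noise_cv: float = 0.03
    noise_sd_rate: float = 0.0  # uM/min
    seed: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.Km > 0:
            raise ValueError("Km must be positive")
        if self.kcat < 0:
            raise ValueError("kcat must be >= 0")
        if not self.enzyme_conc > 0:
            raise ValueError("enzyme_conc must be positive")
        if any(s < 0 for s in self.substrate_grid):
            raise ValueError("substrate concentrations must be >= 0")
        if self.noise_cv < 0 or self.noise_sd_rate < 0:
            raise ValueError("noise levels must be >= 0")


# --- microtubule path simulation -------------------------------------------

def stationary_distribution(hazards: HazardSet) -> np.ndarray:
    """Stationary occupancy of (growth, shrink, pause).

    Falls back to all-growth when the chain has no transitions (a frozen
    trace) and renormalises over recurrent states when some state is
    unreachable.
    """
    q = hazards.generator_matrix()
    if not np.any(q):
        return np.array([1.0, 0.0, 0.0])
    # a state nothing transitions into carries no stationary mass even if
    # it is absorbing (it is simply unreachable)
    in_rate = q.sum(axis=0) - np.diag(q)
    active = np.nonzero(in_rate > 0)[0]
    if active.size == 0:
        return np.array([1.0, 0.0, 0.0])
    qa = q[np.ix_(active, active)]
    a = np.vstack([qa.T, np.ones(active.size)])
    b = np.zeros(active.size + 1)
    b[-1] = 1.0
    pi_a, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.zeros(3)
    pi[active] = np.clip(pi_a, 0.0, None)
    total = pi.sum()
    if total <= 0:
        return np.array([1.0, 0.0, 0.0])
    return pi / total


def _draw_next_state(state: str, hazards: HazardSet, rng: np.random.Generator) -> str:
    if state == GROWTH:
        pairs = ((SHRINK, hazards.gs), (PAUSE, hazards.gp))
    elif state == SHRINK:
        pairs = ((GROWTH, hazards.sg), (PAUSE, hazards.sp))
    else:
        pairs = ((SHRINK, hazards.ps), (GROWTH, hazards.pg))
    total = pairs[0][1] + pairs[1][1]
    return pairs[0][0] if rng.random() * total < pairs[0][1] else pairs[1][0]


@dataclass(frozen=True)
class PathSegment:
    """One constant-state stretch of the exact (noise-free) trajectory.

    ``renucleated`` marks growth segments forced by the zero-length
    boundary rather than entered through a stochastic transition.
    """

    t_start: float  # s
    t_end: float  # s
    state: str
    l_start: float  # um
    l_end: float  # um
    renucleated: bool = False


def simulate_path(
    params: SimParams, rng: np.random.Generator | None = None
) -> list[PathSegment]:
    """Exact event-driven trajectory of the three-state chain.

    Segment times telescope exactly to ``params.duration`` (unless the
    trace is truncated at the zero-length boundary). The zero boundary
    forces a renucleation transition to growth by default.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h = params.hazards
    if params.l0 == 0 and params.initial_state == SHRINK and (
        h.exit_rate(SHRINK) == 0.0 or params.zero_boundary == "truncate"
    ):
        raise ValueError(
            "degenerate simulation: shrinking from zero length with no way "
            "to leave the shrink state"
        )

    if params.initial_state is not None:
        state = params.initial_state
    else:
        pi = stationary_distribution(h)
        state = _STATES[rng.choice(3, p=pi)]

    v = {GROWTH: params.v_g / 60.0, SHRINK: -params.v_s / 60.0, PAUSE: 0.0}
    t, length = 0.0, params.l0
    forced = False
    segments: list[PathSegment] = []
    while t < params.duration:
        rate = h.exit_rate(state)
        dwell = math.inf if rate == 0 else rng.exponential(60.0 / rate)
        t_next = min(t + dwell, params.duration)
        if state == SHRINK:
            t_hit = t + length / (params.v_s / 60.0)
            if t_hit < t_next:
                segments.append(PathSegment(t, t_hit, SHRINK, length, 0.0))
                t, length = t_hit, 0.0
                if params.zero_boundary == "truncate":
                    return segments
                state, forced = GROWTH, True  # forced renucleation
                continue
        l_next = max(length + v[state] * (t_next - t), 0.0)
        segments.append(
            PathSegment(t, t_next, state, length, l_next,
                        renucleated=forced and state == GROWTH)
        )
        forced = False
        t, length = t_next, l_next
        if t < params.duration:
            state = _draw_next_state(state, h, rng)
    return segments


def _sample_path(segments: Sequence[PathSegment], times: np.ndarray) -> np.ndarray:
    knots_t = [segments[0].t_start] + [s.t_end for s in segments]
    knots_l = [segments[0].l_start] + [s.l_end for s in segments]
    return np.interp(times, knots_t, knots_l)


def simulate_trace(
    params: SimParams,
    cell_id: str = "cell0",
    mt_id: str = "mt0",
    return_path: bool = False,
):
    """Simulate one sampled, noisy length trace (optionally with its path).

    Fully reproducible from ``params.seed``: the same parameters always give
    a bit-identical trace. Noise is drawn after the path, so the noise-free
    trajectory for a given seed is independent of ``noise_sd``.
    """
    rng = np.random.default_rng(params.seed)
    segments = simulate_path(params, rng)
    t_end = segments[-1].t_end
    times = np.arange(0.0, t_end + params.dt / 2, params.dt)
    if times.size < 4:
        raise ValueError(
            "trace truncated at the zero-length boundary before 4 samples"
        )
    lengths = _sample_path(segments, times)
    if params.noise_sd > 0:
        lengths = lengths + rng.normal(0.0, params.noise_sd, size=lengths.size)
    lengths = np.clip(lengths, 0.0, None)
    trace = LengthTrace(cell_id=cell_id, mt_id=mt_id, times=times, lengths=lengths)
    return (trace, segments) if return_path else trace


def simulate_cohort(
    params: SimParams,
    n_traces: int,
    seed: int | None = None,
    mts_per_cell: int = 2,
    return_paths: bool = False,
):
    """Simulate ``n_traces`` independent traces with per-trace child seeds.

    Cells are assigned ``mts_per_cell`` microtubules each (pre-anaphase
    yeast cells typically show one or two astral microtubules). Child seeds
    derive deterministically from ``seed`` (default: ``params.seed``).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    base = params.seed if seed is None else seed
    children = np.random.SeedSequence(base).generate_state(n_traces) >> 1
    out, paths = [], []
    for i in range(n_traces):
        p = replace(params, seed=int(children[i]))
        cell = f"cell{i // mts_per_cell}"
        mt = f"mt{i % mts_per_cell}"
        res = simulate_trace(p, cell_id=cell, mt_id=mt, return_path=return_paths)
        if return_paths:
            out.append(res[0])
            paths.append(res[1])
        else:
            out.append(res)
    return (out, paths) if return_paths else out


def path_statistics(segments: Sequence[PathSegment]) -> dict[str, float]:
    """Chain-level dwell times and event counts of one exact trajectory.

    Catastrophes are entries into shrink from growth or pause; rescues are
    entries into growth from shrink or pause. Growth onsets forced by the
    zero-length boundary are renucleations, not stochastic rescues, and are
    excluded from the rescue count. Times in seconds.
    """
    t = {GROWTH: 0.0, SHRINK: 0.0, PAUSE: 0.0}
    n_cat = n_res = 0
    prev = None
    for seg in segments:
        t[seg.state] += seg.t_end - seg.t_start
        if prev is not None and seg.state != prev:
            if seg.state == SHRINK:
                n_cat += 1
            elif seg.state == GROWTH and not seg.renucleated:
                n_res += 1
        prev = seg.state
    return {
        "t_growth": t[GROWTH],
        "t_shrink": t[SHRINK],
        "t_pause": t[PAUSE],
        "n_catastrophes": float(n_cat),
        "n_rescues": float(n_res),
    }


# --- inverting summary statistics into hazards ------------------------------

@dataclass(frozen=True)
class HazardSolution:
    """Result of the summary-to-hazard inversion.

    ``exact`` is False when the targets were infeasible for the three-state
    chain and the closest (least-squares) hazards are returned instead.
    ``residuals`` are the normalised constraint residuals at the solution.
    """

    hazards: HazardSet
    exact: bool
    residuals: dict[str, float]


def solve_hazards(
    targets: SummaryTargets,
    pause_to_growth: float = 0.5,
    tol: float = 1e-8,
) -> HazardSolution:
    """Solve chain hazards that realise the targeted dynamics statistics.

    In the stationary regime the constraints are: mean dwell in growth,
    shrink and pause equal the targeted durations; catastrophes per unit
    time in growth+pause equal the catastrophe frequency; rescues per unit
    time in shrink+pause equal the rescue frequency. With the dwell times
    fixing the three exit rates, the frequency constraints determine the
    embedded-chain visit rates in closed form, leaving one degree of
    freedom: the fraction of pause exits that resume growth
    (``pause_to_growth``), clamped into its feasible interval. Infeasible
    targets fall back to a bounded least-squares fit and are flagged.
    """
    f_c = targets.catastrophe_freq
    f_r = targets.rescue_freq

    if targets.pause_duration is None:
        # two-state chain: frequencies map directly onto the two hazards
        hz = HazardSet(gs=f_c, sg=f_r)
        return HazardSolution(hz, True, {"catastrophe": 0.0, "rescue": 0.0})

    tau_g = targets.assembly_duration / 60.0  # min
    tau_s = targets.disassembly_duration / 60.0
    tau_p = targets.pause_duration / 60.0

    # visit rates per growth entry: u_s entries into shrink, u_p into pause
    u_p = (1.0 / f_r - tau_s * f_c * tau_g) / (tau_p * (1.0 + tau_s * f_c))
    feasible = u_p >= 0
    u_p = max(u_p, 0.0)
    u_s = f_c * (tau_g + tau_p * u_p)

    if u_s <= 0:
        feasible = False
        u_s = 1e-9

    # branch fractions: a = P(growth->shrink), b = P(shrink->growth),
    # c = P(pause->growth)
    if u_p > 0:
        c_lo = max(0.0, 1.0 - u_s / u_p, (1.0 - u_s) / u_p)
        c_hi = min(1.0, 1.0 - (u_s - 1.0) / u_p, 1.0 / u_p)
        if c_lo > c_hi:
            feasible = False
            c = min(max(pause_to_growth, 0.0), 1.0)
        else:
            c = min(max(pause_to_growth, c_lo), c_hi)
    else:
        c = pause_to_growth
    a = min(max(u_s - (1.0 - c) * u_p, 0.0), 1.0)
    b = min(max((1.0 - c * u_p) / u_s, 0.0), 1.0)

    def hazards_from(a, b, c):
        return HazardSet(
            gs=a / tau_g, gp=(1.0 - a) / tau_g,
            sg=b / tau_s, sp=(1.0 - b) / tau_s,
            pg=c / tau_p, ps=(1.0 - c) / tau_p,
        )

    def residuals(abc) -> dict[str, float]:
        hz = hazards_from(*abc)
        pi = stationary_distribution(hz)
        cat = (pi[0] * hz.gs + pi[2] * hz.ps) / (pi[0] + pi[2])
        res = (pi[1] * hz.sg + pi[2] * hz.pg) / (pi[1] + pi[2])
        return {"catastrophe": cat / f_c - 1.0, "rescue": res / f_r - 1.0}

    r = residuals((a, b, c))
    if max(abs(v) for v in r.values()) <= tol and feasible:
        return HazardSolution(hazards_from(a, b, c), True, r)

    # least-squares-closest feasible hazards
    sol = optimize.least_squares(
        lambda x: list(residuals(x).values()),
        x0=[min(max(a, 1e-6), 1 - 1e-6),
            min(max(b, 1e-6), 1 - 1e-6),
            min(max(c, 1e-6), 1 - 1e-6)],
        bounds=([0.0] * 3, [1.0] * 3),
        xtol=1e-12,
    )
    r = residuals(sol.x)
    exact = max(abs(v) for v in r.values()) <= tol
    if not exact:
        logger.warning(
            "dynamics targets infeasible for the three-state chain; returning "
            "closest hazards (residuals %s)", r,
        )
    return HazardSolution(hazards_from(*sol.x), exact, r)


def hazards_from_summary(
    targets: SummaryTargets, pause_to_growth: float = 0.5
) -> HazardSet:
    """Hazards realising the targeted statistics (see :func:`solve_hazards`)."""
    return solve_hazards(targets, pause_to_growth=pause_to_growth).hazards


def params_from_targets(
    targets: SummaryTargets,
    dt: float = 4.0,
    duration: float = 600.0,
    noise_sd: float = 0.05,
    l0: float = 0.9,
    seed: int = 0,
) -> SimParams:
    """Convenience: SimParams whose chain realises a published condition row."""
    return SimParams(
        v_g=targets.assembly_rate,
        v_s=targets.disassembly_rate,
        hazards=hazards_from_summary(targets),
        dt=dt,
        duration=duration,
        noise_sd=noise_sd,
        l0=l0,
        seed=seed,
    )


# --- GTPase assay synthesis --------------------------------------------------

def simulate_titration(
    truth: KineticGroundTruth,
    mode: Literal["initial_rate", "depleting"] = "initial_rate",
    incubation_min: float = 90.0,
) -> TitrationSeries:
    """Synthesize a GTP titration at known Michaelis-Menten parameters.

    ``initial_rate`` evaluates v = kcat*E*S/(Km+S) directly. ``depleting``
    integrates substrate consumption over the incubation and reports the
    endpoint-averaged rate (accumulated phosphate / time), quantifying how
    far a 90-min endpoint assay sits from a true initial rate at low [GTP].
    Noise is per-point Gaussian (multiplicative ``noise_cv`` plus additive
    ``noise_sd_rate``); reported rates are clamped at zero since measured
    phosphate cannot be negative.
    """
    rng = np.random.default_rng(truth.seed)
    S = np.asarray(truth.substrate_grid, dtype=float)
    vmax = truth.kcat * truth.enzyme_conc
    if mode == "initial_rate":
        v = vmax * S / (truth.Km + S)
    elif mode == "depleting":
        v = np.empty_like(S)
        for i, s0 in enumerate(S):
            v[i] = _depleted_mean_rate(s0, vmax, truth.Km, incubation_min)
    else:
        raise ValueError("mode must be 'initial_rate' or 'depleting'")
    sd = truth.noise_cv * v + truth.noise_sd_rate
    noisy = v + rng.normal(0.0, 1.0, size=v.size) * sd
    noisy = np.clip(noisy, 0.0, None)
    return TitrationSeries(substrate=S, rate=noisy, condition=truth.condition)


def _depleted_mean_rate(s0: float, vmax: float, km: float, t_min: float) -> float:
    """Mean hydrolysis rate over an endpoint assay with substrate depletion.

    Integrates dS/dt = -vmax*S/(Km+S); the consumed substrate equals the
    accumulated phosphate, so the reported rate is (S0 - S(t))/t.
    """
    if s0 <= 0 or vmax == 0:
        return 0.0
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, s: -vmax * s / (km + s),
        (0.0, t_min),
        [s0],
        rtol=1e-10,
        atol=1e-12,
    )
    s_end = max(float(sol.y[0, -1]), 0.0)
    return (s0 - s_end) / t_min


def simulate_standard_series(
    slope: float,
    intercept: float,
    phosphate_points: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StandardSeries:
    """Synthesize a 0-5 uM phosphate standard series: A = slope*Pi + intercept."""
    pi = np.asarray(phosphate_points, dtype=float)
    if pi.size < 3:
        raise ValueError("a standard series needs at least 3 points")
    if np.any((pi < 0) | (pi > 5)):
        raise ValueError("standard points must lie within 0-5 uM")
    rng = np.random.default_rng(seed)
    a = slope * pi + intercept
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=pi.size)
    return StandardSeries(pi=pi, a621=a)


# --- plain-text IO -----------------------------------------------------------

def write_traces(traces: Iterable[LengthTrace], path) -> None:
    """Write traces as a tab-delimited table ``cell_id mt_id time_s length_um``."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "mt_id": tr.mt_id,
                "time_s": tr.times,
                "length_um": tr.lengths,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path) -> list[LengthTrace]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"cell_id", "mt_id", "time_s", "length_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    traces = []
    for (cell, mt), grp in df.groupby(["cell_id", "mt_id"], sort=False):
        traces.append(
            LengthTrace(
                cell_id=str(cell),
                mt_id=str(mt),
                times=grp["time_s"].to_numpy(),
                lengths=grp["length_um"].to_numpy(),
            )
        )
    return traces


def write_ground_truth(obj, path) -> None:
    """Emit a ground-truth sidecar (JSON) for test harnesses."""
    def encode(o):
        if isinstance(o, (SimParams, SummaryTargets, KineticGroundTruth, HazardSet)):
            # shallow: nested dataclasses are encoded by their own pass
            return {
                "__type__": type(o).__name__,
                **{f.name: getattr(o, f.name) for f in fields(o)},
            }
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"cannot serialise {type(o).__name__}")

    Path(path).write_text(json.dumps(obj, default=encode, indent=2) + "\n")


def read_ground_truth(path):
    types = {
        "SimParams": SimParams,
        "SummaryTargets": SummaryTargets,
        "KineticGroundTruth": KineticGroundTruth,
        "HazardSet": HazardSet,
    }

    def hook(d):
        name = d.pop("__type__", None)
        if name:
            if "substrate_grid" in d:
                d["substrate_grid"] = tuple(d["substrate_grid"])
            return types[name](**d)
        return d

    return json.loads(Path(path).read_text(), object_hook=hook)
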