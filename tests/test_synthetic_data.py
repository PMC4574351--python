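"""Generator tests: exact limits, seed determinism, and round-trip recovery."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tbckit.synthetic_data import (
    GROWTH,
    PAUSE,
    SHRINK,
    DYNAMICS_REFERENCE_TARGETS,
    HazardSet,
    KineticGroundTruth,
    LengthTrace,
    SimParams,
    SummaryTargets,
    hazards_from_summary,
    params_from_targets,
    path_statistics,
    read_ground_truth,
    read_traces,
    simulate_cohort,
    simulate_path,
    simulate_standard_series,
    simulate_titration,
    simulate_trace,
    solve_hazards,
    stationary_distribution,
    write_ground_truth,
    write_traces,
)

WT = DYNAMICS_REFERENCE_TARGETS["wild_type"]


def _random_hazards(rng):
    vals = rng.uniform(0.1, 3.0, size=6)
    return HazardSet(*vals)


class TestSimulateTrace:
    def test_deterministic_single_phase_limit(self):
        """With no transitions a growth-only trace rises linearly to v_g*t."""
        params = SimParams(
            v_g=1.4, v_s=3.0, hazards=HazardSet(), dt=4, duration=60,
            noise_sd=0.0, l0=0.0, seed=0, initial_state=GROWTH,
        )
        tr = simulate_trace(params)
        assert np.all(np.diff(tr.lengths) > 0)
        assert tr.times[-1] == 60.0
        assert tr.lengths[-1] == pytest.approx(1.4, rel=1e-12)

    def test_mean_growth_dwell_is_inverse_hazard(self):
        """First growth dwell averages 1/lambda_GS = 66.7 s at 0.9 min^-1."""
        params = SimParams(
            v_g=1.4, v_s=30.0, hazards=HazardSet(gs=0.9), duration=600,
            noise_sd=0.0, l0=5.0, initial_state=GROWTH, seed=0,
        )
        dwells = []
        for seed in range(2000):
            segs = simulate_path(SimParams(**{**params.__dict__, "seed": seed}))
            dwells.append(segs[0].t_end - segs[0].t_start)
        # exponential mean 66.7 s, SE ~1.5 s at n=2000
        assert np.mean(dwells) == pytest.approx(66.7, abs=5.0)

    def test_seed_determinism_bit_identical(self):
        params = params_from_targets(WT, seed=42)
        a, b = simulate_trace(params), simulate_trace(params)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.lengths, b.lengths)
        c = simulate_trace(SimParams(**{**params.__dict__, "seed": 43}))
        assert not np.array_equal(a.lengths, c.lengths)

    def test_time_conservation_and_contiguity(self, rng):
        """Dwell segments tile [0, duration] exactly, for arbitrary hazards."""
        for _ in range(50):
            params = SimParams(
                v_g=float(rng.uniform(0.5, 3)),
                v_s=float(rng.uniform(1, 5)),
                hazards=_random_hazards(rng),
                duration=200,
                l0=float(rng.uniform(0, 3)),
                seed=int(rng.integers(2**31)),
            )
            segs = simulate_path(params)
            assert segs[0].t_start == 0.0
            assert segs[-1].t_end == params.duration
            for s, t in zip(segs, segs[1:]):
                assert s.t_end == t.t_start

    def test_lengths_never_negative_and_renucleation(self):
        """The zero boundary clamps length and restarts growth."""
        params = SimParams(
            v_g=1.0, v_s=10.0, hazards=HazardSet(gs=3.0, sg=0.5),
            duration=600, l0=0.2, noise_sd=0.05, seed=7,
        )
        tr, segs = simulate_trace(params, return_path=True)
        assert np.all(tr.lengths >= 0)
        hits = [s for s in segs if s.renucleated]
        assert hits, "expected at least one renucleation at these rates"

    def test_truncate_boundary_ends_trace(self):
        params = SimParams(
            v_g=1.0, v_s=10.0, hazards=HazardSet(gs=5.0), duration=600,
            l0=2.0, seed=3, initial_state=GROWTH, zero_boundary="truncate",
        )
        segs = simulate_path(params)
        assert segs[-1].l_end == 0.0
        assert segs[-1].t_end < params.duration

    def test_degenerate_absorbing_shrink_rejected(self):
        params = SimParams(
            v_g=1.0, v_s=2.0, hazards=HazardSet(gs=1.0), duration=600,
            l0=0.0, initial_state=SHRINK, seed=0,
        )
        with pytest.raises(ValueError, match="degenerate"):
            simulate_path(params)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": 3.0},
            {"duration": 10.0},
            {"noise_sd": -0.1},
            {"l0": -1.0},
            {"v_g": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(v_g=1.4, v_s=3.0, hazards=HazardSet(), dt=4.0,
                    duration=600.0, noise_sd=0.05, l0=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimParams(**base)


class TestHazardSolver:
    def test_two_state_closed_form(self):
        """Pause disabled: frequencies map directly onto the two hazards."""
        targets = SummaryTargets(
            assembly_rate=1.4, disassembly_rate=3.0, catastrophe_freq=0.9,
            rescue_freq=1.5, pause_duration=None,
            assembly_duration=66.7, disassembly_duration=40.0,
        )
        hz = hazards_from_summary(targets)
        assert hz.gs == 0.9 and hz.sg == 1.5
        assert hz.gp == hz.sp == hz.ps == hz.pg == 0.0

    @pytest.mark.parametrize("label", sorted(DYNAMICS_REFERENCE_TARGETS))
    def test_reference_rows_solve_exactly(self, label):
        """Stationary-chain constraint residuals below 1e-8 for every row."""
        sol = solve_hazards(DYNAMICS_REFERENCE_TARGETS[label])
        assert sol.exact
        assert max(abs(v) for v in sol.residuals.values()) < 1e-8
        # dwell means are the inverse exit rates by construction
        t = DYNAMICS_REFERENCE_TARGETS[label]
        assert 60.0 / sol.hazards.exit_rate(GROWTH) == pytest.approx(
            t.assembly_duration, rel=1e-9
        )
        assert 60.0 / sol.hazards.exit_rate(PAUSE) == pytest.approx(
            t.pause_duration, rel=1e-9
        )

    def test_infeasible_targets_flagged(self):
        """Impossible frequency/dwell combinations return a flagged best fit."""
        bad = SummaryTargets(
            assembly_rate=1.4, disassembly_rate=3.0, catastrophe_freq=0.1,
            rescue_freq=200.0, pause_duration=60.0,
            assembly_duration=46.0, disassembly_duration=27.0,
        )
        sol = solve_hazards(bad)
        assert not sol.exact

    def test_non_positive_targets_rejected(self):
        with pytest.raises(ValueError):
            SummaryTargets(
                assembly_rate=-1, disassembly_rate=3, catastrophe_freq=0.9,
                rescue_freq=1.5, pause_duration=18,
                assembly_duration=46, disassembly_duration=27,
            )

    def test_two_state_limit_frequency(self):
        """Noiseless two-state chain: path catastrophe rate matches lambda_GS."""
        lam = 0.9
        params = SimParams(
            v_g=1.4, v_s=3.06, hazards=HazardSet(gs=lam, sg=1.5),
            duration=600, noise_sd=0.0, l0=2.0, seed=11,
        )
        _, paths = simulate_cohort(params, 500, seed=11, return_paths=True)
        per_mt = []
        t_g = n_c = 0.0
        for p in paths:
            st = path_statistics(p)
            t_g += st["t_growth"]
            n_c += st["n_catastrophes"]
            if st["t_growth"] > 0:
                per_mt.append(st["n_catastrophes"] / (st["t_growth"] / 60.0))
        pooled = n_c / (t_g / 60.0)
        se = np.std(per_mt, ddof=1) / math.sqrt(len(per_mt))
        assert abs(pooled - lam) < 3 * se

    def test_wild_type_roundtrip_chain_frequencies(self):
        """Solve -> simulate -> path frequencies recovers the targets (n=500)."""
        params = params_from_targets(WT, seed=0)
        _, paths = simulate_cohort(params, 500, seed=1, return_paths=True)
        stats = [path_statistics(p) for p in paths]
        tg = sum(s["t_growth"] for s in stats)
        ts = sum(s["t_shrink"] for s in stats)
        tp = sum(s["t_pause"] for s in stats)
        f_cat = sum(s["n_catastrophes"] for s in stats) / ((tg + tp) / 60.0)
        f_res = sum(s["n_rescues"] for s in stats) / ((ts + tp) / 60.0)
        cat_mt = [
            s["n_catastrophes"] / ((s["t_growth"] + s["t_pause"]) / 60.0)
            for s in stats
            if s["t_growth"] + s["t_pause"] > 0
        ]
        res_mt = [
            s["n_rescues"] / ((s["t_shrink"] + s["t_pause"]) / 60.0)
            for s in stats
            if s["t_shrink"] + s["t_pause"] > 0
        ]
        se_cat = np.std(cat_mt, ddof=1) / math.sqrt(len(cat_mt))
        se_res = np.std(res_mt, ddof=1) / math.sqrt(len(res_mt))
        assert abs(f_cat - WT.catastrophe_freq) < 3 * se_cat
        assert abs(f_res - WT.rescue_freq) < 3 * se_res
        # the published wild-type catastrophe frequency is met within 15%
        assert f_cat == pytest.approx(0.90, rel=0.15)


class TestKineticsGenerators:
    def test_half_saturation_identity(self):
        truth = KineticGroundTruth(Km=100, kcat=2.0, noise_cv=0.0,
                                   substrate_grid=(25, 50, 100, 200, 400))
        series = simulate_titration(truth)
        i = list(series.substrate).index(100)
        assert series.rate[i] == pytest.approx(1.0, rel=1e-12)

    def test_direct_mm_evaluation(self):
        """v(800; Km=100, kcat=2, E=1) = 1600/900 = 1.778 uM/min."""
        truth = KineticGroundTruth(Km=100, kcat=2.0, noise_cv=0.0)
        series = simulate_titration(truth)
        i = list(series.substrate).index(800)
        assert series.rate[i] == pytest.approx(1.778, abs=5e-4)

    def test_depleting_mode_underestimates_initial_rate(self):
        """Endpoint-averaged rates sit below true initial rates, worst at low S."""
        truth = KineticGroundTruth(Km=100, kcat=2.0, noise_cv=0.0)
        ideal = simulate_titration(truth, mode="initial_rate")
        depleted = simulate_titration(truth, mode="depleting")
        pos = ideal.substrate > 0
        assert np.all(depleted.rate[pos] < ideal.rate[pos])
        assert np.all(depleted.rate >= 0)
        rel = depleted.rate[pos] / ideal.rate[pos]
        # depletion bias shrinks monotonically as substrate rises
        assert np.all(np.diff(rel) > 0)

    def test_titration_seed_determinism(self):
        truth = KineticGroundTruth(Km=99, kcat=1.85, seed=5)
        a, b = simulate_titration(truth), simulate_titration(truth)
        assert np.array_equal(a.rate, b.rate)

    def test_standard_series_line_and_validation(self):
        series = simulate_standard_series(0.2, 0.05, (0, 2.5, 5.0), noise_sd=0.0)
        assert series.a621[1] == pytest.approx(0.55, rel=1e-12)
        with pytest.raises(ValueError):
            simulate_standard_series(0.2, 0.05, (0.0, 5.0))
        with pytest.raises(ValueError):
            simulate_standard_series(0.2, 0.05, (0.0, 3.0, 6.0))


class TestNoiseScaling:
    def test_recovered_rate_variance_grows_with_noise(self):
        """Classifier-input SNR degrades monotonically with noise_sd."""
        from tbckit.phase_classifier import classify_trace
        from tbckit.dynamics_stats import summarize_mt

        variances = []
        for noise in (0.0, 0.08, 0.2):
            params = SimParams(
                v_g=1.4, v_s=3.06, hazards=hazards_from_summary(WT),
                noise_sd=noise, seed=0,
            )
            traces = simulate_cohort(params, 120, seed=99)
            rates = [
                summarize_mt(classify_trace(tr), tr).assembly_rate
                for tr in traces
            ]
            rates = np.asarray(rates)
            variances.append(float(np.var(rates[np.isfinite(rates)])))
        assert variances[0] < variances[1] < variances[2]


class TestTraceIO:
    def test_trace_table_roundtrip(self, tmp_path):
        params = params_from_targets(WT, seed=2)
        traces = simulate_cohort(params, 4, seed=2)
        path = tmp_path / "traces.tsv"
        write_traces(traces, path)
        back = read_traces(path)
        assert len(back) == 4
        for a, b in zip(traces, back):
            assert (a.cell_id, a.mt_id) == (b.cell_id, b.mt_id)
            assert np.array_equal(a.times, b.times)
            assert np.array_equal(a.lengths, b.lengths)

    def test_ground_truth_sidecar_roundtrip(self, tmp_path):
        params = params_from_targets(WT, seed=3)
        truth = KineticGroundTruth(Km=99, kcat=1.85, seed=3)
        path = tmp_path / "truth.json"
        write_ground_truth({"sim": params, "kinetics": truth, "targets": WT}, path)
        back = read_ground_truth(path)
        assert back["sim"] == params
        assert back["kinetics"] == truth
        assert back["targets"] == WT

    def test_length_trace_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            LengthTrace("c", "m", np.array([0, 4, 8, 13.0]), np.zeros(4))
        with pytest.raises(ValueError, match="increasing"):
            LengthTrace("c", "m", np.array([0, 4, 4, 8.0]), np.zeros(4))
        with pytest.raises(ValueError):
            LengthTrace("c", "m", np.array([0, 4, 8.0]), np.zeros(3))


def test_stationary_distribution_matches_long_run():
    hz = hazards_from_summary(WT)
    pi = stationary_distribution(hz)
    assert pi.sum() == pytest.approx(1.0)
    q = hz.generator_matrix()
    assert np.allclose(pi @ q, 0.0, atol=1e-12)
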