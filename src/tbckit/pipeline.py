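"""End-to-end orchestration: generate -> classify -> summarize -> compare.

A :class:`RunConfig` (plain dict / YAML) describes every stage: the
per-condition dynamics targets and simulation settings, the kinetics ground
truths, the subunit mass table, significance levels, the output directory
and a master seed. The master seed fans out deterministically to
per-condition child seeds by hashing the condition label, so adding or
removing a condition never perturbs the others. Reruns with the same config
and seed are byte-identical; a manifest records the config hash and all
derived seeds.

All outputs are plain tab-delimited text with unit-bearing headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .complex_mass import (
    MassMeasurement,
    TUBULIN_DIMER_SEQUENCE_DA,
    YEAST_COFACTOR_MASSES_DA,
    mass_report,
)
from .dynamics_stats import (
    compare_conditions,
    condition_table,
    dynamics_long_table,
    summarize_condition,
    summarize_mt,
)
from .gtpase_kinetics import (
    KINETIC_REFERENCE_PARAMS,
    compare_kcat,
    fit_mm,
    mm_report,
)
from .phase_classifier import ClassifierConfig, classify_trace, phase_table, transition_table
from .synthetic_data import (
    DYNAMICS_REFERENCE_TARGETS,
    KineticGroundTruth,
    SimParams,
    SummaryTargets,
    hazards_from_summary,
    simulate_cohort,
    simulate_titration,
    write_traces,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "child_seed",
    "default_demo_config",
    "run_dynamics_pipeline",
    "run_kinetics_pipeline",
    "run_mass_report",
    "run_demo",
]


def child_seed(master: int, label: str) -> int:
    """Deterministic per-condition seed below 2**31 from a master seed."""
    return zlib.crc32(label.encode("utf-8"), master & 0xFFFFFFFF) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see module docstring)."""

    seed: int = 0
    out_dir: str = "tbckit_out"
    alpha: float = 0.05
    n_traces: int = 200
    dt: float = 4.0
    duration: float = 600.0
    noise_sd: float = 0.05
    l0: float = 0.9
    dynamics_conditions: dict[str, SummaryTargets] = field(default_factory=dict)
    dynamics_reference: str | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    kinetics_conditions: dict[str, tuple[float, float]] = field(default_factory=dict)
    kinetics_reference: str | None = None
    noise_cv: float = 0.03
    enzyme_conc: float = 1.0
    subunit_masses: dict[str, float] = field(default_factory=dict)
    mass_entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = list(self.dynamics_conditions) + list(self.kinetics_conditions)
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        dyn = {
            label: t if isinstance(t, SummaryTargets) else SummaryTargets(**t)
            for label, t in dict(raw.pop("dynamics_conditions", {})).items()
        }
        kin = {
            label: tuple(v)
            for label, v in dict(raw.pop("kinetics_conditions", {})).items()
        }
        clf = raw.pop("classifier", None)
        cfg = cls(
            dynamics_conditions=dyn,
            kinetics_conditions=kin,
            classifier=(
                clf if isinstance(clf, ClassifierConfig)
                else ClassifierConfig(**clf) if clf else ClassifierConfig()
            ),
            **raw,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dynamics_conditions"] = {
            k: asdict(v) for k, v in self.dynamics_conditions.items()
        }
        d["kinetics_conditions"] = {
            k: list(v) for k, v in self.kinetics_conditions.items()
        }
        d["classifier"] = asdict(self.classifier)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def default_demo_config(seed: int = 0, out_dir: str = "tbckit_out") -> RunConfig:
    """The built-in demo: reference dynamics, kinetics and mass reproductions."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        dynamics_conditions=dict(DYNAMICS_REFERENCE_TARGETS),
        dynamics_reference="wild_type",
        kinetics_conditions={
            k: KINETIC_REFERENCE_PARAMS[k]
            for k in (
                "TBC-DEG:TBCC:tubulin",
                "TBC-DEG:TBCC",
                "TBC-DEG:TBCC-R186A:tubulin",
                "TBC-DEG:TBCC-dLoop:tubulin",
                "TBC-DEG-Q73L:TBCC:tubulin",
            )
        },
        kinetics_reference="TBC-DEG:TBCC:tubulin",
        subunit_masses={
            **YEAST_COFACTOR_MASSES_DA,
            "tubulin_dimer": TUBULIN_DIMER_SEQUENCE_DA,
        },
        mass_entries=[
            ("TBC-DEG", {"TBCD": 1, "TBCE": 1, "Arl2": 1}, (215.0, 10.0)),
            (
                "TBC-DEG:tubulin",
                {"TBCD": 1, "TBCE": 1, "Arl2": 1, "tubulin_dimer": 1},
                (310.0, 10.0),
            ),
            (
                "TBC-DEG:TBCC:tubulin",
                {"TBCD": 1, "TBCE": 1, "Arl2": 1, "tubulin_dimer": 1, "TBCC": 1},
                (335.0, 10.0),
            ),
        ],
    )


def _write_manifest(
    out: Path, config: RunConfig, seeds: Mapping[str, int], name: str
) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "master_seed": config.seed,
        "condition_seeds": dict(seeds),
    }
    (out / name).write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")


def run_dynamics_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Simulate, classify and summarize every dynamics condition.

    Writes ``traces.tsv``, ``phases.tsv``, ``transitions.tsv``,
    ``per_mt.tsv``, ``condition_summary.tsv`` and (when a reference
    condition is set) ``comparison.tsv`` under ``config.out_dir``, plus a
    manifest. Returns the tables keyed by name.
    """
    if not config.dynamics_conditions:
        raise ValueError("no dynamics conditions configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds: dict[str, int] = {}
    trace_frames, phase_frames, trans_frames = [], [], []
    cohorts: dict[str, list] = {}
    summaries = []
    for label, targets in config.dynamics_conditions.items():
        stage = "simulate"
        try:
            seed = child_seed(config.seed, label)
            seeds[label] = seed
            params = SimParams(
                v_g=targets.assembly_rate,
                v_s=targets.disassembly_rate,
                hazards=hazards_from_summary(targets),
                dt=config.dt,
                duration=config.duration,
                noise_sd=config.noise_sd,
                l0=config.l0,
                seed=seed,
            )
            traces = simulate_cohort(params, config.n_traces, seed=seed)
            stage = "classify"
            segs = [classify_trace(tr, config.classifier) for tr in traces]
            stage = "summarize"
            dyn = [summarize_mt(s, tr) for s, tr in zip(segs, traces)]
            cohorts[label] = dyn
            summaries.append(summarize_condition(dyn, label))

            tf = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "cell_id": tr.cell_id,
                            "mt_id": tr.mt_id,
                            "time_s": tr.times,
                            "length_um": tr.lengths,
                        }
                    )
                    for tr in traces
                ],
                ignore_index=True,
            )
            tf.insert(0, "condition", label)
            trace_frames.append(tf)
            pf = phase_table(segs)
            pf.insert(0, "condition", label)
            phase_frames.append(pf)
            xf = transition_table(segs)
            xf.insert(0, "condition", label)
            trans_frames.append(xf)
        except Exception as exc:
            raise RuntimeError(
                f"dynamics pipeline failed at stage {stage!r} for condition "
                f"{label!r}: {exc}"
            ) from exc

    tables = {
        "traces": pd.concat(trace_frames, ignore_index=True),
        "phases": pd.concat(phase_frames, ignore_index=True),
        "transitions": pd.concat(trans_frames, ignore_index=True),
        "per_mt": dynamics_long_table(cohorts),
        "condition_summary": condition_table(summaries),
    }
    ref = config.dynamics_reference
    if ref is not None:
        if ref not in cohorts:
            raise RuntimeError(f"reference condition {ref!r} was not run")
        comps = []
        for label, dyn in cohorts.items():
            if label == ref:
                continue
            c = compare_conditions(
                cohorts[ref], dyn, alpha=config.alpha, label_a=ref, label_b=label
            )
            c.insert(0, "condition", label)
            c = c.rename(
                columns={f"mean_{ref}": "mean_reference", f"mean_{label}": "mean"}
            )
            comps.append(c)
        if comps:
            tables["comparison"] = pd.concat(comps, ignore_index=True)

    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    _write_manifest(out, config, seeds, "manifest_dynamics.json")
    return tables


def run_kinetics_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Simulate and fit every kinetics condition; write a kinetics report.

    The report has one row per condition (Km, kcat and standard errors,
    convergence flag) plus the percent change of kcat against the reference
    condition when one is configured.
    """
    if not config.kinetics_conditions:
        raise ValueError("no kinetics conditions configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds: dict[str, int] = {}
    frames, fits = [], []
    for label, (km, kcat) in config.kinetics_conditions.items():
        stage = "simulate"
        try:
            seed = child_seed(config.seed, label)
            seeds[label] = seed
            truth = KineticGroundTruth(
                Km=km,
                kcat=kcat,
                enzyme_conc=config.enzyme_conc,
                noise_cv=config.noise_cv,
                seed=seed,
                condition=label,
            )
            series = simulate_titration(truth)
            stage = "fit"
            fits.append(fit_mm(series, enzyme_conc=config.enzyme_conc))
            frames.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "substrate_uM": series.substrate,
                        "rate_uM_per_min": series.rate,
                    }
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"kinetics pipeline failed at stage {stage!r} for condition "
                f"{label!r}: {exc}"
            ) from exc

    report = mm_report(fits)
    if config.kinetics_reference is not None:
        pct = compare_kcat(fits, config.kinetics_reference)
        report = report.merge(
            pct[["condition", "kcat_ratio", "percent_decrease"]], on="condition"
        )
    tables = {
        "titrations": pd.concat(frames, ignore_index=True),
        "kinetics_report": report,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    _write_manifest(out, config, seeds, "manifest_kinetics.json")
    return tables


def run_mass_report(config: RunConfig) -> pd.DataFrame:
    """Predicted-vs-measured mass table for the configured complexes."""
    if not config.mass_entries:
        raise ValueError("no mass entries configured")
    entries = [
        (
            label,
            counts,
            MassMeasurement(mean=meas[0], sd=meas[1]) if meas else None,
        )
        for label, counts, meas in config.mass_entries
    ]
    df = mass_report(entries, config.subunit_masses)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "mass_report.tsv", sep="\t", index=False)
    return df


def run_demo(config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Full reproduction run: dynamics, kinetics and mass reports."""
    cfg = config or default_demo_config()
    tables = {}
    tables.update(run_dynamics_pipeline(cfg))
    tables.update(run_kinetics_pipeline(cfg))
    tables["mass_report"] = run_mass_report(cfg)
    return tables
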