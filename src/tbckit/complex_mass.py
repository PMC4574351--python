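"""Mass bookkeeping for tubulin-cofactor chaperone complexes.

Predicts the molecular mass of an integer stoichiometric composition of
subunits and, inversely, enumerates which compositions are consistent with
a measured mass (e.g. from SEC-MALS) within a stated uncertainty.

All arithmetic is carried out in daltons; kilodalton rounding happens only
at display time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SubunitMass",
    "ComplexComposition",
    "MassMeasurement",
    "YEAST_COFACTOR_MASSES_DA",
    "TUBULIN_DIMER_SEQUENCE_DA",
    "TUBULIN_DIMER_MALS_DA",
    "predicted_mass",
    "infer_stoichiometry",
    "read_subunit_table",
    "write_subunit_table",
    "mass_report",
]


@dataclass(frozen=True)
class SubunitMass:
    """A named subunit and its molecular mass in daltons."""

    name: str
    mass: float  # Da

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("subunit name must be non-empty")
        if not self.mass > 0:
            raise ValueError(f"subunit mass must be positive, got {self.mass}")


#: Molecular masses of the yeast tubulin-cofactor subunits (Da), as determined
#: by mass spectrometry of the purified chaperone.
YEAST_COFACTOR_MASSES_DA: dict[str, float] = {
    "TBCD": 116_647.8,
    "TBCE": 59_257.6,
    "Arl2": 22_066.6,
    "TBCC": 34_045.4,
}

#: Nominal sequence mass of an alpha/beta-tubulin heterodimer (Da), the value
#: used for predicted complex masses.
TUBULIN_DIMER_SEQUENCE_DA: float = 110_000.0

#: Apparent mass of the free alpha/beta-tubulin dimer from light scattering
#: (Da); shipped as an alternative preset for sensitivity checks.
TUBULIN_DIMER_MALS_DA: float = 100_000.0


def _as_mass_map(subunits) -> dict[str, float]:
    """Normalise a subunit table (mapping or SubunitMass iterable) to name->Da."""
    if isinstance(subunits, Mapping):
        table = {str(k): float(v) for k, v in subunits.items()}
    else:
        table = {s.name: float(s.mass) for s in subunits}
    for name, mass in table.items():
        if not mass > 0:
            raise ValueError(f"subunit {name!r} has non-positive mass {mass}")
    return table


@dataclass(frozen=True)
class ComplexComposition:
    """An integer subunit stoichiometry with its exactly-summed mass.

    ``counts`` maps subunit name to a non-negative copy number;
    ``predicted_mass`` is the exact weighted sum in daltons.
    """

    counts: Mapping[str, int]
    predicted_mass: float  # Da

    @property
    def predicted_kda(self) -> float:
        return self.predicted_mass / 1000.0

    def label(self) -> str:
        parts = [
            f"{n}x{c}" if c != 1 else n
            for n, c in sorted(self.counts.items())
            if c > 0
        ]
        return ":".join(parts) if parts else "(empty)"


@dataclass(frozen=True)
class MassMeasurement:
    """A measured complex mass (kDa) with its uncertainty and method label."""

    mean: float  # kDa
    sd: float  # kDa
    method: str = "SEC-MALS"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("mass uncertainty must be non-negative")


def predicted_mass(counts: Mapping[str, int], subunits) -> float:
    """Exact mass (Da) of an integer composition.

    Parameters
    ----------
    counts
        Mapping subunit name -> non-negative integer copy number.
    subunits
        Mapping name -> mass (Da), or an iterable of :class:`SubunitMass`.
    """
    table = _as_mass_map(subunits)
    total = 0.0
    for name, n in counts.items():
        if name not in table:
            raise KeyError(f"unknown subunit {name!r}")
        if n < 0 or int(n) != n:
            raise ValueError(f"copy number for {name!r} must be a non-negative integer")
        total += int(n) * table[name]
    return total


def infer_stoichiometry(
    measured: MassMeasurement,
    subunits,
    max_copies: int = 2,
    tolerance_sd: float = 2.0,
) -> list[ComplexComposition]:
    """Enumerate integer compositions consistent with a measured mass.

    Every composition with per-subunit copy numbers in ``0..max_copies``
    (excluding the empty composition) is scored against ``measured.mean``;
    those with ``|predicted - mean| <= tolerance_sd * sd`` (masses in kDa)
    are returned sorted by absolute residual, ties broken lexicographically
    by composition.

    An empty list means no composition fits; that is a result, not an error.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    table = _as_mass_map(subunits)
    if not table:
        raise ValueError("at least one subunit is required")

    names = sorted(table)
    tol_kda = tolerance_sd * measured.sd
    hits: list[tuple[float, tuple[int, ...], ComplexComposition]] = []
    for combo in itertools.product(range(max_copies + 1), repeat=len(names)):
        if not any(combo):
            continue
        mass_da = sum(c * table[n] for n, c in zip(names, combo))
        residual = abs(mass_da / 1000.0 - measured.mean)
        if residual <= tol_kda:
            comp = ComplexComposition(
                counts=dict(zip(names, combo)), predicted_mass=mass_da
            )
            hits.append((residual, combo, comp))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [h[2] for h in hits]


def read_subunit_table(path) -> dict[str, float]:
    """Read a two-column tab-delimited subunit table ``name  mass_da``."""
    df = pd.read_csv(path, sep="\t")
    if not {"name", "mass_da"}.issubset(df.columns):
        raise ValueError("subunit table must have columns 'name' and 'mass_da'")
    return _as_mass_map(dict(zip(df["name"], df["mass_da"])))


def write_subunit_table(subunits, path) -> None:
    table = _as_mass_map(subunits)
    df = pd.DataFrame({"name": list(table), "mass_da": list(table.values())})
    df.to_csv(path, sep="\t", index=False)


def mass_report(
    entries: Sequence[tuple[str, Mapping[str, int], MassMeasurement | None]],
    subunits,
) -> pd.DataFrame:
    """Predicted-vs-measured comparison table for a set of complexes.

    ``entries`` is a sequence of (label, composition counts, measurement or
    None). Predicted masses are reported both exactly (Da) and rounded (kDa).
    """
    rows = []
    for label, counts, meas in entries:
        pred_da = predicted_mass(counts, subunits)
        row: dict[str, object] = {
            "complex": label,
            "predicted_da": pred_da,
            "predicted_kda": round(pred_da / 1000.0),
        }
        if meas is not None:
            row["measured_kda"] = meas.mean
            row["measured_sd_kda"] = meas.sd
            row["residual_kda"] = pred_da / 1000.0 - meas.mean
            row["method"] = meas.method
        rows.append(row)
    return pd.DataFrame(rows)
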