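"""Malachite-green GTPase assay analysis.

The colorimetric assay measures free phosphate released by GTP hydrolysis:
absorbance at 621 nm is calibrated against a linear 0-5 uM phosphate
standard series, converted to phosphate concentration, and divided by the
incubation time (90 min by default) to give a mean hydrolysis rate. Rates
across a GTP titration (0-800 uM) are then fitted to the Michaelis-Menten
model

    v(S) = Vmax * S / (Km + S),

with the turnover number k_cat = Vmax / [E] for enzyme concentration [E]
(1 uM in the standard assay, so k_cat in min^-1 equals Vmax in uM/min).

Fitting is unweighted nonlinear least squares; a weighting hook is exposed
for users with replicate-based variance estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "StandardSeries",
    "TitrationSeries",
    "MMFit",
    "KINETIC_REFERENCE_PARAMS",
    "fit_standard_curve",
    "absorbance_to_rate",
    "michaelis_menten",
    "fit_mm",
    "compare_kcat",
    "mm_report",
    "read_titration",
    "write_titration",
    "read_standard_series",
    "write_standard_series",
]

#: Reference (Km [uM], kcat [min^-1]) parameter sets for the yeast TBC-DEG
#: chaperone GTPase under the standard 1 uM enzyme assay. Keys name the
#: assembled reaction; these drive the demo pipeline and recovery tests.
KINETIC_REFERENCE_PARAMS: dict[str, tuple[float, float]] = {
    "TBC-DEG": (400.0, 0.06),
    "TBCC:tubulin": (20.0, 0.00),
    "TBC-DEG:tubulin": (69.0, 0.40),
    "TBC-DEG:TBCC": (94.0, 0.77),
    "TBC-DEG:TBCC:tubulin": (99.0, 1.85),
    "TBC-DEG-Q73L:TBCC:tubulin": (371.0, 0.50),
    "TBC-DEG:TBCC-R186A:tubulin": (40.0, 0.54),
    "TBC-DEG:TBCC-dLoop:tubulin": (35.0, 0.34),
}


@dataclass(frozen=True)
class StandardSeries:
    """Phosphate standard curve points: known Pi (uM) vs absorbance at 621 nm."""

    pi: np.ndarray  # uM
    a621: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        object.__setattr__(self, "a621", np.asarray(self.a621, dtype=float))
        if self.pi.shape != self.a621.shape or self.pi.ndim != 1:
            raise ValueError("pi and a621 must be 1-d arrays of equal length")
        if self.pi.size < 3:
            raise ValueError("a standard series needs at least 3 points")
        if np.any(self.pi < 0):
            raise ValueError("phosphate concentrations must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """GTP titration: substrate concentrations (uM) and hydrolysis rates (uM/min)."""

    substrate: np.ndarray  # uM
    rate: np.ndarray  # uM/min
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate", np.asarray(self.substrate, dtype=float))
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        if self.substrate.shape != self.rate.shape or self.substrate.ndim != 1:
            raise ValueError("substrate and rate must be 1-d arrays of equal length")
        if np.any(self.substrate < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if np.unique(self.substrate).size != self.substrate.size:
            raise ValueError("substrate concentrations must be distinct")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters for one titration.

    ``kcat`` is ``Vmax / enzyme_conc`` exactly; standard errors come from the
    local linearization (Jacobian) at the optimum.
    """

    Km: float  # uM
    Vmax: float  # uM/min
    kcat: float  # min^-1
    enzyme_conc: float  # uM
    Km_se: float
    kcat_se: float
    converged: bool
    residual_norm: float
    condition: str = ""


def michaelis_menten(S, Vmax: float, Km: float):
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def fit_standard_curve(series: StandardSeries) -> tuple[float, float, float]:
    """Ordinary least-squares line through the phosphate standard points.

    Returns ``(slope, intercept, r_squared)`` with slope in absorbance per uM.
    """
    if np.unique(series.pi).size < 2:
        raise ValueError("standard series needs at least 2 distinct Pi levels")
    res = stats.linregress(series.pi, series.a621)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def absorbance_to_rate(
    a621,
    slope: float,
    intercept: float,
    incubation_min: float = 90.0,
) -> np.ndarray:
    """Convert raw 621 nm absorbances to mean hydrolysis rates (uM/min).

    Phosphate is ``(A - intercept) / slope``, clamped at zero (a blank cannot
    contain negative phosphate; clamped points are logged, not fatal), and the
    rate assumes linear phosphate accumulation over the incubation.
    """
    if not slope > 0:
        raise ValueError("standard-curve slope must be positive")
    if not incubation_min > 0:
        raise ValueError("incubation time must be positive")
    a621 = np.asarray(a621, dtype=float)
    pi = (a621 - intercept) / slope
    n_neg = int(np.sum(pi < 0))
    if n_neg:
        for val in pi[pi < 0]:
            logger.warning("clamping negative phosphate %.4g uM to 0", val)
        pi = np.clip(pi, 0.0, None)
    return pi / incubation_min


def _km_initial_guess(S: np.ndarray, v: np.ndarray, vmax0: float) -> float:
    """Substrate concentration at half of the maximal observed rate.

    Interpolates along the titration sorted by substrate; falls back to the
    median positive substrate level for pathological data.
    """
    half = vmax0 / 2.0
    order = np.argsort(S)
    S_s, v_s = S[order], v[order]
    above = np.nonzero(v_s >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        dv = v_s[i] - v_s[i - 1]
        frac = (half - v_s[i - 1]) / dv if dv != 0 else 0.5
        guess = S_s[i - 1] + frac * (S_s[i] - S_s[i - 1])
        if guess > 0:
            return float(guess)
    pos = S_s[S_s > 0]
    return float(np.median(pos)) if pos.size else 1.0


def fit_mm(
    series: TitrationSeries,
    enzyme_conc: float = 1.0,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    xtol: float = 1e-13,
) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit of a titration.

    Initialised at ``Vmax0 = max(v)`` and ``Km0 =`` the interpolated substrate
    level at half-maximal rate. Convergence (relative parameter change below
    ``xtol`` within ``max_iter`` residual evaluations) is reported in the
    ``converged`` flag rather than raised. ``weights`` multiplies residuals
    (unweighted by default).
    """
    if not enzyme_conc > 0:
        raise ValueError("enzyme_conc must be positive")
    S, v = series.substrate, series.rate
    if np.unique(S).size < 5:
        raise ValueError("Michaelis-Menten fitting needs >= 5 distinct substrate levels")

    if np.all(v == 0):
        # no detectable activity: Vmax 0, Km unidentifiable
        return MMFit(
            Km=float("nan"), Vmax=0.0, kcat=0.0, enzyme_conc=enzyme_conc,
            Km_se=float("nan"), kcat_se=float("nan"), converged=True,
            residual_norm=0.0, condition=series.condition,
        )

    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    vmax0 = float(np.max(v))
    km0 = _km_initial_guess(S, v, vmax0)

    # fit in rate-normalized units: conditions the problem and makes the
    # result equivariant under rescaling of the rates
    v_norm = v / vmax0

    def resid(p):
        return w * (michaelis_menten(S, p[0], p[1]) - v_norm)

    def jac(p):
        denom = p[1] + S
        d_vmax = S / denom
        d_km = -p[0] * S / denom**2
        return np.column_stack([w * d_vmax, w * d_km])

    sol = optimize.least_squares(
        resid,
        x0=[1.0, km0],
        jac=jac,
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        xtol=xtol,
        ftol=None,
        gtol=None,
        x_scale="jac",
        max_nfev=max_iter,
    )
    # Gauss-Newton polish: the trust-region search stops on the float-flat
    # cost plateau; a few Newton steps pin the stationary point to ~1e-13
    # so the fit is reproducible under rescaled inputs
    p = sol.x.copy()
    for _ in range(50):
        J = jac(p)
        r = resid(p)
        try:
            step = np.linalg.solve(J.T @ J, J.T @ r)
        except np.linalg.LinAlgError:
            break
        cand = p - step
        if not (cand[0] >= 0 and cand[1] > 0):
            break
        p = cand
        if np.max(np.abs(step) / np.maximum(np.abs(p), 1e-300)) < 1e-13:
            break
    vmax_hat, km_hat = float(p[0]) * vmax0, float(p[1])
    sol.x = p
    converged = bool(sol.status > 0)
    if not converged:
        logger.warning(
            "Michaelis-Menten fit did not converge for %r", series.condition
        )

    # standard errors from the Jacobian at the (polished) optimum
    km_se = vmax_se = float("nan")
    r_hat = resid(p)
    sse = float(r_hat @ r_hat)
    dof = S.size - 2
    if dof > 0:
        try:
            cov = np.linalg.inv(jac(p).T @ jac(p)) * (sse / dof)
            vmax_se = float(np.sqrt(cov[0, 0])) * vmax0  # undo normalization
            km_se = float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass

    if not km_hat > 0 or not S[S > np.nextafter(0, 1)].size:
        logger.warning("fitted Km %.3g outside the titration design", km_hat)
    elif not (S.min() < km_hat < S.max()):
        logger.warning(
            "titration does not bracket the fitted Km (%.3g uM); estimate may "
            "be poorly constrained", km_hat,
        )

    return MMFit(
        Km=km_hat,
        Vmax=vmax_hat,
        kcat=vmax_hat / enzyme_conc,
        enzyme_conc=enzyme_conc,
        Km_se=km_se,
        kcat_se=vmax_se / enzyme_conc,
        converged=converged,
        residual_norm=float(np.sqrt(sse)) * vmax0,
        condition=series.condition,
    )


def compare_kcat(fits: Sequence[MMFit], reference: str) -> pd.DataFrame:
    """Percent change of each condition's k_cat relative to a reference.

    Returns one row per fit with the k_cat ratio and the percent decrease
    ``100 * (kcat_ref - kcat) / kcat_ref`` (negative = faster than reference).
    """
    by_label = {f.condition: f for f in fits}
    if reference not in by_label:
        raise KeyError(f"reference condition {reference!r} not among the fits")
    kref = by_label[reference].kcat
    if kref == 0:
        raise ValueError("reference kcat is zero; percent change undefined")
    rows = [
        {
            "condition": f.condition,
            "kcat_per_min": f.kcat,
            "kcat_ratio": f.kcat / kref,
            "percent_decrease": 100.0 * (kref - f.kcat) / kref,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def mm_report(fits: Sequence[MMFit]) -> pd.DataFrame:
    """Kinetics summary table: one row per condition with Km/kcat and errors."""
    return pd.DataFrame(
        [
            {
                "condition": f.condition,
                "Km_uM": f.Km,
                "Km_se": f.Km_se,
                "kcat_per_min": f.kcat,
                "kcat_se": f.kcat_se,
                "converged": f.converged,
            }
            for f in fits
        ]
    )


# --- plain-text table IO ---------------------------------------------------

def write_titration(series: TitrationSeries, path) -> None:
    pd.DataFrame(
        {"substrate_uM": series.substrate, "rate_uM_per_min": series.rate}
    ).to_csv(path, sep="\t", index=False)


def read_titration(path, condition: str = "") -> TitrationSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return TitrationSeries(
        substrate=df["substrate_uM"].to_numpy(),
        rate=df["rate_uM_per_min"].to_numpy(),
        condition=condition,
    )


def write_standard_series(series: StandardSeries, path) -> None:
    pd.DataFrame({"pi_uM": series.pi, "a621": series.a621}).to_csv(
        path, sep="\t", index=False
    )


def read_standard_series(path) -> StandardSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return StandardSeries(pi=df["pi_uM"].to_numpy(), a621=df["a621"].to_numpy())
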