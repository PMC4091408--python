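"""Absolute calibration and synthesis of centromeric copy-number estimates.

Three routes meet here: (i) the quantitative-immunoblot standard curve against
purified recombinant protein converts a cellular lane signal into molecules
per cell, which combined with the imaging-derived centromeric fraction gives a
point estimate of molecules per centromere; (ii) the fluctuation route
provides a minimum; (iii) a calibrated fluorescent standard (a LacO array
binding at most 204 GFP-LacI molecules) provides a maximum. The module also
fits the forced-through-origin proportionality between centromeric and total
pools that characterizes mass-action regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.constants import Avogadro

__all__ = [
    "StandardCurve",
    "BlotQuantification",
    "CopyNumberEstimate",
    "ProportionalityFit",
    "fit_standard_curve",
    "molecules_per_cell",
    "combine",
    "standard_bound",
    "proportionality_fit",
    "cross_method_summary",
    "report_int",
]

MOLAR_MASS_UNTAGGED = 16_000.0  # Da, ~16 kDa CENP-A
MOLAR_MASS_TAGGED = 43_000.0    # Da, ~43 kDa GFP/YFP fusion


@dataclass
class StandardCurve:
    """OLS fit of blot signal against loaded mass (ng) of purified protein."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    masses: np.ndarray = field(default_factory=lambda: np.array([]))
    signals: np.ndarray = field(default_factory=lambda: np.array([]))
    linear_range_fold: float = np.nan
    max_relative_deviation: float = np.nan
    linear: bool = True


@dataclass
class BlotQuantification:
    mass_ng: float
    molecules_total: float
    molecules_per_cell: float
    n_cells: int
    molar_mass: float


@dataclass
class CopyNumberEstimate:
    molecules_per_centromere: float
    method: str                   # integrated_fluorescence | fluctuation_min | standard_max
    bound_type: str = "point"     # point | lower | upper
    molecules_per_cell: float = np.nan
    uncertainty: float = np.nan   # SEM


@dataclass
class ProportionalityFit:
    """Least-squares line through the origin and its r^2 against that line.

    ``r_squared = 1 - SS_res / SS_tot`` with residuals taken against ``y = kx``
    and total variation against the mean of y; it may be negative when the
    proportional line fits worse than a constant, and is reported as-is.
    """

    slope: float
    r_squared: float
    n: int


def fit_standard_curve(masses, signals, linearity_tol: float = 0.2) -> StandardCurve:
    """Ordinary least squares of signal on mass, with a linearity diagnostic.

    The diagnostic is the maximum relative deviation of the per-point
    intercept-corrected signal/mass ratio from the fitted slope, evaluated
    over the full fold range spanned by the standards; the curve is flagged
    non-linear when it exceeds ``linearity_tol``.
    """
    masses = np.asarray(masses, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if masses.size < 3:
        raise ValueError("at least 3 standards are required for a curve")
    if np.unique(masses).size < 2:
        raise ValueError("masses must span at least 2 distinct values")
    fit = stats.linregress(masses, signals)
    pos = masses > 0
    ratios = (signals[pos] - fit.intercept) / masses[pos]
    max_dev = float(np.max(np.abs(ratios / fit.slope - 1.0))) if fit.slope != 0 else np.inf
    fold = float(masses[pos].max() / masses[pos].min()) if pos.any() else np.nan
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        slope_stderr=float(fit.stderr),
        masses=masses,
        signals=signals,
        linear_range_fold=fold,
        max_relative_deviation=max_dev,
        linear=bool(fit.slope > 0 and max_dev <= linearity_tol),
    )


def molecules_per_cell(curve: StandardCurve, sample_signal: float,
                       n_cells: int, molar_mass: float = MOLAR_MASS_UNTAGGED,
                       loading_control: float | None = None) -> BlotQuantification:
    """Convert a sample lane signal to molecules per cell via the curve.

    ``mass = (signal - intercept) / slope`` (ng), then Avogadro arithmetic at
    the given molar mass. An optional per-lane loading-control scalar divides
    the signal before conversion. Raises when the signal falls below the
    intercept (no measurable mass).
    """
    signal = sample_signal / loading_control if loading_control else sample_signal
    mass_ng = (signal - curve.intercept) / curve.slope
    if mass_ng <= 0:
        raise ValueError("sample signal at or below the curve intercept")
    molecules = mass_ng * 1e-9 * Avogadro / molar_mass
    return BlotQuantification(
        mass_ng=float(mass_ng),
        molecules_total=float(molecules),
        molecules_per_cell=float(molecules / n_cells),
        n_cells=int(n_cells),
        molar_mass=molar_mass,
    )


def combine(fraction: float, per_cell: float, fraction_sem: float = 0.0,
            per_cell_sem: float = 0.0) -> CopyNumberEstimate:
    """Molecules per centromere = centromeric fraction x molecules per cell.

    The SEM is propagated in quadrature from the two relative uncertainties.
    """
    point = fraction * per_cell
    sem = np.nan
    if fraction > 0 and per_cell > 0:
        rel = math.hypot(fraction_sem / fraction, per_cell_sem / per_cell)
        sem = point * rel
    return CopyNumberEstimate(
        molecules_per_centromere=float(point),
        method="integrated_fluorescence",
        bound_type="point",
        molecules_per_cell=float(per_cell),
        uncertainty=float(sem),
    )


def standard_bound(spot_signal: float, standard_signal: float,
                   standard_copies: float = 204.0,
                   relative_level: float = 1.0) -> CopyNumberEstimate:
    """Upper bound from a calibrated fluorescent standard.

    The standard (a LacO array) can bind at most ``standard_copies``
    GFP molecules but need not be fully occupied, so
    ``spot/standard x standard_copies`` bounds the focus copy number from
    above. Wild-type scaling divides by ``relative_level``; the bound is
    rounded *up* (a bound must not shrink by rounding).
    """
    if standard_signal <= 0:
        raise ValueError("standard_signal must be > 0")
    if relative_level <= 0:
        raise ValueError("relative_level must be > 0")
    copies = spot_signal / standard_signal * standard_copies
    wt = copies / relative_level
    return CopyNumberEstimate(
        molecules_per_centromere=float(math.ceil(wt)),
        method="standard_max",
        bound_type="upper",
    )


def proportionality_fit(x, y) -> ProportionalityFit:
    """Fit ``y = kx`` (least squares through the origin)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must be equal-length with >= 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("x must not be all zero")
    k = float(np.sum(x * y) / sxx)
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return ProportionalityFit(slope=k, r_squared=float(r2), n=int(x.size))


def cross_method_summary(estimates) -> tuple[pd.DataFrame, bool]:
    """Three-method comparison table with a bound-ordering consistency check.

    Returns ``(table, consistent)``: every lower bound must not exceed any
    point estimate, and no point estimate may exceed any upper bound.
    """
    rows = [
        {
            "method": e.method,
            "bound_type": e.bound_type,
            "molecules_per_centromere": e.molecules_per_centromere,
            "reported": report_int(e),
        }
        for e in estimates
    ]
    table = pd.DataFrame(rows)
    lowers = [e.molecules_per_centromere for e in estimates if e.bound_type == "lower"]
    points = [e.molecules_per_centromere for e in estimates if e.bound_type == "point"]
    uppers = [e.molecules_per_centromere for e in estimates if e.bound_type == "upper"]
    consistent = True
    for lo in lowers:
        if any(lo > p for p in points) or any(lo > u for u in uppers):
            consistent = False
    for p in points:
        if any(p > u for u in uppers):
            consistent = False
    return table, consistent


def report_int(estimate: CopyNumberEstimate) -> int:
    """Round an estimate for reporting: half-up points, ceil uppers, floor lowers."""
    x = estimate.molecules_per_centromere
    if estimate.bound_type == "upper":
        return int(math.ceil(x))
    if estimate.bound_type == "lower":
        return int(math.floor(x))
    return int(math.floor(x + 0.5))
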