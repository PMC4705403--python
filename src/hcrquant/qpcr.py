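"""Sigmoidal amplification-curve fitting and efficiency-corrected qPCR quantification.

Each well of a plate yields a baseline-subtracted fluorescence trace. The trace is
fit with a Richards sigmoid

    F(x) = Fmax / (1 + exp(-(x - c) / b))**d

whose early (exponential) phase multiplies fluorescence by ``exp(d / b)`` per cycle.
From the fit we take Cy0 — the cycle at which the tangent drawn at the curve's
inflection point crosses zero fluorescence — an efficiency-robust alternative to
threshold cycles. Per-reaction amplification efficiency is estimated from the
window-of-linearity around Cy0 (slope of log2 fluorescence over the cycle nearest
Cy0 and the two cycles on either side), averaged per amplicon per plate, and the
relative expression of a well is ``Eff**(-Cy0)``. The plate-average efficiency
correction mirrors the LinRegPCR family of methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "AmplificationCurve",
    "RichardsFit",
    "PlateQuant",
    "richards",
    "fit_amplification_model",
    "compute_cy0",
    "estimate_reaction_efficiency",
    "quantify_plate",
    "expression_value",
]

MIN_CYCLES = 10
#: Plausible band for a per-amplicon mean efficiency (fold per cycle). PCR cannot
#: more than double product per cycle; a small overshoot is allowed for noise.
EFFICIENCY_BAND = (1.0, 2.2)


def richards(x, fmax: float, b: float, c: float, d: float):
    """Richards (generalised logistic) curve, overflow-safe.

    ``d = 1`` reduces to the plain logistic. ``b`` sets the rise width in cycles,
    ``c`` the horizontal position, ``d`` the asymmetry.
    """
    x = np.asarray(x, dtype=float)
    # log F = log fmax - d * log(1 + exp(-(x - c)/b))
    return fmax * np.exp(-d * np.logaddexp(0.0, -(x - c) / b))


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's baseline-subtracted fluorescence trace.

    Cycles are 1-based, strictly increasing integers; fluorescence is in arbitrary
    (already baseline-subtracted) units, one value per cycle.
    """

    well_id: str
    amplicon: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        cycles = np.asarray(self.cycles, dtype=int)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if cycles.shape != fluo.shape or cycles.ndim != 1:
            raise ValueError(
                f"well {self.well_id}: cycles and fluorescence must be 1-D and of "
                f"equal length (got {cycles.shape} vs {fluo.shape})"
            )
        if len(cycles) < MIN_CYCLES:
            raise ValueError(
                f"well {self.well_id}: need at least {MIN_CYCLES} cycles, got {len(cycles)}"
            )
        if np.any(np.diff(cycles) <= 0):
            raise ValueError(f"well {self.well_id}: cycles must be strictly increasing")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)


@dataclass
class RichardsFit:
    """Fitted Richards parameters for one amplification curve.

    ``cy0`` is populated by :func:`compute_cy0`; ``converged`` is False for
    non-amplifying or unfittable curves (never an exception).
    """

    well_id: str = ""
    amplicon: str = ""
    fmax: float = float("nan")
    b: float = float("nan")
    c: float = float("nan")
    d: float = float("nan")
    rmse: float = float("nan")
    converged: bool = False
    cy0: float = float("nan")


def _initial_guesses(cycles: np.ndarray, fluo: np.ndarray) -> list[tuple[float, float, float, float]]:
    """Landmark-based multi-start initial guesses (fmax, b, c, d)."""
    fmax0 = float(np.max(fluo))
    half = fmax0 / 2.0
    above = np.nonzero(fluo >= half)[0]
    c0 = float(cycles[above[0]]) if len(above) else float(np.median(cycles))
    lo = np.nonzero(fluo >= 0.25 * fmax0)[0]
    hi = np.nonzero(fluo >= 0.75 * fmax0)[0]
    if len(lo) and len(hi):
        width = max(float(cycles[hi[0]] - cycles[lo[0]]), 0.5)
    else:
        width = 2.0
    b0 = max(width / 2.2, 0.3)  # logistic rises 25->75% over ~2.2 b
    guesses = []
    for d0 in (1.0, 0.5, 2.0):
        for bscale in (1.0, 2.0):
            guesses.append((fmax0, b0 * bscale, c0, d0))
    return guesses


def fit_amplification_model(curve: AmplificationCurve, fix_d: bool = False) -> RichardsFit:
    """Least-squares Richards fit of a single amplification curve.

    Non-amplifying curves (no positive signal, no dynamic range) and optimizer
    failures yield ``converged=False`` rather than raising. Cy0 is computed and
    stored on the returned fit when the fit converges.

    Parameters
    ----------
    curve : AmplificationCurve
    fix_d : bool
        Fit the plain logistic (d pinned to 1) instead of the full 4-parameter
        Richards model.
    """
    x = curve.cycles.astype(float)
    y = curve.fluorescence
    fit = RichardsFit(well_id=curve.well_id, amplicon=curve.amplicon)

    ymax = float(np.max(y))
    if ymax <= 0 or np.ptp(y) == 0 or not np.all(np.isfinite(y)):
        return fit  # flat / non-amplifying

    best = None
    for fmax0, b0, c0, d0 in _initial_guesses(x, y):
        if fix_d:
            p0 = [fmax0, b0, c0]
            model = lambda xx, fmax, b, c: richards(xx, fmax, b, c, 1.0)
            bounds = ([1e-9, 1e-3, -10.0], [20 * ymax, 50.0, 2 * x[-1]])
        else:
            p0 = [fmax0, b0, c0, d0]
            model = richards
            bounds = ([1e-9, 1e-3, -10.0, 1e-3], [20 * ymax, 50.0, 2 * x[-1], 50.0])
        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-10, ftol=1e-10
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - model(x, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)

    if best is None and not fix_d:
        return fit_amplification_model(curve, fix_d=True)
    if best is None:
        return fit

    sse, popt = best
    if fix_d:
        fmax, b, c = popt
        d = 1.0
    else:
        fmax, b, c, d = popt
    rmse = math.sqrt(sse / len(y))
    # reject fits that explain less than the curve's own spread
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.8 or fmax <= 0 or b <= 0 or d <= 0:
        fit.rmse = rmse
        return fit

    fit.fmax, fit.b, fit.c, fit.d = float(fmax), float(b), float(c), float(d)
    fit.rmse = rmse
    fit.converged = True
    fit.cy0 = compute_cy0(fit)
    return fit


def compute_cy0(fit: RichardsFit) -> float:
    """Cy0: x-intercept of the tangent at the fitted curve's inflection point.

    For the Richards curve the inflection lies at ``x* = c + b ln d`` with
    ``F(x*) = Fmax (1 + 1/d)^-d`` and ``F'(x*) = (Fmax / b)(1 + 1/d)^-(d+1)``, so

        Cy0 = x* - F(x*)/F'(x*) = c + b ln d - b (1 + 1/d).

    The logistic special case (d = 1) gives ``Cy0 = c - 2b``.
    """
    if not fit.converged and not (
        np.isfinite(fit.b) and np.isfinite(fit.c) and np.isfinite(fit.d) and fit.b > 0 and fit.d > 0
    ):
        raise ValueError(f"well {fit.well_id!r}: cannot compute Cy0 from a non-converged fit")
    cy0 = fit.c + fit.b * math.log(fit.d) - fit.b * (1.0 + 1.0 / fit.d)
    fit.cy0 = cy0
    return cy0


def estimate_reaction_efficiency(curve: AmplificationCurve, cy0: float) -> float:
    """Per-reaction amplification efficiency from the 5-cycle window around Cy0.

    The slope ``m`` of a least-squares line through log2(fluorescence) versus cycle
    at the cycle nearest Cy0 and the two cycles before and after it gives
    ``Eff = 2**m`` (fold per cycle; perfect doubling -> 2.0).

    Raises
    ------
    ValueError
        If the 5-cycle window extends past the trace or contains non-positive
        fluorescence.
    """
    if not np.isfinite(cy0):
        raise ValueError("cy0 must be finite")
    idx = int(np.argmin(np.abs(curve.cycles - cy0)))
    if idx - 2 < 0 or idx + 2 >= len(curve.cycles):
        raise ValueError(
            f"well {curve.well_id}: efficiency window around Cy0={cy0:.2f} "
            "extends outside the recorded cycles"
        )
    w = slice(idx - 2, idx + 3)
    fw = curve.fluorescence[w]
    if np.any(fw <= 0):
        raise ValueError(
            f"well {curve.well_id}: non-positive fluorescence in the efficiency window"
        )
    slope = float(np.polyfit(curve.cycles[w].astype(float), np.log2(fw), 1)[0])
    return 2.0 ** slope


def expression_value(efficiency: float, cy0: float) -> float:
    """Relative expression ``Eff**(-Cy0)``; strictly decreasing in Cy0 for Eff > 1."""
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    return efficiency ** (-cy0)


@dataclass
class PlateQuant:
    """Quantification of one plate.

    ``table`` has one row per converged well (columns: well, amplicon, cy0,
    efficiency, expression); ``amplicon_efficiency`` maps amplicon label to the
    plate-mean efficiency used in the expression values; ``excluded`` records the
    wells dropped and why.
    """

    table: pd.DataFrame
    amplicon_efficiency: dict[str, float]
    excluded: list[tuple[str, str]] = field(default_factory=list)


def quantify_plate(
    curves: list[AmplificationCurve],
    fix_d: bool = False,
    efficiency_band: tuple[float, float] = EFFICIENCY_BAND,
) -> PlateQuant:
    """Fit every curve on a plate and compute per-well relative expression.

    Per amplicon the plate efficiency is the mean of the per-reaction window
    efficiencies over converged wells; each converged well's expression is
    ``(mean Eff)**(-Cy0)``. Wells that fail to converge, or whose efficiency
    window is unusable, are excluded and logged on the result.

    Raises
    ------
    ValueError
        If no well converges for some amplicon, or a plate-mean efficiency falls
        outside the sanity band (1, 2.2].
    """
    if not curves:
        raise ValueError("empty plate")
    rows = []
    excluded: list[tuple[str, str]] = []
    per_amp_eff: dict[str, list[float]] = {}
    amplicons = []
    for curve in curves:
        if curve.amplicon not in amplicons:
            amplicons.append(curve.amplicon)
        fit = fit_amplification_model(curve, fix_d=fix_d)
        if not fit.converged:
            excluded.append((curve.well_id, "fit did not converge"))
            continue
        try:
            eff = estimate_reaction_efficiency(curve, fit.cy0)
        except ValueError as exc:
            excluded.append((curve.well_id, f"efficiency window: {exc}"))
            continue
        per_amp_eff.setdefault(curve.amplicon, []).append(eff)
        rows.append({"well": curve.well_id, "amplicon": curve.amplicon,
                     "cy0": fit.cy0, "efficiency": eff})

    amplicon_efficiency = {}
    for amp in amplicons:
        effs = per_amp_eff.get(amp, [])
        if not effs:
            raise ValueError(f"no converged curve for amplicon {amp!r}")
        mean_eff = float(np.mean(effs))
        lo, hi = efficiency_band
        if not (lo < mean_eff <= hi):
            raise ValueError(
                f"amplicon {amp!r}: plate-mean efficiency {mean_eff:.3f} outside "
                f"sanity band ({lo}, {hi}]"
            )
        amplicon_efficiency[amp] = mean_eff

    table = pd.DataFrame(rows, columns=["well", "amplicon", "cy0", "efficiency"])
    table["expression"] = [
        expression_value(amplicon_efficiency[a], c)
        for a, c in zip(table["amplicon"], table["cy0"])
    ]
    return PlateQuant(table=table, amplicon_efficiency=amplicon_efficiency, excluded=excluded)
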