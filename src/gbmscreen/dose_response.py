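"""Four-parameter logistic dose-response fitting, EC50/AUC extraction and growth rates.

The viability model is the standard 4PL curve

    V(D) = bottom + (top - bottom) / (1 + (D / ec50)^hill)

with ``hill > 0`` so that viability falls from ``top`` (vehicle-like, low dose)
to ``bottom`` (maximal inhibition, high dose).  Two fitting conventions are
supported: a free four-parameter least-squares fit, and the anchored
convention used in end-point screens where ``top`` is pinned to the mean
viability at the lowest dose and ``bottom`` to the mean viability at the
highest dose, leaving only (ec50, hill) free.

Sensitivity summaries are the fitted EC50, the normalised area under the
viability-vs-log10(dose) curve (a mean viability, in [0, 1] for viability
<= 1; lower = more sensitive), and interpolated viability at a common dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .exceptions import (
    DegenerateFitError,
    ExtrapolationError,
    InsufficientDataError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: multistart grid over the Hill slope; fixed for reproducibility
HILL_STARTS = (0.5, 1.0, 2.0, 4.0)
#: optimizer budget per start
MAX_NFEV = 10_000
#: convergence tolerance on the residual sum of squares
RSS_TOL = 1e-10


@dataclass(frozen=True)
class DoseResponseSeries:
    """Replicate viability fractions over a dose ladder for one (cell line, drug) pair.

    ``viability[i]`` holds the replicate fractions-of-vehicle measured at
    ``doses[i]``; ladders may be ragged across doses.  Concentrations are
    stored in a single recorded unit (nM internally throughout the package).
    """

    cell_line: str
    drug: str
    doses: np.ndarray
    viability: tuple[np.ndarray, ...]
    unit: str = "nM"
    timepoint_h: float = 72.0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(
            self, "viability", tuple(np.asarray(v, dtype=float) for v in self.viability)
        )
        if doses.ndim != 1 or len(doses) != len(self.viability):
            raise ValidationError("doses and viability must align one-to-one")
        if len(doses) and (np.any(doses <= 0) or np.any(np.diff(doses) <= 0)):
            raise ValidationError("doses must be strictly increasing and positive")
        for v in self.viability:
            if np.any(~np.isfinite(v)) or np.any(v < 0):
                raise ValidationError("viability must be finite and >= 0")

    @property
    def mean_viability(self) -> np.ndarray:
        """Arithmetic mean of replicates per dose."""
        return np.array([v.mean() for v in self.viability])

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All (dose, viability) observations flattened across replicates."""
        d = np.concatenate([np.full(len(v), x) for x, v in zip(self.doses, self.viability)])
        y = np.concatenate(self.viability)
        return d, y


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    anchored: bool = False

    def predict(self, dose) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float), self.bottom, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class GrowthFit:
    rate: float
    doubling_time_h: float
    rss: float
    growing: bool = True


def four_pl(dose, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the four-parameter logistic viability curve."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def _fit_theta(dose, y, resid, x0, bounds):
    sol = least_squares(resid, x0, bounds=bounds, max_nfev=MAX_NFEV, xtol=1e-14, ftol=RSS_TOL, gtol=None)
    return sol


def fit_4pl(series: DoseResponseSeries, anchor_asymptotes: bool = True) -> FourPLFit:
    """Least-squares 4PL fit of a dose-response series.

    With ``anchor_asymptotes`` (the end-point screen convention) the top
    asymptote is fixed to the mean viability at the lowest dose and the bottom
    to the mean at the highest dose; only (ec50, hill) are free.  Otherwise
    all four parameters are fitted.  A fixed multistart over Hill slopes
    ``HILL_STARTS`` is used and the best-RSS solution returned.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 distinct doses.
    DegenerateFitError
        All viability values identical.
    """
    if len(np.unique(series.doses)) < 4:
        raise InsufficientDataError(
            f"{series.cell_line}/{series.drug}: need >= 4 distinct doses, got {len(series.doses)}"
        )
    d, y = series.pooled()
    if np.ptp(y) == 0:
        raise DegenerateFitError(f"{series.cell_line}/{series.drug}: all viability values identical")

    logd = np.log10(d)
    means = series.mean_viability
    # scale-free ec50 starting points, expressed in log10 dose
    ec50_starts = [np.median(logd), logd.min() + 0.25 * np.ptp(logd), logd.max() - 0.25 * np.ptp(logd)]
    lo_e, hi_e = logd.min() - 3.0, logd.max() + 3.0

    best = None
    if anchor_asymptotes:
        top = float(means[0])
        bottom = float(means[-1])

        def resid(theta):
            le, lh = theta
            return four_pl(d, bottom, top, 10.0 ** le, 10.0 ** lh) - y

        bounds = ([lo_e, -2.0], [hi_e, 2.0])
        for h0 in HILL_STARTS:
            for e0 in ec50_starts:
                sol = _fit_theta(d, y, resid, [e0, np.log10(h0)], bounds)
                if best is None or sol.cost < best.cost:
                    best = sol
        le, lh = best.x
        fit = FourPLFit(bottom, top, 10.0 ** le, 10.0 ** lh, 2.0 * best.cost, best.success, True)
    else:
        b0, t0 = float(means.min()), float(means.max())
        span = max(np.ptp(means), 0.1)

        def resid(theta):
            b, t, le, lh = theta
            return four_pl(d, b, t, 10.0 ** le, 10.0 ** lh) - y

        bounds = (
            [b0 - 2 * span, t0 - 2 * span, lo_e, -2.0],
            [b0 + 2 * span, t0 + 2 * span, hi_e, 2.0],
        )
        for h0 in HILL_STARTS:
            for e0 in ec50_starts:
                sol = _fit_theta(d, y, resid, [b0, t0, e0, np.log10(h0)], bounds)
                if best is None or sol.cost < best.cost:
                    best = sol
        b, t, le, lh = best.x
        fit = FourPLFit(float(b), float(t), 10.0 ** le, 10.0 ** lh, 2.0 * best.cost, best.success, False)
    if not fit.converged:
        log.warning("4PL fit did not converge for %s/%s", series.cell_line, series.drug)
    return fit


def compute_auc(series: DoseResponseSeries) -> float:
    """Normalised area under the viability-vs-log10(dose) curve.

    Trapezoidal integral of mean viability over log10(dose), divided by the
    log10 dose range, i.e. a mean viability across the ladder.  Lower values
    indicate greater sensitivity.
    """
    if len(series.doses) < 2:
        raise InsufficientDataError("AUC needs >= 2 doses")
    x = np.log10(series.doses)
    y = series.mean_viability
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def viability_at_dose(series: DoseResponseSeries, dose: float) -> float:
    """Mean viability at ``dose``, log10-linearly interpolated off-ladder.

    Raises :class:`ExtrapolationError` for doses outside the ladder.
    """
    if dose < series.doses[0] or dose > series.doses[-1]:
        raise ExtrapolationError(
            f"dose {dose} outside ladder [{series.doses[0]}, {series.doses[-1]}] {series.unit}"
        )
    means = series.mean_viability
    exact = np.flatnonzero(np.isclose(series.doses, dose, rtol=1e-12))
    if exact.size:
        return float(means[exact[0]])
    return float(np.interp(np.log10(dose), np.log10(series.doses), means))


def fit_doubling_time(times_h: Sequence[float], signal: Sequence[float]) -> GrowthFit:
    """Exponential growth fit s(t) = s0 * exp(rate * t) via OLS on log signal.

    doubling_time_h = ln(2)/rate; a non-positive rate is reported as
    non-growing with an undefined (NaN) doubling time.
    """
    t = np.asarray(times_h, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.shape != s.shape or t.ndim != 1:
        raise ValidationError("times_h and signal must be equal-length 1-D")
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 timepoints for a growth fit")
    if np.any(s <= 0):
        raise ValidationError("signal must be strictly positive")
    res = linregress(t, np.log(s))
    rate = float(res.slope)
    pred = res.intercept + rate * t
    rss = float(np.sum((np.log(s) - pred) ** 2))
    if rate <= 0:
        log.warning("non-growing series (rate=%.3g /h); doubling time undefined", rate)
        return GrowthFit(rate, float("nan"), rss, growing=False)
    return GrowthFit(rate, float(np.log(2) / rate), rss, growing=True)
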