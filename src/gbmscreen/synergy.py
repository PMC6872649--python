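"""Median-effect analysis and Chou-Talalay combination-index synergy scoring.

The median-effect equation fa/fu = (D/Dm)^m linearises as

    log10(fa / (1 - fa)) = m * log10(D) - m * log10(Dm)

and is fitted by ordinary least squares to each single agent and to the
fixed-ratio mixture treated as one composite agent.  At an effect level fa
the mixture's total dose splits into components by the design ratio and the
combination index is the mutually-exclusive Chou-Talalay form

    CI(fa) = d1 / Dx1(fa) + d2 / Dx2(fa),   Dx = Dm * (fa/(1-fa))^(1/m).

CI < 0.8 is called synergism, 0.8 <= CI <= 1.2 addition, CI > 1.2
antagonism (boundary values fall in the additive band).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .exceptions import IncompleteDesignError, InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

#: fa values outside (CLIP_EPS, 1 - CLIP_EPS) carry no linearisable information
CLIP_EPS = 0.005
#: CI bands: below -> synergism, inside (inclusive) -> addition, above -> antagonism
CI_THRESHOLDS = (0.8, 1.2)

SYNERGISM = "synergism"
ADDITION = "addition"
ANTAGONISM = "antagonism"


@dataclass(frozen=True)
class CombinationGrid:
    """Fixed-ratio combination design: single-agent arms plus the mixture.

    ``rows`` has columns (d1, d2, fa): drug1 alone (d2 == 0), drug2 alone
    (d1 == 0) and combination rows whose d1:d2 ratio is constant.
    """

    drug1: str
    drug2: str
    ratio: float
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"d1", "d2", "fa"}
        if not need.issubset(self.rows.columns):
            raise ValidationError(f"grid rows missing columns {sorted(need - set(self.rows.columns))}")
        fa = self.rows["fa"].to_numpy()
        if np.any(fa < 0) or np.any(fa > 1):
            raise ValidationError("fa must lie in [0, 1]")
        comb = self.combination_rows()
        if len(comb):
            r = comb["d1"].to_numpy() / comb["d2"].to_numpy()
            if np.any(np.abs(r - self.ratio) > 1e-9 * max(self.ratio, 1.0)):
                raise ValidationError("combination rows deviate from the stated d1:d2 ratio")

    def single_agent_rows(self, which: int) -> pd.DataFrame:
        if which == 1:
            return self.rows[(self.rows["d1"] > 0) & (self.rows["d2"] == 0)]
        return self.rows[(self.rows["d2"] > 0) & (self.rows["d1"] == 0)]

    def combination_rows(self) -> pd.DataFrame:
        return self.rows[(self.rows["d1"] > 0) & (self.rows["d2"] > 0)]

    def swapped(self) -> "CombinationGrid":
        """The same design with drug1 and drug2 relabelled (ratio inverted)."""
        rows = self.rows.rename(columns={"d1": "d2", "d2": "d1"})[["d1", "d2", "fa"]]
        return CombinationGrid(self.drug2, self.drug1, 1.0 / self.ratio, rows)


@dataclass(frozen=True)
class MedianEffectFit:
    dm: float
    m: float
    r: float
    n_points: int
    n_excluded: int = 0

    def fa(self, dose) -> np.ndarray:
        x = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        return x / (1.0 + x)


@dataclass(frozen=True)
class CombinationIndexResult:
    fa_level: float
    ci: float
    call: str
    d1: float
    d2: float


def viability_to_fa(viability) -> np.ndarray:
    """fa = 1 - viability; viability above vehicle control maps to fa = 0."""
    v = np.asarray(viability, dtype=float)
    return np.clip(1.0 - v, 0.0, 1.0)


def fit_median_effect(doses, fa, clip_eps: float = CLIP_EPS) -> MedianEffectFit:
    """OLS fit of the linearised median-effect equation.

    Observations with fa outside (clip_eps, 1 - clip_eps) are excluded from
    the linearisation (logged, counted in ``n_excluded``); at least two
    usable dose levels must remain.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if d.shape != f.shape or d.ndim != 1:
        raise ValidationError("doses and fa must be equal-length 1-D")
    if np.any(d <= 0):
        raise ValidationError("doses must be strictly positive")
    keep = (f > clip_eps) & (f < 1.0 - clip_eps)
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.warning("excluding %d fa value(s) outside (%g, %g) from median-effect fit",
                    n_excluded, clip_eps, 1 - clip_eps)
    d, f = d[keep], f[keep]
    if len(np.unique(d)) < 2:
        raise InsufficientDataError(f"median-effect fit needs >= 2 usable dose levels, got {len(np.unique(d))}")
    y = np.log10(f / (1.0 - f))
    x = np.log10(d)
    res = linregress(x, y)
    m = float(res.slope)
    dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(dm=dm, m=m, r=float(res.rvalue), n_points=len(d), n_excluded=n_excluded)


def dose_for_effect(fit: MedianEffectFit, fa_level: float) -> float:
    """Invert the median-effect curve: Dx = Dm * (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa_level < 1.0:
        raise ValidationError(f"fa_level must be in (0, 1), got {fa_level}")
    return float(fit.dm * (fa_level / (1.0 - fa_level)) ** (1.0 / fit.m))


def classify_ci(ci: float, thresholds: tuple[float, float] = CI_THRESHOLDS) -> str:
    """Map a combination index to synergism / addition / antagonism."""
    if ci <= 0:
        raise ValidationError(f"combination index must be positive, got {ci}")
    lo, hi = thresholds
    if ci < lo:
        return SYNERGISM
    if ci > hi:
        return ANTAGONISM
    return ADDITION


def combination_index(
    grid: CombinationGrid,
    fa_level: float = 0.5,
    thresholds: tuple[float, float] = CI_THRESHOLDS,
    clip_eps: float = CLIP_EPS,
) -> CombinationIndexResult:
    """Combination index of a fixed-ratio design at one effect level.

    Fits median-effect curves to drug1 alone, drug2 alone and the mixture
    (total dose d1 + d2 as a composite agent); the mixture dose achieving
    ``fa_level`` splits by the design ratio into (d1, d2) and
    CI = d1/Dx1 + d2/Dx2.
    """
    arm1 = grid.single_agent_rows(1)
    arm2 = grid.single_agent_rows(2)
    comb = grid.combination_rows()
    for name, arm in (("drug1", arm1), ("drug2", arm2), ("combination", comb)):
        if arm.empty:
            raise IncompleteDesignError(f"grid is missing its {name} arm")
    fit1 = fit_median_effect(arm1["d1"], arm1["fa"], clip_eps)
    fit2 = fit_median_effect(arm2["d2"], arm2["fa"], clip_eps)
    fit_mix = fit_median_effect(comb["d1"] + comb["d2"], comb["fa"], clip_eps)

    d_comb = dose_for_effect(fit_mix, fa_level)
    d1 = d_comb * grid.ratio / (1.0 + grid.ratio)
    d2 = d_comb / (1.0 + grid.ratio)
    ci = d1 / dose_for_effect(fit1, fa_level) + d2 / dose_for_effect(fit2, fa_level)
    return CombinationIndexResult(fa_level, float(ci), classify_ci(ci, thresholds), d1, d2)


def ci_at_ec50(grid: CombinationGrid, **kwargs) -> CombinationIndexResult:
    """CI at the 50% effect level — the per-cell-line CI_EC50 summary."""
    return combination_index(grid, fa_level=0.5, **kwargs)
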