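"""Paired differential expression, FDR adjustment, correlations and ddCt fold change.

Differential expression between matched control/treated replicate pairs is a
per-gene paired t-test on log2 values; p-values are adjusted to q-values by
Benjamini-Hochberg step-up (the default; equivalent to Storey's q-value with
pi0 = 1) or by Storey's method with the smoother pi0 estimate.  Top-gene
selection is by ascending q with documented tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedExpressionSet:
    """Matched control/treated log2 expression: two genes x pairs frames."""

    control: pd.DataFrame
    treated: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.control.index.equals(self.treated.index):
            raise ValidationError("control and treated must share the same gene index")
        if self.control.shape[1] != self.treated.shape[1]:
            raise ValidationError("every treated replicate needs a control partner")
        if self.control.shape[1] < 2:
            raise InsufficientDataError("paired testing needs >= 2 pairs")


def paired_t_test(pairs: PairedExpressionSet) -> pd.DataFrame:
    """Per-gene paired t-test on differences d = treated - control.

    Returns a frame indexed by gene with columns mean_diff, t_stat, p_value,
    direction ('up' for mean_diff > 0) and zero_variance flag.  Genes whose
    differences have zero variance get the degenerate limits t = 0, p = 1
    (zero mean) or t = +-inf, p = 0 (nonzero mean, flagged).
    """
    d = (pairs.treated.to_numpy() - pairs.control.to_numpy()).astype(float)
    if np.any(~np.isfinite(d)):
        raise ValidationError("non-finite expression values")
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    t = np.where(zero_var, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    p = np.where(zero_var, np.where(mean == 0, 1.0, 0.0), p)
    if np.any(zero_var & (mean != 0)):
        log.warning("%d gene(s) with zero-variance nonzero differences: p -> 0 limit",
                    int(np.sum(zero_var & (mean != 0))))
    return pd.DataFrame(
        {
            "mean_diff": mean,
            "t_stat": t,
            "p_value": p,
            "direction": np.where(mean > 0, "up", "down"),
            "zero_variance": zero_var,
        },
        index=pairs.control.index.rename("gene"),
    )


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 with the cubic-spline smoother evaluated at max(lambda)."""
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    p = np.asarray(p, dtype=float)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = CubicSpline(lambdas, pi0_lambda)
    pi0 = float(spline(lambdas.max()))
    return float(np.clip(pi0, 1e-8, 1.0))


def adjust_q(p_values, method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values.

    'bh' is Benjamini-Hochberg step-up; 'storey' rescales BH by the smoother
    pi0 estimate (q_storey = pi0 * q_bh).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([])
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        return np.minimum(storey_pi0(p) * q, 1.0)
    raise ValidationError(f"unknown adjustment method: {method!r}")


def top_n_genes(results: pd.DataFrame, n: int, direction: str) -> tuple[list[str], bool]:
    """Top n genes of one direction, ranked by ascending q.

    Ties on q break by |t| descending, then gene id lexicographic.  Returns
    (genes, exhausted) where ``exhausted`` is True when fewer than n genes of
    the requested direction exist.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if results.empty:
        raise ValidationError("empty results table")
    if "q_value" not in results.columns:
        raise ValidationError("results must carry q_value (run adjust_q first)")
    sub = results[results["direction"] == direction].copy()
    sub["_abs_t"] = -sub["t_stat"].abs()  # negated so a plain ascending sort ranks large |t| first
    sub.index.name = "gene"
    ordered = sub.reset_index().sort_values(["q_value", "_abs_t", "gene"], kind="mergesort")["gene"].tolist()
    exhausted = len(ordered) < n
    if exhausted:
        log.warning("only %d %s-regulated genes available (requested %d)", len(ordered), direction, n)
    return ordered[:n], exhausted


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("x and y must be equal-length 1-D with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method: {method!r}")
    return float(res[0]), float(res[1])


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Comparative ddCt fold change: 2^-((Ct_t,s - Ct_r,s) - (Ct_t,c - Ct_r,c))."""
    cts = [ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator]
    if not all(np.isfinite(c) for c in cts):
        raise ValidationError("all Ct values (target and reference gene) must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
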