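"""Sensitive-vs-resistant +-1 expression signature: derivation, cohort scoring, classification.

The signature is a gene list with weight +1 for genes upregulated in the
sensitive cell-line class and -1 for genes upregulated in the resistant
class.  A cohort sample is scored by the Pearson correlation between its
per-gene z-score profile (z-scored gene-wise across the cohort) and the
weight vector; scores >= theta are called sensitive-like, <= -theta
resistant-like (boundaries inclusive, default theta = 0.2), the rest
unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, UnusableSignatureError, ValidationError

log = logging.getLogger(__name__)

SENSITIVE_LIKE = "sensitive-like"
RESISTANT_LIKE = "resistant-like"
UNCLASSIFIED = "unclassified"


def _canon(gene: str) -> str:
    return str(gene).strip().upper()


@dataclass(frozen=True)
class SignatureVector:
    """Gene weights in {+1, -1}; +1 = sensitive-up, -1 = resistant-up."""

    weights: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weights
        if w.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in signature")
        if not set(np.unique(w.to_numpy())) <= {-1, 1}:
            raise ValidationError("signature weights must be +1 or -1")
        if (w == 1).sum() == 0 or (w == -1).sum() == 0:
            raise UnusableSignatureError("signature needs at least one gene of each sign")

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def flipped(self) -> "SignatureVector":
        return SignatureVector(-self.weights, dict(self.provenance))


@dataclass(frozen=True)
class CohortScore:
    sample: str
    subtype: str | None
    score: float
    call: str
    theta: float
    degenerate: bool = False


def derive_signature(
    expr: pd.DataFrame,
    labels: Mapping[str, str],
    n_per_class: int = 50,
) -> SignatureVector:
    """Derive the +-1 signature from a labelled cell-line expression matrix.

    Per gene, a Welch two-sample t-test compares sensitive vs resistant lines
    (log2 values); the ``n_per_class`` genes most significantly up in each
    class (ascending p among genes with the class-favouring sign) define the
    signature.
    """
    sens = [s for s in expr.columns if labels.get(s) == "sensitive"]
    res = [s for s in expr.columns if labels.get(s) == "resistant"]
    if len(sens) < 2 or len(res) < 2:
        raise InsufficientDataError(
            f"need >= 2 cell lines per class, got {len(sens)} sensitive / {len(res)} resistant"
        )
    a = expr[sens].to_numpy()
    b = expr[res].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame({"p": p, "diff": diff, "gene": expr.index.map(_canon)})
    up_s = table[table["diff"] > 0].sort_values(["p", "gene"], kind="mergesort")["gene"].head(n_per_class)
    up_r = table[table["diff"] < 0].sort_values(["p", "gene"], kind="mergesort")["gene"].head(n_per_class)
    overlap = set(up_s) & set(up_r)
    if overlap:
        log.warning("excluding %d gene(s) appearing in both directions: %s", len(overlap), sorted(overlap))
    weights = pd.Series(
        {**{g: 1 for g in up_s if g not in overlap}, **{g: -1 for g in up_r if g not in overlap}},
        dtype=int,
    )
    prov = {
        "requested_per_class": n_per_class,
        "retained_up_sensitive": int((weights == 1).sum()),
        "retained_up_resistant": int((weights == -1).sum()),
    }
    return SignatureVector(weights, prov)


def intersect_with_cohort(sig: SignatureVector, cohort_genes) -> SignatureVector:
    """Restrict the signature to genes measured in the cohort.

    Matching is exact string match after uppercasing/trimming.  Raises if a
    sign class is emptied by the intersection.
    """
    cohort = {_canon(g) for g in cohort_genes}
    keep = [g for g in sig.weights.index if _canon(g) in cohort]
    w = sig.weights.loc[keep]
    req_pos = int((sig.weights == 1).sum())
    req_neg = int((sig.weights == -1).sum())
    if w.empty or (w == 1).sum() == 0 or (w == -1).sum() == 0:
        raise UnusableSignatureError(
            f"cohort intersection emptied a sign class ({req_pos}+/{req_neg}- requested, "
            f"{int((w == 1).sum())}+/{int((w == -1).sum())}- retained)"
        )
    prov = dict(sig.provenance)
    prov.update(
        requested_up_sensitive=req_pos,
        requested_up_resistant=req_neg,
        retained_up_sensitive=int((w == 1).sum()),
        retained_up_resistant=int((w == -1).sum()),
    )
    dropped = len(sig.weights) - len(w)
    if dropped:
        log.info("cohort intersection dropped %d of %d signature genes", dropped, len(sig.weights))
    return SignatureVector(w, prov)


def zscore_cohort(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise z-scores across samples: (x - mean) / sd, sd with ddof=1.

    Zero-variance genes are dropped with a warning.
    """
    if expr.shape[1] < 3:
        raise InsufficientDataError(f"cohort z-scoring needs >= 3 samples, got {expr.shape[1]}")
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.warning("dropping %d zero-variance gene(s): %s", int(flat.sum()), list(expr.index[flat][:10]))
    z = expr.loc[~flat].sub(mu[~flat], axis=0).div(sd[~flat], axis=0)
    return z


def score_samples(
    z: pd.DataFrame,
    sig: SignatureVector,
    theta: float = 0.2,
    subtypes: Mapping[str, str] | None = None,
) -> list[CohortScore]:
    """Score every cohort sample against the +-1 signature.

    score = Pearson r between the sample's z-profile over the signature genes
    and the weight vector; call by the inclusive +-theta rule.  A sample with
    zero variance over the signature genes is unclassified and flagged.
    """
    if not 0.0 < theta < 1.0:
        raise ValidationError(f"theta must be in (0, 1), got {theta}")
    zc = z.copy()
    zc.index = zc.index.map(_canon)
    missing = [g for g in sig.genes if g not in zc.index]
    if missing:
        raise ValidationError(f"signature genes absent from z-matrix: {missing[:10]}")
    prof = zc.loc[sig.genes]
    w = sig.weights.to_numpy(dtype=float)
    wc = w - w.mean()
    scores = []
    for sample in prof.columns:
        x = prof[sample].to_numpy(dtype=float)
        xc = x - x.mean()
        denom = np.sqrt((xc @ xc) * (wc @ wc))
        if denom == 0:
            log.warning("sample %s has zero variance over signature genes; unclassified", sample)
            scores.append(CohortScore(sample, (subtypes or {}).get(sample), float("nan"),
                                      UNCLASSIFIED, theta, degenerate=True))
            continue
        r = float((xc @ wc) / denom)
        if r >= theta:
            call = SENSITIVE_LIKE
        elif r <= -theta:
            call = RESISTANT_LIKE
        else:
            call = UNCLASSIFIED
        scores.append(CohortScore(sample, (subtypes or {}).get(sample), r, call, theta))
    return scores


def classify_cohort_by_subtype(
    scores: list[CohortScore],
    clinical: pd.DataFrame,
    min_calls_per_class: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Contingency of signature calls by cohort subtype.

    ``clinical`` must be indexed by sample with a 'subtype' column.  Returns
    (counts frame indexed by subtype with call columns, flagged subtypes) —
    a subtype is flagged for survival exclusion when either called class has
    fewer than ``min_calls_per_class`` samples.
    """
    unlabeled = [s.sample for s in scores if s.sample not in clinical.index]
    if unlabeled:
        raise KeyError(f"samples without a subtype label: {unlabeled[:10]}")
    rows = pd.DataFrame(
        {
            "sample": [s.sample for s in scores],
            "call": [s.call for s in scores],
            "subtype": [clinical.loc[s.sample, "subtype"] for s in scores],
        }
    )
    counts = (
        rows.pivot_table(index="subtype", columns="call", aggfunc="size", fill_value=0)
        .reindex(columns=[SENSITIVE_LIKE, RESISTANT_LIKE, UNCLASSIFIED], fill_value=0)
    )
    counts.columns.name = None
    flagged = [
        str(st)
        for st in counts.index
        if counts.loc[st, SENSITIVE_LIKE] < min_calls_per_class
        or counts.loc[st, RESISTANT_LIKE] < min_calls_per_class
    ]
    if flagged:
        log.info("subtypes flagged for survival exclusion (few calls): %s", flagged)
    return counts, flagged
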