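"""Seeded generators for every input the pipeline consumes, with known ground truth.

Four generators emulate the study designs the pipeline is built for:

* ``simulate_viability_panel`` — an 18-cell-line end-point screen over a
  2-fold serial dilution ladder (11.2 nM .. 1433.6 nM by default), three
  technical replicates, additive Gaussian viability noise on true 4PL curves.
* ``simulate_combination_grid`` — a fixed-ratio 0.25-4 x EC50 combination
  design whose true Chou-Talalay combination index equals a chosen Loewe
  interaction factor at every effect level (doses on the additive isobole are
  scaled by the factor, making CI analytically known).
* ``simulate_cell_line_expression`` — a labelled cell-line log2 expression
  matrix with planted class-separating genes for signature derivation.
* ``simulate_expression_cohort`` — a TCGA-like cohort (default 442 samples,
  proneural/classical/mesenchymal) whose signature genes separate a latent
  sensitive-like/resistant-like class, with exponential survival linked to
  that class through a hazard ratio.

All randomness flows from a single integer seed per call; equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import DoseResponseSeries, four_pl
from .exceptions import ValidationError
from .synergy import CombinationGrid

#: the 2-fold serial-dilution ladder of the BET-inhibitor screen, nM
DEFAULT_DOSE_LADDER = tuple(11.2 * 2.0 ** k for k in range(8))
#: fixed-ratio combination design: 2-fold multipliers of the EC50-isobole point
DEFAULT_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)

SUBTYPES = ("proneural", "classical", "mesenchymal")
#: per-subtype probability that a cohort sample's latent class is sensitive-like,
#: emulating the strong subtype/signature association seen in GBM cohorts
DEFAULT_SENSITIVE_PROB = {"proneural": 0.85, "classical": 0.80, "mesenchymal": 0.05}


# ---------------------------------------------------------------- viability


@dataclass(frozen=True)
class PanelSpec:
    """Design of a synthetic end-point viability screen."""

    n_cell_lines: int = 18
    dose_ladder: tuple[float, ...] = DEFAULT_DOSE_LADDER
    n_replicates: int = 3
    true_params: tuple[tuple[float, float, float, float], ...] | None = None
    noise_sd: float = 0.05
    seed: int = 0
    drug: str = "JQ1"

    def __post_init__(self) -> None:
        ladder = np.asarray(self.dose_ladder, dtype=float)
        if np.any(ladder <= 0) or np.any(np.diff(ladder) <= 0):
            raise ValidationError("dose_ladder must be strictly increasing and positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.n_cell_lines < 1:
            raise ValidationError("n_cell_lines must be >= 1")
        if self.true_params is not None and len(self.true_params) != self.n_cell_lines:
            raise ValidationError("true_params must supply one (bottom, top, ec50, hill) per cell line")


def draw_panel_params(spec: PanelSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-line true 4PL parameters: realistic heterogeneous responders.

    bottom ~ U(0.0, 0.5), top ~ U(0.9, 1.1), ec50 log-uniform across the
    central ladder (one 2-fold step inside each end, i.e. 22.4-716.8 nM for
    the default ladder — serial-dilution screens centre the ladder on the
    expected EC50 range so both curve shoulders are observed), hill ~ U(1, 3).
    """
    n = spec.n_cell_lines
    lo, hi = spec.dose_ladder[0], spec.dose_ladder[-1]
    bottom = rng.uniform(0.0, 0.5, n)
    top = rng.uniform(0.9, 1.1, n)
    ec50 = 10.0 ** rng.uniform(np.log10(lo * 2.0), np.log10(hi / 2.0), n)
    hill = rng.uniform(1.0, 3.0, n)
    return np.column_stack([bottom, top, ec50, hill])


def simulate_viability_panel(spec: PanelSpec) -> tuple[list[DoseResponseSeries], pd.DataFrame]:
    """Simulate one dose-response series per cell line.

    Each replicate viability is 4PL(dose; true params) + N(0, noise_sd),
    clipped at 0 (fluorescence can exceed vehicle control, so no upper clip).
    Returns the series plus a ground-truth frame (cell_line, bottom, top,
    ec50, hill).
    """
    rng = np.random.default_rng(spec.seed)
    params = (
        np.asarray(spec.true_params, dtype=float)
        if spec.true_params is not None
        else draw_panel_params(spec, rng)
    )
    doses = np.asarray(spec.dose_ladder, dtype=float)
    series = []
    for i in range(spec.n_cell_lines):
        b, t, e, h = params[i]
        clean = four_pl(doses, b, t, e, h)
        reps = tuple(
            np.clip(clean[j] + rng.normal(0.0, spec.noise_sd, spec.n_replicates), 0.0, None)
            for j in range(len(doses))
        )
        series.append(
            DoseResponseSeries(f"L{i + 1:03d}", spec.drug, doses, reps, unit="nM")
        )
    truth = pd.DataFrame(params, columns=["bottom", "top", "ec50", "hill"])
    truth.insert(0, "cell_line", [s.cell_line for s in series])
    return series, truth


# ------------------------------------------------------------- combinations


def simulate_combination_grid(
    dm1: float,
    m1: float,
    dm2: float,
    m2: float,
    ratio: float | None = None,
    interaction: float = 1.0,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    drug1: str = "drug1",
    drug2: str = "drug2",
) -> CombinationGrid:
    """Fixed-ratio combination grid with analytically known combination index.

    Single agents follow their median-effect curves (Dm, m).  Combination
    rows sit at ``multipliers`` of the Loewe-additive 50%-effect isobole
    point (component ratio ``ratio``, default Dm1:Dm2), with component doses
    scaled by ``interaction``; the fraction affected then solves

        d1 / (I * Dx1(fa)) + d2 / (I * Dx2(fa)) = 1,

    so the true CI equals ``interaction`` at every effect level.  With
    m1 == m2 the mixture is an exact median-effect curve
    (fa/fu = (mu / I)^m); otherwise fa is solved numerically.

    Every row is observed ``n_replicates`` times (independent noise;
    combination screens are typically run in duplicate).
    """
    for name, v in (("dm1", dm1), ("m1", m1), ("dm2", dm2), ("m2", m2), ("interaction", interaction)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    mult = np.asarray(multipliers, dtype=float)
    if np.any(mult <= 0):
        raise ValidationError("multipliers must be positive")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if ratio is None:
        ratio = dm1 / dm2
    if ratio <= 0:
        raise ValidationError(f"ratio must be positive, got {ratio}")

    rng = np.random.default_rng(seed)
    rows = []
    # single agents at multiplier x their own Dm
    for mu in mult:
        x = mu ** m1
        rows.append((mu * dm1, 0.0, x / (1.0 + x)))
    for mu in mult:
        x = mu ** m2
        rows.append((0.0, mu * dm2, x / (1.0 + x)))
    # additive 50%-effect isobole point at the design ratio
    d2u = 1.0 / (ratio / dm1 + 1.0 / dm2)
    d1u = ratio * d2u
    for mu in mult:
        d1, d2 = mu * d1u, mu * d2u
        if m1 == m2:
            x = (mu / interaction) ** m1
        else:
            def excess(logx: float) -> float:
                x_ = np.exp(logx)
                return (
                    d1 / (interaction * dm1 * x_ ** (1.0 / m1))
                    + d2 / (interaction * dm2 * x_ ** (1.0 / m2))
                    - 1.0
                )
            x = np.exp(brentq(excess, -60.0, 60.0, xtol=1e-14))
        rows.append((d1, d2, x / (1.0 + x)))

    frame = pd.DataFrame(np.repeat(np.asarray(rows, dtype=float), n_replicates, axis=0),
                         columns=["d1", "d2", "fa"])
    if noise_sd > 0:
        frame["fa"] = np.clip(frame["fa"] + rng.normal(0.0, noise_sd, len(frame)), 0.0, 1.0)
    return CombinationGrid(drug1, drug2, float(ratio), frame)


# --------------------------------------------------------------- expression


def _signature_gene_names(n_up_sensitive: int, n_up_resistant: int) -> tuple[list[str], list[str]]:
    up_s = [f"SIG_S_{i + 1:03d}" for i in range(n_up_sensitive)]
    up_r = [f"SIG_R_{i + 1:03d}" for i in range(n_up_resistant)]
    return up_s, up_r


def simulate_cell_line_expression(
    n_sensitive: int = 5,
    n_resistant: int = 5,
    n_up_per_class: int = 50,
    n_background: int = 900,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Labelled cell-line log2 expression matrix with planted signature genes.

    ``n_up_per_class`` genes are shifted up by ``effect_size`` in each class
    on a N(0, 1) baseline with N(0, noise_sd) replicate noise.  Returns
    (genes x lines matrix, line -> 'sensitive'/'resistant' labels).
    """
    if n_sensitive < 2 or n_resistant < 2:
        raise ValidationError("need >= 2 cell lines per class")
    if n_up_per_class < 1:
        raise ValidationError("n_up_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    up_s, up_r = _signature_gene_names(n_up_per_class, n_up_per_class)
    bg = [f"BG_{i + 1:04d}" for i in range(n_background)]
    genes = up_s + up_r + bg
    lines = [f"S{i + 1:02d}" for i in range(n_sensitive)] + [f"R{i + 1:02d}" for i in range(n_resistant)]
    labels = {ln: ("sensitive" if ln.startswith("S") else "resistant") for ln in lines}

    base = rng.normal(0.0, 1.0, size=len(genes))
    mat = np.tile(base[:, None], (1, len(lines))) + rng.normal(0.0, noise_sd, (len(genes), len(lines)))
    sens_cols = np.arange(n_sensitive)
    res_cols = np.arange(n_sensitive, n_sensitive + n_resistant)
    mat[: len(up_s)][:, sens_cols] += effect_size
    mat[len(up_s): len(up_s) + len(up_r)][:, res_cols] += effect_size
    return pd.DataFrame(mat, index=genes, columns=lines), labels


def simulate_paired_expression(
    n_genes: int = 2000,
    n_pairs: int = 3,
    n_diff: int = 100,
    effect: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Matched control/treated log2 replicate pairs for paired testing.

    The first ``n_diff`` genes respond to treatment (half up by ``effect``,
    half down); the rest are null.  Returns (control, treated, true log2
    shift per gene), both frames genes x pairs.
    """
    if n_pairs < 2:
        raise ValidationError("n_pairs must be >= 2")
    if n_diff > n_genes:
        raise ValidationError("n_diff cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    pairs = [f"rep{j + 1}" for j in range(n_pairs)]
    shift = np.zeros(n_genes)
    shift[: n_diff // 2] = effect
    shift[n_diff // 2: n_diff] = -effect
    base = rng.normal(6.0, 2.0, size=n_genes)
    control = base[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_pairs))
    treated = base[:, None] + shift[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_pairs))
    idx = pd.Index(genes, name="gene")
    return (
        pd.DataFrame(control, index=idx, columns=pairs),
        pd.DataFrame(treated, index=idx, columns=pairs),
        pd.Series(shift, index=idx, name="true_shift"),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic expression cohort with class-linked survival."""

    n_samples: int = 442
    subtype_proportions: dict = field(
        default_factory=lambda: {"proneural": 139 / 442, "classical": 145 / 442, "mesenchymal": 158 / 442}
    )
    n_signature_genes: int = 79
    signature_split: tuple[int, int] | None = (41, 38)
    n_background_genes: int = 921
    effect_size: float = 2.0
    survival_scale_days: float = 400.0
    hazard_ratio: float = 2.0
    censor_rate: float = 0.2
    sensitive_prob: dict = field(default_factory=lambda: dict(DEFAULT_SENSITIVE_PROB))
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.subtype_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"subtype_proportions must sum to 1, got {tot}")
        if set(self.subtype_proportions) != set(SUBTYPES):
            raise ValidationError(f"subtype_proportions must cover {SUBTYPES}")
        if self.n_signature_genes < 1:
            raise ValidationError("n_signature_genes must be >= 1")
        if self.signature_split is not None and sum(self.signature_split) != self.n_signature_genes:
            raise ValidationError("signature_split must sum to n_signature_genes")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValidationError("censor_rate must lie in [0, 1]")
        if self.survival_scale_days <= 0 or self.hazard_ratio <= 0:
            raise ValidationError("survival parameters must be positive")


def simulate_expression_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a cohort expression matrix, clinical table and latent truth.

    Signature genes are shifted by +-effect_size/2 by the sample's latent
    sensitive-like/resistant-like class (sensitive-up genes up in
    sensitive-like samples and vice versa); background genes are N(0, 1).
    Survival is exponential with hazard (1/scale) * hazard_ratio for
    resistant-like samples; a ``censor_rate`` fraction of samples is censored
    uniformly before their event.  Returns (genes x samples log2 matrix,
    clinical frame indexed by sample with subtype/os_days/event, latent class
    Series).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    split = spec.signature_split or (
        int(np.ceil(spec.n_signature_genes / 2)),
        spec.n_signature_genes - int(np.ceil(spec.n_signature_genes / 2)),
    )
    up_s, up_r = _signature_gene_names(*split)
    bg = [f"BG_{i + 1:04d}" for i in range(spec.n_background_genes)]
    genes = up_s + up_r + bg

    # deterministic subtype block sizes (largest-remainder rounding)
    raw = {st: spec.subtype_proportions[st] * n for st in SUBTYPES}
    sizes = {st: int(np.floor(v)) for st, v in raw.items()}
    rem = n - sum(sizes.values())
    for st in sorted(SUBTYPES, key=lambda s: raw[s] - sizes[s], reverse=True)[:rem]:
        sizes[st] += 1
    subtypes = np.concatenate([[st] * sizes[st] for st in SUBTYPES])
    samples = [f"TCGA_{i + 1:04d}" for i in range(n)]

    p_sens = np.array([spec.sensitive_prob[st] for st in subtypes])
    latent = np.where(rng.random(n) < p_sens, "sensitive-like", "resistant-like")

    mat = rng.normal(0.0, 1.0, (len(genes), n))
    sens_mask = latent == "sensitive-like"
    half = spec.effect_size / 2.0
    mat[: len(up_s)][:, sens_mask] += half
    mat[: len(up_s)][:, ~sens_mask] -= half
    mat[len(up_s): len(up_s) + len(up_r)][:, sens_mask] -= half
    mat[len(up_s): len(up_s) + len(up_r)][:, ~sens_mask] += half

    rate = (1.0 / spec.survival_scale_days) * np.where(sens_mask, 1.0, spec.hazard_ratio)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.random(n) < spec.censor_rate
    obs_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    clinical = pd.DataFrame(
        {
            "subtype": subtypes,
            "os_days": np.round(obs_time, 1),
            "event": (~censored).astype(int),
        },
        index=pd.Index(samples, name="sample"),
    )
    expr = pd.DataFrame(mat, index=genes, columns=samples)
    return expr, clinical, pd.Series(latent, index=samples, name="latent_class")
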