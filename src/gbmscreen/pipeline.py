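"""End-to-end pipeline: configuration, stage orchestration and result writing.

``run_pipeline`` drives the whole analysis chain on seeded synthetic inputs:
viability screen -> 4PL fits / EC50 / AUC -> percentile stratification (two
metrics, compared) -> fixed-ratio combination grids -> combination indices
-> paired differential expression -> sensitive-vs-resistant signature ->
cohort z-scoring / correlation scoring / classification -> within-subtype
survival comparison.  Every stage writes a TSV and the run closes with a
JSON manifest echoing the configuration, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_response import compute_auc, fit_4pl, viability_at_dose
from .exceptions import ValidationError
from .expression import PairedExpressionSet, adjust_q, paired_t_test, top_n_genes
from .io import write_clinical_table, write_expression_matrix, write_viability_table
from .signature import (
    RESISTANT_LIKE,
    SENSITIVE_LIKE,
    classify_cohort_by_subtype,
    derive_signature,
    intersect_with_cohort,
    score_samples,
    zscore_cohort,
)
from .stratification import compare_stratifications, stratify
from .survival import km_estimate, logrank_test, survival_records_from_frame
from .synergy import combination_index
from .synthetic import (
    CohortSpec,
    PanelSpec,
    simulate_cell_line_expression,
    simulate_combination_grid,
    simulate_expression_cohort,
    simulate_paired_expression,
    simulate_viability_panel,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class PipelineConfig:
    """Parameters for every stage of the synthetic end-to-end run."""

    seed: int = 1
    out_dir: str = "results"
    log_level: str = "INFO"
    # screen + stratification
    panel: dict = dataclasses.field(default_factory=dict)
    common_dose_nm: float = 500.0
    # synergy designs: list of dicts accepted by simulate_combination_grid
    synergy_grids: list = dataclasses.field(
        default_factory=lambda: [
            {"name": "sensitive_pair", "dm1": 500.0, "m1": 1.6, "dm2": 400.0, "m2": 1.6, "interaction": 0.5},
            {"name": "additive_pair", "dm1": 500.0, "m1": 1.6, "dm2": 400.0, "m2": 1.6, "interaction": 1.0},
            {"name": "resistant_pair", "dm1": 500.0, "m1": 1.6, "dm2": 400.0, "m2": 1.6, "interaction": 1.5},
        ]
    )
    synergy_noise_sd: float = 0.02
    ci_fa_levels: tuple = (0.25, 0.5, 0.75)
    # paired differential expression
    de: dict = dataclasses.field(
        default_factory=lambda: {"n_genes": 2000, "n_pairs": 3, "n_diff": 100, "effect": 1.5, "noise_sd": 0.3}
    )
    de_top_n: int = 100
    # signature + cohort scoring
    signature_n_per_class: int = 50
    theta: float = 0.2
    cell_line_expr: dict = dataclasses.field(default_factory=dict)
    cohort: dict = dataclasses.field(default_factory=dict)
    min_calls_per_class: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValidationError(f"theta must lie in (0, 1), got {self.theta}")
        if self.common_dose_nm <= 0:
            raise ValidationError("common_dose_nm must be positive")
        if self.signature_n_per_class < 1 or self.de_top_n < 1:
            raise ValidationError("top-gene counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ci_fa_levels"] = list(self.ci_fa_levels)
        return d


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs and write results under out_dir.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    manifest: dict = {"package": "gbmscreen", "version": __version__, "config": config.to_dict(), "outputs": {}}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = path.name

    # --- screen: simulate, fit, summarise -------------------------------
    panel_spec = PanelSpec(seed=seed, **config.panel)
    series, truth = simulate_viability_panel(panel_spec)
    write_viability_table(series, out / "panel_viability.csv")
    record("panel_viability", out / "panel_viability.csv")

    rows = []
    for s in series:
        fit = fit_4pl(s, anchor_asymptotes=True)
        rows.append(
            dict(
                cell_line=s.cell_line,
                drug=s.drug,
                bottom=fit.bottom,
                top=fit.top,
                ec50_nm=fit.ec50,
                hill=fit.hill,
                rss=fit.rss,
                converged=fit.converged,
                auc=compute_auc(s),
                viability_at_common_dose=viability_at_dose(s, config.common_dose_nm),
            )
        )
    fits = pd.DataFrame(rows)
    _write(fits, out / "dose_response_fits.tsv")
    record("dose_response_fits", out / "dose_response_fits.tsv")

    # --- stratification by two metrics, compared ------------------------
    calls_v = stratify(
        dict(zip(fits["cell_line"], fits["viability_at_common_dose"])), metric="viability_at_common_ec50"
    )
    calls_a = stratify(dict(zip(fits["cell_line"], fits["auc"])), metric="auc")
    strat = pd.DataFrame(
        [
            dict(cell_line=c.cell_line, metric=c.metric, value=c.value, class_label=c.class_label,
                 cutoff_low=c.cutoff_low, cutoff_high=c.cutoff_high)
            for c in calls_v + calls_a
        ]
    )
    _write(strat, out / "stratification.tsv")
    record("stratification", out / "stratification.tsv")
    crosstab, shifts = compare_stratifications(calls_v, calls_a)
    _write(crosstab.rename_axis("viability_class"), out / "stratification_crosstab.tsv", index=True)
    record("stratification_crosstab", out / "stratification_crosstab.tsv")
    _write(pd.DataFrame(shifts, columns=["cell_line", "from_class", "to_class"]), out / "stratification_shifts.tsv")
    record("stratification_shifts", out / "stratification_shifts.tsv")

    # --- synergy --------------------------------------------------------
    syn_rows = []
    for i, g in enumerate(config.synergy_grids):
        g = dict(g)
        name = g.pop("name", f"grid{i + 1}")
        grid = simulate_combination_grid(noise_sd=config.synergy_noise_sd, seed=seed + 100 + i, **g)
        for fa in config.ci_fa_levels:
            res = combination_index(grid, fa_level=float(fa))
            syn_rows.append(
                dict(grid=name, true_interaction=g.get("interaction", 1.0), fa_level=res.fa_level,
                     ci=res.ci, call=res.call)
            )
    syn = pd.DataFrame(syn_rows)
    _write(syn, out / "combination_indices.tsv")
    record("combination_indices", out / "combination_indices.tsv")

    # --- paired differential expression ---------------------------------
    control, treated, de_truth = simulate_paired_expression(seed=seed + 200, **config.de)
    de = paired_t_test(PairedExpressionSet(control, treated))
    de["q_value"] = adjust_q(de["p_value"].to_numpy())
    _write(de.reset_index(), out / "differential_expression.tsv")
    record("differential_expression", out / "differential_expression.tsv")
    top_up, _ = top_n_genes(de, config.de_top_n, "up")
    top_down, _ = top_n_genes(de, config.de_top_n, "down")
    _write(
        pd.DataFrame({"gene": top_up + top_down, "direction": ["up"] * len(top_up) + ["down"] * len(top_down)}),
        out / "top_genes.tsv",
    )
    record("top_genes", out / "top_genes.tsv")

    # --- signature from labelled cell-line expression -------------------
    cl_expr, cl_labels = simulate_cell_line_expression(seed=seed + 300, **config.cell_line_expr)
    sig = derive_signature(cl_expr, cl_labels, n_per_class=config.signature_n_per_class)

    # --- cohort scoring and classification ------------------------------
    cohort_spec = CohortSpec(seed=seed + 400, **config.cohort)
    expr, clinical, latent = simulate_expression_cohort(cohort_spec)
    write_expression_matrix(expr, out / "cohort_expression.gct")
    record("cohort_expression", out / "cohort_expression.gct")
    write_clinical_table(clinical, out / "cohort_clinical.tsv")
    record("cohort_clinical", out / "cohort_clinical.tsv")

    sig79 = intersect_with_cohort(sig, expr.index)
    sig_frame = pd.DataFrame({"gene": sig79.genes, "weight": sig79.weights.to_numpy()})
    _write(sig_frame, out / "signature.tsv")
    record("signature", out / "signature.tsv")

    z = zscore_cohort(expr)
    scores = score_samples(z, sig79, theta=config.theta, subtypes=clinical["subtype"].to_dict())
    score_frame = pd.DataFrame(
        [dict(sample=s.sample, subtype=s.subtype, score=s.score, call=s.call) for s in scores]
    )
    score_frame["latent_class"] = latent.reindex(score_frame["sample"]).to_numpy()
    _write(score_frame, out / "cohort_scores.tsv")
    record("cohort_scores", out / "cohort_scores.tsv")

    counts, flagged = classify_cohort_by_subtype(scores, clinical, config.min_calls_per_class)
    _write(counts.rename_axis("subtype"), out / "subtype_counts.tsv", index=True)
    record("subtype_counts", out / "subtype_counts.tsv")

    # --- survival within non-flagged subtypes ---------------------------
    call_by_sample = {s.sample: s.call for s in scores if s.call in (SENSITIVE_LIKE, RESISTANT_LIKE)}
    surv_rows = []
    for st in counts.index:
        if st in flagged:
            continue
        sub = clinical[clinical["subtype"] == st]
        recs = survival_records_from_frame(sub, {k: v for k, v in call_by_sample.items() if k in sub.index})
        groups = {r.group for r in recs}
        if groups != {SENSITIVE_LIKE, RESISTANT_LIKE}:
            continue
        km_s = km_estimate([r for r in recs if r.group == SENSITIVE_LIKE])
        km_r = km_estimate([r for r in recs if r.group == RESISTANT_LIKE])
        chi2, p = logrank_test(recs)
        surv_rows.append(
            dict(subtype=st, n_sensitive_like=km_s.n, n_resistant_like=km_r.n,
                 median_sensitive_days=km_s.median_days, median_resistant_days=km_r.median_days,
                 logrank_chi2=chi2, logrank_p=p)
        )
    surv = pd.DataFrame(surv_rows)
    _write(surv, out / "survival_by_subtype.tsv")
    record("survival_by_subtype", out / "survival_by_subtype.tsv")
    manifest["excluded_subtypes"] = flagged

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
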