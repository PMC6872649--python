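# gbmscreen

Analysis pipeline for drug-sensitivity screens of patient-derived
glioblastoma (GBM) cell lines, and for projecting the resulting sensitivity
signatures onto expression cohorts.  It is written for groups who run
end-point viability screens (e.g. resazurin readouts of BET-inhibitor or
temozolomide panels), need reproducible dose–response, synergy and
stratification analysis, and want to ask whether the cell-line-derived
sensitivity phenotype is visible — and prognostic — in patient expression
data.

## What it computes

**Dose–response.** Viability fractions V over a serial-dilution ladder D are
fitted with the four-parameter logistic curve

    V(D) = bottom + (top − bottom) / (1 + (D/EC50)^h)

either freely or with the end-point screen convention (top pinned to mean
viability at the lowest dose, bottom at the highest).  Sensitivity summaries
are the EC50, the normalised AUC of viability over log10 dose (a mean
viability; lower = more sensitive), viability interpolated at a common dose,
and exponential-fit doubling times for growth curves.

**Stratification.** Cell lines are split at the panel's 25th/75th
percentiles of a sensitivity metric into sensitive (< P25), intermediate
(P25–P75, boundaries inclusive) and resistant (> P75) classes;
stratifications under different metrics are cross-tabulated with the
class-shifted lines enumerated.

**Synergy.** Fixed-ratio combination designs are analysed with the
Chou–Talalay median-effect model, fa/fu = (D/Dm)^m, fitted by OLS on the
linearisation log(fa/fu) = m·log D − m·log Dm.  The combination index at
effect level fa is the mutually-exclusive form

    CI = d1/Dx1(fa) + d2/Dx2(fa),   Dx = Dm · (fa/(1−fa))^(1/m)

with CI < 0.8 called synergism, 0.8–1.2 addition and > 1.2 antagonism;
CI at fa = 0.5 is the per-cell-line CI_EC50 summary.

**Expression.** Paired t-tests between matched control/treated replicates
with Benjamini–Hochberg (or Storey) q-values and documented top-n selection;
Pearson/Spearman correlation utilities and ΔΔCt qPCR fold changes.

**Signature scoring.** A ±1 signature (weight +1 for genes up in sensitive
lines, −1 for genes up in resistant lines, Welch-t derived) is correlated
against each cohort sample's gene-wise z-score profile; samples with Pearson
r ≥ 0.2 are sensitive-like, r ≤ −0.2 resistant-like, the rest unclassified.
Calls are tabulated by transcriptional subtype (proneural / classical /
mesenchymal) and compared within subtype by Kaplan–Meier median survival and
the log-rank test.

**Synthetic data.** Seeded generators emulate each study design — an
18-line, 2-fold serial-dilution screen (11.2–1433.6 nM, 3 replicates);
fixed-ratio 0.25–4 × EC50 combination grids whose true CI is analytically
known via a scaled Loewe-additivity construction; labelled cell-line
expression matrices with planted class-separating genes; and a 442-sample
three-subtype cohort with signature-linked exponential survival — so every
stage can be validated against ground truth.

## Worked example

```python
from gbmscreen import fit_4pl, compute_auc, viability_at_dose, stratify, ci_at_ec50
from gbmscreen.synthetic import PanelSpec, simulate_viability_panel, simulate_combination_grid

series, truth = simulate_viability_panel(PanelSpec(seed=7))
s = series[0]
fit = fit_4pl(s, anchor_asymptotes=False)
print(f"{s.cell_line}: EC50 = {fit.ec50:.1f} nM (true {truth.ec50[0]:.1f}), "
      f"hill = {fit.hill:.2f}, AUC = {compute_auc(s):.3f}")

v500 = {x.cell_line: viability_at_dose(x, 500.0) for x in series}
calls = stratify(v500, metric="viability_at_common_ec50")
counts = {c: sum(x.class_label == c for x in calls)
          for c in ("sensitive", "intermediate", "resistant")}
print("panel classes:", counts, f"cutoffs = ({calls[0].cutoff_low:.3f}, {calls[0].cutoff_high:.3f})")

grid = simulate_combination_grid(dm1=500, m1=1.6, dm2=400, m2=1.6,
                                 interaction=0.5, noise_sd=0.02, seed=7)
res = ci_at_ec50(grid)
print(f"CI_EC50 = {res.ci:.2f} -> {res.call}")
```

prints

```
L001: EC50 = 82.2 nM (true 80.6), hill = 2.22, AUC = 0.609
panel classes: {'sensitive': 5, 'intermediate': 8, 'resistant': 5} cutoffs = (0.228, 0.517)
CI_EC50 = 0.51 -> synergism
```

The first line fits one simulated cell line: the free 4PL fit recovers the
generating EC50 within a few nM at realistic noise, and the AUC of 0.609
means the line keeps ~61% mean viability across the ladder.  The
stratification splits the 18-line panel 5/8/5 at the realized quartile
cutoffs of viability at the 500 nM common dose.  The combination grid was
generated with a true Loewe interaction factor of 0.5, and the estimated
CI_EC50 of 0.51 correctly calls the pair synergistic.

The same stages are available from the shell (`gbmscreen --help`):
`simulate panel|grid|cohort`, `fit`, `stratify`, `synergy`, `de`,
`signature`, `score`, `survive` and `run-all`, which executes the entire
synthetic end-to-end pipeline and writes TSV results plus a JSON manifest
whose reruns are byte-identical for a fixed seed.

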