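# somanet

Discovery pipeline for plasma-proteomic signatures of early cardiovascular
death in systolic heart failure, built for aptamer-array (SOMAscan-style)
case/control cohorts and reusable on any sample × analyte RFU matrix.

Risk stratification of heart-failure patients with reduced ejection
fraction is still dominated by a handful of clinical markers (NYHA class,
LVEF, BNP, peak VO₂).  Aptamer arrays measure >1000 plasma proteins at
once, and this package implements the two complementary analysis arms such
a profiling study needs:

1. **Mechanism** — map differentially abundant proteins onto a molecular
   interaction graph, extract a seed-node network model, cluster it with
   the map equation, and rank nodes by betweenness centrality;
2. **Prediction** — select a small, stable protein signature by
   ridge-weighted adaptive-LASSO logistic regression with jackknife
   stability selection.

Because real cohorts of this kind (and the proprietary interaction
databases behind them) are rarely shareable, the package ships a
synthetic-data generator that emulates the full data structure — biased
RFU matrices with hybridization controls, planted group effects, clinical
covariates, planted-community knowledge graphs and pathway sets — so every
stage is testable against known ground truth.

## The methods

**Normalization.**  Per sample, the hybridization scale factor is
median_c(ref_c / x_c) over the spiked control sequences; every value of
the sample is multiplied by it.  Median normalization then scales each
dilution set (40% / 1% / 0.05% plasma) of each sample by
median_a(ref_a / x_a), where ref_a is the analyte's median across the
sample group.  Samples with any median factor outside [0.4, 2.5] fail QC.

**Screen.**  Per analyte, a two-sided Mann-Whitney-Wilcoxon test (exact
for tie-free groups ≤ 8, tie-corrected normal approximation otherwise)
with Benjamini-Hochberg adjustment; *modulated* means p_adj < 0.05 and
|log₂FC| > 0.25, with FC = mean(case)/mean(control) on the raw scale.

**Network model.**  Modulated analytes map (one-to-many) to seed nodes.
The model keeps: (1) non-seed nodes adjacent to ≥ 2 seeds ("connectors");
(2) seeds with ≥ 1 interaction with a seed or connector; (3) only
seed–seed and seed–connector edges.  Betweenness centrality
b(v) = Σ_{s≠v≠t} σ_st(v)/σ_st, normalized by (N−1)(N−2)/2, ranks nodes.
InfoMap (two-level map equation, igraph) partitions the model; clusters
with < 5 nodes or ≤ 1 internal edge per node are dropped; the rest are
annotated by one-sided hypergeometric (Fisher) tests against pathway sets
of 10–500 members, BH-adjusted within cluster.

**Signature.**  On log₂, z-scored modulated analytes: ridge logistic
regression (λ by leave-one-out deviance) gives adaptive weights
w_j = 1/|β̂_j^ridge|; the adaptive LASSO (penalty λ·w_j·|β_j|, λ again by
LOO) selects variables; n leave-one-out refits at frozen (λ, w) give
selection frequencies; the signature keeps frequency > 0.90.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort at the emulated study scale (84+84 samples, 1310 analytes, 25
planted signals at log₂FC = 1):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_normalize.py
...
python analysis/07_report.py
```

Selected output (seed 42):

```
bias recovery: 100.0% of samples within 5% of 1/bias (median error 0.55%)
25 of 1310 analytes modulated (p_adj < 0.05 and |log2FC| > 0.25)
planted-signal recall: 25/25; false positives: 0
network model: 92 nodes (25 seeds, 67 connectors), 179 edges
8 clusters found, 7 retained after size/edge-density filters
planted-community recovery on the full graph: ARI = 1.000
signature (frequency > 0.90): 22 analytes
planted-signal recall: 22/25; null analytes in signature: 0
```

The normalization undoes the planted per-sample biases almost exactly; the
screen recovers every planted signal with no false positives; InfoMap
recovers the planted graph communities perfectly; and the stability
selection keeps only true signals (22 of the 25 planted analytes clear the
0.90 frequency bar in this run).  The fold-change arithmetic reproduces
the published six-protein signature values from their reported group
means, e.g. MMP1 1499.6/766.4 → 1.96 and complement C3 104221/159620 →
0.65.

The same pipeline is exposed as a CLI (`somanet simulate`, `somanet
normalize`, `somanet diff`, `somanet run`) for file-based use on real
cohorts.

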