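# Methods

This note documents the models, defaults and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Synthetic cohort generator

The generator emulates an aptamer-array case/control study of systolic
heart failure: 84 cases (cardiovascular death within 3 years) matched with
84 controls, 1310 plasma analytes, 12 spiked hybridization-control
sequences per sample.

RFU values are log-normal.  For sample *s*, analyte *a*:

    log RFU[s,a] = mu_a + ln(2) * delta_a * case_s + ln(b_s) + eps,   eps ~ N(0, sigma_w^2)

- `mu_a` — analyte baseline, N(rfu_location, analyte_spread²) with defaults
  7.0 and 1.5 on the natural-log scale (baselines spanning roughly
  10²–10⁴ RFU, matching the dynamic range aptamer panels report).
- `delta_a` — planted log₂ group shift: `effect_log2fc` (default 1.0) for
  the `n_signal` signal analytes (default 25), zero otherwise.  The shift
  is additive on the log scale, so the true expected log₂ fold change of a
  signal analyte is exactly `effect_log2fc`.  All planted shifts share one
  sign; the screen and the selection are sign-symmetric, so nothing
  downstream depends on this simplification.
- `b_s` — per-sample multiplicative bias, log b ~ N(0, sample_bias_sd²),
  default 0.3 (biases mostly in [0.55, 1.8], i.e. inside the QC window).
- `sigma_w = rfu_scale` — within-analyte between-sample log-SD, default
  0.2 (~20% CV, in line with the modest per-analyte variability reported
  for aptamer assays).  This is the noise scale every downstream recovery
  property is calibrated against; it was fixed once, before the test
  suites were run, and is documented here rather than tuned.

Hybridization controls have fixed reference RFUs and measured values
`ref_c * b_s * exp(N(0, 0.05²))`: they carry the sample bias plus a small
technical noise but never a group effect, which is what makes the
hybridization scale factor an estimator of 1/b.  Analytes are split over
the three dilution sets at proportions 0.5 / 0.3 / 0.2.

Clinical covariates (age, sex, aetiology, diabetes, NYHA, BNP category,
LVEF, peak VO₂, creatinine, treatment flags) are drawn with case/control
shifts qualitatively matching a systolic-HF cohort — matched age/sex/
aetiology, higher NYHA/BNP/creatinine and markedly lower peak VO₂ in
cases.  They are sampled independently of the RFU matrix given case
status; any analyte–covariate correlation in the demo therefore flows
through the group label, not through a latent biology shared with the
proteome.

**What the generator does not emulate:** plate chemistry, dilution-
dependent saturation, assay cross-reactivity, heavy-tailed or multimodal
analyte distributions, analyte–analyte correlation beyond the shared
sample bias, missingness, and batch structure across plates.  Passing
recovery tests therefore demonstrates the correctness and calibration of
the procedure under its stated model, not robustness to every artefact of
real plasma proteomics.

The knowledge-graph generator is a planted-partition model (default 8
communities × 25 nodes, p_within = 0.3, p_between = 0.005) plus one
deterministic ring per community so every planted community is internally
connected (with p_between = 0 the graph then has exactly one component per
community).  Node types are assigned independently of community at
proportions 0.57 / 0.37 / 0.06 (protein-coding / miRNA / metabolite,
mirroring the composition of published molecular networks of this kind).
One pathway set per community of size ≥ 10 is emitted; analytes map to
uniformly chosen nodes, ~5% of them to two nodes (so the seed set can be
larger than the modulated set, as observed in real mappings).

## Normalization

Hybridization scaling precedes median normalization (the order the assay
protocol presents them).  Medians of even-length vectors are the mean of
the middle pair.  The acceptance window [0.4, 2.5] is treated as closed;
a sample is excluded when **any** of its per-dilution-set median factors
leaves the window, and the exclusion reason records the offending factor.
The "sample group" defining the per-analyte reference defaults to all
samples in the matrix (one plate run); a precomputed reference can be
supplied instead, and with a fixed reference the normalization is an
exact fixed point (re-applying changes nothing beyond 1e-9).  Note that
re-estimating references from already-normalized data perturbs factors by
O(1/sqrt(analytes per set)), so idempotence is only exact with respect to
a fixed reference.

The combined per-sample scale reported by `total_sample_scale` is the hyb
factor times the analyte-count-weighted geometric mean of the dilution-set
factors; under the generator's model its error is dominated by the median
over analytes of the within-sample noise, with SD ≈ 1.2533·sigma_w/sqrt(p_set)
per set — hence the 5%-recovery property holds comfortably at 400
analytes and sigma_w = 0.2.

## Differential screen

Rank tests are computed on normalized RFU (rank statistics are invariant
to monotone per-sample scaling, and fold changes must be read on the raw
measurement scale, so both arms are served by one matrix).  The exact
Wilcoxon null is used when both groups have ≤ 8 observations and the
pooled values are tie-free; otherwise the normal approximation with
midranks, tie-corrected variance and continuity correction.  Both
modulation thresholds are strict inequalities.  In the baseline table,
2×2 categorical comparisons use the Yates-corrected χ² unless an expected
cell count falls below 5, in which case Fisher's exact test is used;
continuous variables use the two-sided pooled-variance t-test, and a
variable constant in both groups is reported with p = 1 rather than
crashing.

## Network model

The interaction graph is treated as undirected and unweighted; duplicate
edges from multiple source databases collapse to one edge with
concatenated tags.  Connector–connector edges are deliberately excluded —
the inclusion criteria list only seed–seed and seed–connector edges — so
every non-seed node in a model has ≥ 2 seed neighbours (asserted on every
construction).  Betweenness normalization uses the unordered pair count
(N−1)(N−2)/2; graphs with fewer than 3 nodes get all-zero centralities,
and ranking ties break by node id for determinism.

## Clustering and annotation

InfoMap runs two-level, undirected, unweighted, 10 trials, seeded (the
igraph implementation; igraph draws from Python's `random`, which is
seeded and restored around the call).  Cluster ids are relabelled 1..K by
decreasing size for stable output.  The edge-density filter reads "one or
fewer edges per node" as internal_edge_count / cluster_size ≤ 1 ⇒
exclude; the alternative reading (minimum internal degree ≤ 1) would be
stricter and cannot be arbitrated without the original network, so the
direct reading was chosen.  The enrichment universe is the set of all
annotated nodes (union of the pathway sets); pathway sizes are measured
inside the universe, sets of fewer than 10 or more than 500 members are
dropped before testing, p-values are one-sided hypergeometric tails, and
BH adjustment is applied within each cluster (the source protocol names
no adjustment; per-cluster BH is the conservative default that keeps
"best pathway per cluster" well-defined — minimum adjusted p, ties by
name).

## Signature selection

Predictors are log₂-transformed and z-scored once on the full data;
jackknife refits reuse that standardization, the adaptive weights and the
tuned λ (the jackknife probes the stability of the *selection*, not of the
preprocessing).  The objective is

    (1/n) Σ_i log(1 + exp(−s_i·η_i)) + Σ_j λ1_j |β_j| + ½ Σ_j λ2_j β_j²

with unpenalized intercept; ridge uses λ2 = λ, the adaptive LASSO
λ1_j = λ·w_j with γ = 1 weights w_j = 1/|β̂_j^ridge| capped at 1e8 (ridge
coefficients are almost surely nonzero; the cap only guards numerics, and
a capped column can never enter the model).  λ is tuned by leave-one-out
cross-validated binomial deviance on a 100-point log-spaced grid
descending from λ_max — for the LASSO stage, the smallest λ that zeroes
every coefficient, max_j |x_jᵀ(y−ȳ)|/(n·w_j); for the ridge stage, 100×
the unweighted score scale — down to 1e-4·λ_max.  Ties in CV deviance
resolve to the larger λ.  The jackknife count equals the post-QC sample
size, not a hard-coded 168.

The solver is an IRLS coordinate-descent scheme (glmnet-style: outer
quadratic approximation, inner cyclic soft-threshold updates with
active-set cycling and full KKT-verification passes), compiled with
numba.  It is fully deterministic; soft thresholding yields exact zeros,
so "selected" is literally β_j ≠ 0.  Working weights are floored at 1e-6
and probabilities clipped at 1e-9.  Full-data and jackknife fits converge
to 1e-7 on the linear predictor; leave-one-out *tuning* fold fits use a
relaxed 1e-4 tolerance (they only contribute held-out deviances, which
are insensitive at that scale), each warm-started from the full-data
solution at the same λ.  A fold is fit by zeroing the working weight of
the left-out row rather than copying the design.  Tests cross-check the
solver against direct numerical minimization of the penalized deviance
(ridge) and against liblinear at matched penalties (LASSO).

Problem sizes used by the recovery suites — 84+84 samples with 200
analytes and 5 planted signals for stability selection, 400 analytes for
bias recovery, the full 1310-analyte default for the null-control runs —
are the study-scale conditions the package targets; the whole selection
procedure runs in roughly 10-15 seconds per cohort at that scale on one
CPU.

## Pipeline and reporting

The pipeline is a pure function of (inputs, config, seed): stage seeds
derive from the run seed, manifests record settings, per-stage filter
counts and SHA-256 hashes of every written file, and identical
configurations produce hash-identical outputs.  When the screen returns
no modulated analytes (e.g. α = 0, or a null cohort), downstream stages
are skipped with a message and an empty signature.  The heat map fixes
columns as control-then-case blocks (groups are a design variable, not
something to cluster) and orders rows by average-linkage hierarchical
clustering of row z-scores under Euclidean distance; correlations with
clinical markers are Pearson with pairwise-complete handling.

## Limitations

- The published headline results of the motivating study (203 modulated
  proteins, a 2881-node network, the specific six-protein signature)
  require its cohort and a proprietary interaction database; they are not
  reproducible here.  What this package validates is the *procedure*:
  worked-example arithmetic, exhaustive oracles for each algorithmic
  primitive, and planted-truth recovery under the generator's model.
- The LOO-CV loss is binomial deviance and predictors are log₂-
  transformed; the source protocol states neither, and both are
  conventions (documented, configurable in code).
- Survival modelling, covariate-adjusted differential models, risk-score
  evaluation (ROC), GO term ancestry and assay calibration are out of
  scope.
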