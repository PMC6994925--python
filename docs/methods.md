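# Methods

This note documents the statistical procedures, the synthetic-data model the
package validates itself against, the numerical choices, and the places
where the design was genuinely open.

## Study design assumed throughout

Five diet groups — SD (standard-diet control), HFD (high-fat-diet
prediabetes), HFD-STZ (HFD + streptozotocin type-2 diabetes), and the two
dietary-reversal arms HFD-DR and HFD-STZ-DR — sampled at 16 and 24 weeks.
Reversal groups exist only at 24 weeks, because reversal starts at the
16-week baseline. Disease contrasts are HFD vs SD and HFD-STZ vs SD;
reversal contrasts are HFD-DR vs HFD and HFD-STZ-DR vs HFD-STZ. Overlap
("common") analyses use the 24-week contrasts only, since that is the only
timepoint where both sides exist.

## Lipidomics preprocessing

Stages run raw → imputed → normalized → merged (→ zscored for display
summaries).

* **Imputation.** K-nearest-neighbour with lipids as neighbours: each
  missing entry is the mean of the k = 10 nearest lipids (Euclidean distance
  over mutually observed samples, rescaled by √(n/n_obs); implemented via
  scikit-learn's nan-Euclidean KNN imputer applied with features as rows).
  Only missing cells are touched. The impute-before-normalise order is the
  default and is configurable; nothing downstream depends on the order when
  standards are near-constant.
* **Internal-standard normalisation.** Each lipid is divided, per sample, by
  its class's internal standard (user-supplied class → standard map; the
  simulator emits one odd-chain 17:0-based standard per class, the
  convention for spiked standards). Standards are then dropped.
* **Ion-mode merging.** Species measured in both ionisation modes (same
  class + chains, `[+]`/`[-]` suffix stripped) are collapsed to their
  arithmetic mean; singleton-mode species pass through. The merged species
  count is the "lipids identified" figure all later funnels quote.
* **Summaries.** Class sums are per-sample totals over a class with
  mean ± SEM per (group, timepoint); fatty-acyl composition sums abundance ×
  chain multiplicity (so TG(16:0/16:0/18:1) contributes twice to C16:0) and
  is linear in abundance. Classes reported only as total compositions (e.g.
  cardiolipins as CL(72:8)) raise rather than guess chain splits. Z-scoring
  uses the sample SD (ddof = 1), by default within each timepoint's samples
  (one heat-map panel per timepoint).

## Differential analysis

* **Lipids (DALs).** Two-sided pooled-variance Student's *t*-test per lipid;
  log2 fold change of group means; Benjamini–Hochberg step-up
  (q_i = min_{j≥i} p_(j)·m/j) across lipids; significance at q < α = 0.05.
  Welch's form is available behind a flag.
* **Genes (DEGs).** A deliberately lightweight negative-binomial Wald test:
  median-of-ratios size factors (geometric mean over genes expressed in all
  samples), pooled method-of-moments dispersion α_g = (var−μ)/μ² floored at
  1e-8, and a Wald statistic on the log2 ratio of normalised group means
  with delta-method standard error √((1/μ_A + α)/n_A + (1/μ_B + α)/n_B)/ln 2.
  No shrinkage, no outlier filtering — the package's scope is the
  integration, not a full DE framework, and the downstream stages consume
  only the p-values and fold changes. All-zero genes are dropped and
  reported.
* **Overlaps.** "Common" features are significant in both the disease and
  the reversal contrast. Each is labelled by the contrast with the larger
  |log2FC|: `increased_with_disease` when the disease contrast dominates
  with positive fold change, `decreased_with_reversal` when the reversal
  contrast dominates with negative fold change, otherwise `discordant`.
  This partition rule is a design choice (several partitions are
  defensible); both raw fold changes are always retained in the output so
  alternatives can be recomputed, and the rule is recorded in the report.
* **Enrichment.** Upper-tail hypergeometric over-representation per GMT
  set, universe defaulting to all genes present after zero-row filtering,
  BH across sets, overlap gene ids reported.

## O2PLS

Both blocks are prepared by log2(x + 1), column centring and unit-variance
scaling. The transcript block is first reduced to genes with potential
differential signal (raw p < 0.05 in any contrast, union'd with a
top-variance floor) — integration candidates, not inferences.

The fit: (1) W, C ← K leading singular triplets of XᵀY, with each
component's sign fixed so the largest-|entry| of the W column is positive
(C flips with W); (2) T = XW, U = YC; (3) X-side orthogonal block: W_Yo ←
nx leading left singular vectors of (X − TWᵀ)ᵀT — algebraically orthogonal
to W, so WᵀW_Yo = 0 to machine precision — then T_Yo = X W_Yo, P_Yo by
least squares, deflation, and T recomputed; (4) the symmetric Y-side block;
(5) inner regressions B_T, B_U; (6) variance partition from squared
Frobenius norms, renormalised so each joint/orthogonal/noise triple sums to
exactly 1 (cross-terms are O(machine precision)). The orthogonal weights
come from a p×K matrix of rank ≤ K, so nx, ny ≤ K; the estimator rejects
larger requests. Rank-deficient inner Gram matrices (condition > 1e12)
raise with a suggestion to use fewer components.

Defaults K = 2, nx = 2, ny = 2 — six components in total, the overall model
size used for this class of data, with the joint/orthogonal split left
configurable because no single split is canonical. `select_components`
chooses (K, nx, ny) from a grid by 5-fold group-stratified cross-validated
two-way prediction error ‖X−X̂(Y)‖² + ‖Y−Ŷ(X)‖²; because such CV curves
keep creeping down slightly past the true dimensionality, the most
parsimonious candidate within 10% of the minimum error is returned (a
one-standard-error-style rule). Candidate features are ranked by the
Euclidean norm of their joint-loading rows; the conventional list sizes are
top 50 lipids and top 100 genes.

## Correlation network

Pearson correlations are computed across all samples of all groups and
timepoints jointly (configurable); edges are kept at |r| > 0.6, the
threshold operationalising "highly correlated" here — no additional
significance filter by default (one is available). Gene–gene pairs are
never edges: genes enter only through their lipid correlations. Genes are
pre-filtered in two stages: annotated (HMDB-style pair table) to at least
one network lipid, then intersected with the integration-retained
transcript set (a flag switches this to the top-candidate list; which set
is intended is ambiguous in the source procedure, so both are supported and
the funnel counts of both stages are reported). Constant features are
skipped with a log message.

Subnetworks default to greedy modularity communities ("highly
interconnected" implies community structure, not mere connectivity) on a
lexicographically ordered copy of the graph so ties break deterministically;
connected components are available for sensitivity analysis. Subnetworks
are numbered in decreasing size and flagged "large" at ≥ max(24,
⌈10% of nodes⌉). Reversal labelling: a node that is a common
disease/reversal feature in any model is `reversed_up_in_disease` /
`reversed_down_in_disease` by the sign of its disease log2FC; conflicting
signs across models resolve to the larger |log2FC| with the conflict
logged.

## Synthetic-study generator

The generator is first-class code: its defaults define the conditions under
which the pipeline's recovery properties are demonstrated.

* **Scale.** 578 lipid species over 17 classes (TG-dominant proportions,
  as in lipid-rich nerve tissue), 6000 genes, 10 samples/group.
* **Lipids.** log2 intensity = class baseline (N(8, 1.5²) per class) +
  species offset (N(0, 1)) + biological noise (σ = 0.5). Acyl chains are
  drawn from a pool whose high-weight core is the five dominant dietary
  fatty acids (16:0, 16:1, 18:0, 18:1, 18:2) — a wider tail of acyls exists
  only to make 578 ids unique. Cardiolipins are emitted as total
  compositions. 15% of species appear in both ion modes (σ = 0.05 log2
  disagreement); one 17:0-based standard per class; 5% of entries MCAR
  (the missingness mechanism and rate of real runs are not knowable from a
  processed table, so MCAR at a modest rate is an assumption, not an
  inference).
* **Disease effect.** +1 log2 on half the TG and DG species and on 150
  genes (always including a marker panel of lipid-handling genes: Dgat2,
  Lpl, Cd36, Lipf, Pla2g2e, ...), present in HFD/HFD-STZ at both
  timepoints, absent in DR groups — persistence with reversal.
* **Genes.** NB counts, var = μ + αμ² with α = 0.05, gene means 2^N(5, 2²),
  library sizes uniform ±30%.
* **Joint factor.** A per-sample score s (standardised disease indicator +
  N(0, 0.25²)) times sparse positive loadings (strength 3 × U(0.5, 1)) on
  40 TG species and 60 genes, applied multiplicatively (additive in log2).
  The strength-to-noise defaults put the factor in the
  strength ≫ noise regime in which the joint decomposition is expected to
  recover it (leading-score correlation ≥ 0.95); they are deliberately
  strong, and weaker regimes can be configured for power studies.
* **Determinism.** All stages draw from named substreams of the single
  seed; identical seeds give bitwise-identical outputs.

What the generator does **not** model: batch effects, within-animal
longitudinal correlation, intensity-dependent (MNAR) missingness,
ion-suppression artefacts, gene–gene co-expression structure beyond the
planted factor, and raw spectra/reads (the pipeline starts from matrices).
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure under clean conditions — not robustness
to those real-data pathologies.

## Validation problem sizes

The test suite exercises the full default scale where the property demands
it (planted-factor recovery: 20 seeds at 48 samples × 578 lipids × 2000
genes; null false-positive control: 50 seeds of the 80-sample lipidome) and
reduced scales (100–200 lipids, a few hundred genes, 5 samples/group)
elsewhere; each test states its size. The acceptance script runs the
default study end to end and reports recovery medians over 5 seeds.

## Known limitations

* The NB Wald test is anticonservative at very small n relative to
  shrinkage-based DE tools; it is a ranking device here.
* The variance partition attributes any joint-orthogonal cross-leakage
  (numerically tiny) to the noise share via renormalisation.
* Greedy modularity can merge weakly separated communities; the components
  mode and the igraph-style resolution of ties are the provided recourse.
* `fa_composition` requires resolved chains and refuses total-composition
  classes rather than imputing splits.
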