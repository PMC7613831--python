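# Methods

This note documents the models and procedures implemented in `renofao`, the
assumptions behind them, the tunable parameters with their defaults, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Differential expression (`renofao.de`)

Counts for gene *i* in sample *j* are modelled as negative binomial with mean
`s_j · q_i(group)` and dispersion `α_i`, i.e. `Var(K) = μ + α μ²`.

* **Size factors** are DESeq-style median-of-ratios: `s_j = median_i
  k_ij / (∏_j k_ij)^{1/n}` over genes with all-positive counts. At least one
  such gene is required.
* **Dispersion** is estimated per gene by the within-group method of moments
  on normalized counts, `α_g = (s² − μ̄)/μ̄²` per group, pooled across groups
  by a degrees-of-freedom-weighted average and floored at 1e-8. No shrinkage
  toward a mean–dispersion trend is performed; the contracts this engine is
  tested against (type-I error calibration, planted-effect recovery,
  threshold logic) do not require it.
* **Wald test**: `log2FC` is the log-ratio of normalized group means; the
  standard error comes from propagating `Var(K/s) = μ/s + αμ²` through the
  group means by the delta method. Because both the mean and the dispersion
  are noisy plug-in estimates at the study's replication (n = 6 per group),
  the two-sided p-value is referenced to a Student-t distribution with
  `df = n_samples − n_groups` — the residual df of the pooled dispersion
  estimator — rather than a standard normal. This is a deliberate
  small-sample calibration: with the normal reference the empirical null
  type-I error at 6+6 measures ≈ 0.068; with the t reference it measures
  ≈ 0.049 against the nominal 0.05. The two references coincide as
  replication grows.
* Genes observed in neither contrast group are retained (not pre-filtered)
  with `log2FC = 0`, `p = 1` and an `allzero` flag, keeping gene universes
  identical across contrasts. A gene observed in only one group gets a
  half-count pseudo-mean on the empty side so its fold change stays finite.
* **DEG thresholds**: |FC| ≥ 1.3 inclusive, adjusted p < 0.05 strict.
  Percentages are printed to one decimal, rounding half away from zero.
* **Corrected transcripts**: a disease DEG (SHAM vs healthy) counts as
  corrected when the treatment contrast (DMT vs SHAM) calls it in the
  opposite direction. "Any-direction" counting is exposed as a switch
  (`any_direction=True`) because the qualitative notion of correction could
  be read either way; opposite-direction is the default.
* **rlog-like transform**: `log2(k/s + 1)` — a monotone variance-stabilising
  approximation sufficient for the downstream uses (PCA, correlation). The
  exact regularised-log shrinkage of the reference implementation is
  internal to that package and not reproduced.

## Enrichment (`renofao.enrichment`)

Over-representation uses the hypergeometric upper tail `P(X ≥ k)` with
universe N, set size K and query size n, BH-adjusted across sets. The
universe is the set of genes tested for differential expression, not all
annotated genes — the standard guard against background inflation — and is
caller-controlled. The upstream-regulator score is the documented
simplification `z = (n_consistent − n_inconsistent)/√n` over a regulator's
known signed targets that are DEGs, with activation at z ≥ 2 and inhibition
at z ≤ −2; |z| ≤ √n by construction. Commercial knowledge-base scores weight
edges by curated confidence; this score preserves only the qualitative
contract (consistent direction ⇒ activation call).

## Cell-type localization (`renofao.deconv`)

The atlas is a features × 14 cell-type nonnegative abundance matrix in fixed
nephron order S1, S2, S3, DTL1–3, ATL, mTAL, cTAL, DCT, CNT, CCD, OMCD,
IMCD. Localization is by argmax abundance — deterministic, unlike
dendrogram-based visual assignment — with ties broken toward the first cell
type in ontology order and flagged. Raw abundances are used (per-feature
max-normalization would not change the argmax). Features absent from the
atlas are explicitly counted in an "absent" stratum, never dropped.
Stratification percentages use the denominators of the corresponding layer:
entity shares are percentages of DEGs responsive to ≥ 1 entity; compartment
shares are percentages of atlas-present genes in that branch.

## ¹H-NMR processing (`renofao.nmr`)

* **Baseline**: running-quantile estimator (window 1000 points, quantile
  0.1, step 500 points — all in axis points). Each window's quantile value
  is anchored at the median position of the points at or below it — the
  right placement under a linear drift (the low points sit at the window's
  start) and locally correct for curved baselines — and the anchor polyline
  is extended linearly past the outermost anchors so drifts are tracked
  without lag at the spectrum edges. The correction is idempotent up to the
  noise floor.
* **Peak detection**: Mexican-hat (Ricker) continuous wavelet transform with
  ridge-line linking (scipy's `find_peaks_cwt`), default scales 2–32 points,
  followed by an SNR gate: apex intensity over the spectrum's robust noise
  scale (1.4826 × MAD), default min_snr = 5.
* **Grouping**: single-linkage clustering of peak ppm positions cut at a
  tolerance of 0.005 ppm; consensus position = member median; when a sample
  contributes several peaks to one group only the most intense is retained
  and the rest re-pool and regroup among themselves.
* **Silhouette gate**: `s(i) = (b − a)/max(a, b)` computed exactly on the
  1-D ppm positions (own implementation; the group value is the mean over
  members, singletons score 1 by convention). Groups below 0.6 are
  dissolved and their members regrouped with a halved tolerance,
  iterating to 20 rounds; residual failures are dropped with a warning.
* **Peak filling**: missing (sample, group) entries take the maximum
  baseline-corrected intensity within ± tolerance of the consensus ppm,
  floored at zero.
* **PQN**: reference = column-wise median spectrum over all samples
  (QC-pool references can be passed explicitly); per-sample dilution factor
  = median quotient over columns with positive reference; rows divided by
  their factor. PQN factors are defined only up to the scale of the
  reference, so dilution-recovery checks compare factors to planted truth
  after geometric-mean rescaling.

## Classification (`renofao.rdcv`)

Two-class repeated double cross-validation random forest with recursive
variable elimination:

* Outer loop: nOuter = 5 stratified segments (both classes present in every
  segment); the whole segmentation repeats nRep = 100 times by default.
* Inner loop: leave-one-segment-out over the nOuter − 1 remaining segments
  drives elimination: at each step the current variables are scored by the
  inner forests' mean decrease in Gini, the inner validation
  misclassification rate is recorded, and the top ⌈varRatio · current⌉
  (varRatio = 0.85) are retained, down to a floor of 2 variables (the grid
  steps down by one where the ceiling stalls).
* The held-out outer segment is predicted at every variable count by the
  average of the inner-fold forests — no extra refit — and probabilities
  aggregate as the mean over repetitions; class calls use the 50% threshold.
* Flavors on the averaged inner error curve: `min` = count minimising the
  error; `max` = largest count with error ≤ min + 0.05 × (curve range) — a
  deterministic reading of "all relevant predictors without compromising
  performance"; `mid` = rounded geometric mean. Selected sets are prefixes
  of the overall mean-Gini ranking (ties broken by variable id).
* The forest is the standard definition the Gini importance presupposes:
  bootstrap-aggregated CART trees, Gini split criterion, √p candidate
  features per split, 500 trees by default. It is implemented as a thin
  bagging loop over `DecisionTreeClassifier` because the procedure fits tens
  of thousands of small forests; tests and the acceptance script use 20–30
  trees and nRep = 2–20, which at 24–40 samples reproduces the full-size
  behaviour while keeping runs to minutes.
* AUC is the rank (Mann–Whitney) statistic with half-credit for ties.
* A single label permutation has null AUC spread ≈ 0.1 at 20+20 samples, so
  the permutation-null check averages the AUC over several independent
  shuffles.

## Morphometrics (`renofao.measures`)

Weibel–Gomez `V = (β/d)·A^{3/2}` with β = 1.38 (spheres) and d = 1.01,
config-exposed since they come from the stereology literature. PFPD =
8000 nm / PFPF with the 8 µm GBM counting window fixed. Roundness
`4A/(πL²)` equals minor/major exactly for ellipses (property-tested).
Δ% = 100·(post − pre)/pre per animal. ΔΔCt: `RQ = 2^{−ΔΔCt}` against the
calibrator-group mean ΔCt, so the calibrator's geometric-mean RQ is exactly 1.

## Correlation networks (`renofao.correlation`)

Pearson correlations per animal across structure, transcript and metabolite
features (constant columns dropped with a warning; ≥ 3 animals required).
Edges kept at |r| ≥ 0.5 inclusive; isolated nodes flagged, not dropped.
Embedding by classical (Torgerson) MDS of d = 1 − r — signed, not 1 − |r|,
so anti-correlated features separate — and complete-linkage clustering of
the 2-D coordinates cut at k clusters (k is a config parameter, default 2
in the pipeline; the expected structure is one treatment-response cluster
and one disease-severity cluster).

## Synthetic data (`renofao.synthetic`)

The generator emulates the study's inputs with recorded ground truth:

* **Count studies**: NB counts, shared per-gene dispersion 0.05, log-uniform
  library-size factors in [0.7, 1.4], base means log-normal(4, 1), 2000
  genes, 6 animals per group. A 40-gene FAO module is induced (+1.5 log2)
  in DMT vs SHAM; a disjoint 40-gene fibrosis module is elevated (+1.5
  log2) in SHAM vs healthy and reverts to healthy levels under DMT, so it
  is "corrected" by construction.
* **Atlas**: 60% of the gene universe, every FAO gene planted with its
  maximum in S1–S3 (biassed toward S2/S3, the high-peroxisome segments),
  other features planted in a random non-PT type boosted to a strict max.
* **Drug networks**: five medications and three PPAR isotypes with exact
  configured sizes; fenofibrate (300 targets) and PPARα (250) both contain
  the whole FAO module and share an exactly configured overlap (200);
  non-focal entities share a background pool fraction (0.1) plus a token
  FAO overlap. Planted FAO edges carry expected sign +1.
* **NMR cohort**: 30 samples in four phenotypes (healthy 8, untreated-mild
  7, untreated-severe 7, DMT 8), Gaussian resonances (σ = 0.005 ppm;
  Lorentzian optional) on a 12 000-point 0.2–10 ppm axis. Planted families:
  clearance solutes ↓ with disease (×0.35 in severe), TCA intermediates ↑
  with disease (×2.6), nicotinamide metabolites ↑ after treatment (×2.2),
  glucose interference dominating the untreated-severe phenotype (×6), and
  80 unchanged background resonances. Per-sample log-uniform dilution in
  [0.5, 2], 2.5% per-peak biological CV, white noise SD 0.05, smooth
  polynomial-plus-hump baseline of amplitude 1.5. The background density
  and noise levels were chosen so that the PQN quotient median is dominated
  by unchanged resonances, the regime PQN assumes; they are realistic for
  IVDr-style 600 MHz urine spectra, which carry hundreds of resonances.
* **Morphometry**: truncated normals (resampled at ≤ 0) with group-shifted
  means for glomerular area, PFPF, GBM thickness, mitochondrial area and
  major axis. The synthetic treatment shift moves mitochondrial geometry to
  *higher* roundness after DMT. In the real pars convoluta the treatment
  effect on roundness is negative; the synthetic study plants the positive
  direction so that the planted treatment-responsive features (FAO
  transcripts, nicotinamide peaks, roundness) form one positively-correlated
  cluster under the signed d = 1 − r distance — the sign convention is
  arbitrary in synthetic data and only the co-clustering structure is the
  tested property.
* The pipeline's `simulate` stage additionally generates an animal-matched
  cohort: the ZDSD count-study animals reappear with the same ids in the
  NMR cohort (SHAM animals take the untreated-severe family effects) and
  the morphometry table, which is what makes per-animal cross-omic
  correlation possible downstream.

What the generator does **not** emulate: raw reads or FIDs, batch effects
across library chemistries, peak overlap/crowding beyond the planted
minimum separation (0.12 ppm), chemical-shift drift between samples,
metabolite annotation, and ortholog mapping (gene ids are shared across
models by construction). Passing tests therefore demonstrate that the
implementations recover planted structure under the stated model
assumptions — not that those assumptions hold for any particular real
dataset.

## Problem sizes used in tests and the acceptance script

Synthetic studies run at 2000 genes / 6 per group; the NMR cohort at 30
samples × 12 000 points; the classifier benchmarks at 40 samples × 200
variables with nRep = 20 (separable) and 6 × nRep = 2 (permutation null);
the end-to-end pipeline at nRep = 3 with 20-tree forests. These sizes were
chosen to exercise every code path at full statistical fidelity while
keeping a complete run to a few minutes on one CPU.

## Known limitations

* The DE engine is a transparent two-group NB Wald test: no multi-factor
  designs, independent filtering, outlier refitting or LFC shrinkage.
* ORA ignores gene-set topology and inter-set overlap.
* The regulator score treats all target edges equally.
* Silhouette gating operates on 1-D ppm positions only, as the grouping
  does; intensity information does not influence grouping quality.
* Classical MDS of 1 − r can place high-dimensional correlation structures
  imperfectly in 2-D; clustering quality degrades when more than ~2–3
  latent response programs coexist.
* `min`/`mid`/`max` flavor counts derive from the inner validation curve
  averaged over all repetitions, so per-repetition selected variable *sets*
  are not reported, only the aggregate ranking.
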