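# renofao

Multi-omic analysis of PPARα-driven renoprotection in rat models of diabetic
kidney disease (DKD), packaged as a tested, reusable pipeline.

The scientific question: when diabetic rats (ZDF and ZDSD models) receive a
bariatric-mimetic intervention — dietary restriction plus medical therapy
(DMT: fenofibrate, liraglutide, metformin, ramipril, rosuvastatin) — which
molecular program explains the improvement in kidney structure? The analysis
chain implemented here attributes it to fenofibrate/PPARα-driven
fatty-acid-oxidation (FAO) in the proximal tubule by combining:

1. **Differential expression** — negative-binomial Wald tests on gene-level
   counts (median-of-ratios size factors `s_j`, method-of-moments dispersion
   `α`, Wald `z = log2FC / SE` with `Var(K) = μ + αμ²`), Benjamini–Hochberg
   adjustment, DEG thresholds |FC| ≥ 1.3 and adjusted p < 0.05, cross-model
   *concordant* DEGs (same direction in both rat models), and
   *corrected-transcript* fractions (disease DEGs reversed by treatment).
2. **Enrichment** — hypergeometric over-representation analysis against
   gene-set collections, and a sign-consistency upstream-regulator score
   `z = (n_consistent − n_inconsistent)/√n` (activated at z ≥ 2).
3. **Cell-type localization** — each transcript assigned to its site of
   maximal abundance in a 14-cell-type tubular epithelial atlas
   (S1…IMCD); proximal tubule = argmax in {S1, S2, S3}; concordant DEGs
   stratified by medication/PPAR-isotype responsiveness with nested
   count/percentage summaries.
4. **¹H-NMR processing** — running-quantile baseline correction (window
   1000, quantile 0.1, step 500), Mexican-hat CWT peak detection,
   cross-sample peak grouping gated by silhouette ≥ 0.6, peak filling, and
   probabilistic quotient normalization (PQN) to remove urine dilution.
5. **Classification** — repeated double cross-validation random forests
   (nOuter = 5, nRep = 100, varRatio = 0.85) with recursive elimination of
   the least informative variables, ranked by mean decrease in Gini; AUC
   and misclassifications at the 50% probability threshold.
6. **Morphometrics** — Weibel–Gomez glomerular volume
   `V = (β/d)·A^{3/2}`, podocyte foot-process diameter `PFPD = 8000/PFPF`
   nm, mitochondrial roundness `4A/(πL²)`, Δ% change, and ΔΔCt relative
   quantification.
7. **Correlation networks** — per-animal Pearson correlations between
   structure, transcripts and metabolites; edges kept at |r| ≥ 0.5;
   classical MDS of d = 1 − r with complete-linkage clustering
   ("molecular morphometrics").

A synthetic-data module generates every input with recorded ground truth
(planted FAO and fibrosis gene modules, proximal-tubule atlas placement,
fenofibrate/PPARα-dominant target networks, urinary metabolite families with
dilution factors, morphometry tables with group shifts), so the whole chain
is testable without downloads.

## Worked example

```python
import renofao as rf

cfg = rf.SyntheticStudyConfig(seed=1)              # planted-truth study
counts, truth = rf.generate_count_study(cfg, "ZDF")
res = rf.wald_test(counts, ("DMT", "SHAM"))        # NB Wald per gene
degs = rf.call_degs(res)                           # |FC|>=1.3, padj<0.05
fao = set(cfg.fao_module.genes)
print(len(degs), len(degs.genes & fao) / len(fao))
```

prints

```
82 1.0
```

— 82 DEGs called for the treatment contrast, and all 40 planted FAO-module
genes recovered (recall 1.0). The extra calls are the 40 planted fibrosis
genes reverted by treatment plus a couple of borderline null genes.

The full synthetic analysis, end to end:

```bash
renofao run-all --seed 1 --outdir results/run1
```

writes counts, DE tables, DEG sets, enrichment, localization and
stratification summaries, the processed NMR intensity matrix with PQN
factors, classifier results, derived morphometry and the correlation
network under `results/run1/`, plus a `manifest.json` with parameters and
output checksums (identical seed ⇒ identical checksums). In
`stratification.json` the planted fenofibrate dominance is recovered — e.g.
50 of the concordant DEGs are responsive to at least one medication, 44
(88.0%) of them fenofibrate-responsive, 93.0% of the atlas-present
fenofibrate-responsive ones proximal-tubular — and in `network_nodes.tsv`
the planted FAO transcripts, nicotinamide peaks and mitochondrial roundness
fall in one cluster, separated from TCA intermediates and glomerular injury
indices.

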