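# tnftime

Temporal transcriptome analysis of a cytokine-stimulated endothelial cell
time course. The package implements, as a tested and reusable pipeline, the
statistical workflow used to dissect how TNF-α reshapes the endothelial
transcriptome over an extended time course (11 time points, 0.5–72 h, with
matched untreated controls and pooled biological replicates of each sex):

1. **Normalization & QC** — median-of-ratios size factors, TPM, classical
   MDS of inter-sample Euclidean distances.
2. **Time-series differential expression** — per-gene negative-binomial
   GLM likelihood-ratio test of the full model
   `~ treatment + time + treatment:time` against the reduced
   `~ treatment + time` (time as a factor; with T time levels the test has
   T−1 df), Benjamini–Hochberg correction, and per-time-point DEG calls
   (adjusted p < 0.05 and |log₂ FC| > 1 versus the time-matched control).
3. **Regulation classification** — a gene is *TNF-upregulated* when the
   control profile is temporally stable (CV of per-time-point mean TPM
   < 0.3), the treated profile varies (CV > 0.3), the peak log₂ FC of the
   treated profile against its own 0.5 h baseline exceeds 0.7, and it is a
   DEG at ≥ 2 sequential time points with a consistent direction;
   *downregulation* mirrors this with the peak |log₂ FC| > 0.7 measured
   against the time-matched control. Genes failing a criterion receive an
   explicit exclusion label (e.g. drifting-control confounders) with full
   per-criterion evidence.
4. **Coexpression modules** — signed-hybrid adjacency
   a₍ᵢⱼ₎ = max(cor₍ᵢⱼ₎, 0)^β with soft-threshold selection by scale-free
   fit, topological overlap matrix (TOM), average-linkage clustering of
   1 − TOM, dynamic tree cut (minimum module size 30), module eigengenes
   (first principal component), kME module membership and hub genes.
5. **Over-representation analysis** — upper-tail hypergeometric tests of a
   query list against user-supplied GMT gene sets with BH FDR.
6. **Sex comparisons** — per-time-point baseline (control-only) DE between
   sexes, and a concordance check that flags genes regulated in one sex
   (pool-level |log₂ FC| > 1) while quiet in every sample of the other
   (|log₂ FC| < 0.1375, i.e. fold change < 1.1).

Because the original count data are external, the package ships a
first-class synthetic generator (`tnftime.simulate`) that emulates the
study design — NB-distributed counts over 2 conditions × 11 time points ×
3 pools per sex — with planted temporal archetypes (early-transient,
early-sustained, delayed, sustained/resolving suppression, drift
confounders, nulls) and planted coexpression blocks, so every stage is
testable end-to-end against known truth.

## Worked example

```python
from tnftime import SyntheticConfig, generate_dataset, PipelineConfig, run_pipeline

sim = generate_dataset(SyntheticConfig(n_genes=400, seed=9, coexpression_blocks=(60, 40)))
sim.write("simdata")

cfg = PipelineConfig(
    counts="simdata/counts.tsv", samples="simdata/samples.tsv",
    genes="simdata/genes.tsv", outdir="out", seed=1,
)
report = run_pipeline(cfg)
print(report.stages["merged_classification"])
print(report.stages["network"])
```

which prints (400 genes, 132 samples, default thresholds):

```
{'neither': 280, 'both': 119, 'male_only': 1}
{'n_network_genes': 384, 'n_modules': 5, 'n_unassigned': 144}
```

Of the 400 simulated genes, 120 carry a planted treatment response; 119
are classified as regulated in both sexes and one reaches the thresholds
in males only — the generator plants no sex difference, so the split is
pure thresholding noise, mirroring how strict criteria can produce
apparent sex specificity. The five modules are cleanly interpretable:
the two planted coexpression blocks come back exactly (60 and 40 genes),
and the remaining three collect, respectively, the sustained/delayed
induced genes, the drift confounders and the downregulated genes —
coregulation discovered from expression alone. The `out/` directory
holds per-stage TSVs (DE tables, classification with evidence,
eigengenes, kME, hubs) plus `run_report.json`.

The same stages are available from the shell:

```bash
tnftime simulate --seed 9 --outdir simdata
tnftime de --counts simdata/counts.tsv --samples simdata/samples.tsv \
    --genes simdata/genes.tsv --sex F --out de_F.tsv
tnftime run-all --config pipeline.yaml
```

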