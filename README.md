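# epireg

Epigenetically regulated gene screening and molecular subtyping for tumor
expression cohorts.

Tumor transcriptomes are shaped by two major epigenetic layers: promoter
DNA methylation, which tends to silence the downstream gene, and miRNAs,
which repress their target mRNAs. `epireg` implements, as a tested and
reusable pipeline, the analysis chain that goes from those two layers to
clinically interpretable molecular subtypes:

1. **Regulatory screen.** For every annotated CpG–gene pair and every
   miRNA–gene pair supported by all three supplied target lists, compute
   the Pearson correlation r between regulator and gene expression across
   samples and apply the variance-stabilized Fisher criterion
   z = atanh(r), retaining pairs with z·√(n−3) < −1.96 (one-sided
   α ≈ 0.025 for negative coupling). Genes with at least one significant
   pair are the METcor (methylation-correlated) / MIRcor
   (miRNA-correlated) gene sets.
2. **Aberrance co-regulation.** Per gene, expression quartiles across
   samples define "aberrantly high/low" calls; per-sample frequencies of
   aberrant METcor and MIRcor genes quantify each tumor's epigenetic
   dysregulation burden, and their correlation tests whether the two
   layers co-regulate.
3. **Integrative subtyping.** The METcor and MIRcor expression blocks are
   jointly clustered via a Gaussian latent factor model
   X_b = W_b Z + E_b (k−1 factors for k clusters) fitted by a
   deterministic MAP-EM, with k-means on the posterior factor scores
   E[Z|X] and k selected by BIC.
4. **Validation.** Per-subtype marker signatures (one-vs-rest Welch t +
   BH, top-500 by log2FC); nearest template prediction (cosine distance
   to indicator templates, gene-resampling p-values) to classify external
   cohorts; a subclass-mapping concordance screen (signature enrichment
   with label-permutation nulls) across cohorts.
5. **Downstream characterization.** ssGSEA per-sample gene-set scores for
   arbitrary GMT collections (immune cell sets, pathway steps); survival
   separation by Kaplan–Meier/log-rank; and subtype-specific drug calls
   from dose–response AUC matrices: missingness filter (> 20% dropped),
   k-NN imputation, optional ridge-regression transfer from cell lines to
   tumors, and the rule that drug d belongs to subtype s iff
   log2(m_t/m_s) > 0.05 for every other subtype t, where m_s is the mean
   predicted AUC in s (lower AUC = more sensitive).

A first-class synthetic-cohort generator (`epireg.simulate`) plants known
regulatory pairs, subtypes, survival hazards and drug effects, so every
stage is testable without any external download.

## Worked example

`examples/` contains one short script per capability. The end-to-end run:

```bash
python examples/07_full_pipeline.py
```

prints (seed 1, 200 samples, 300 planted pairs per layer at r = −0.5):

```
"screen":   { "significant_cpg_pairs": 318, "metcor_genes": 317,
              "mircor_genes": 300, ... }
"aberrance": { "cor": 0.654, "p": 9.7e-26 }
"cluster":  { "chosen_k": 4, "sizes": {"1": 72, "2": 56, "3": 49, "4": 23} }
"ntp":      { "self_agreement": 1.0 }
"drugs":    { 12 drugs assigned, 3 per subtype }
"survival": { "p": 7.8e-05 }
```

Reading these numbers: the screen recovers the 300 planted
methylation-coupled genes (plus ~2.5% of null pairs, the expected
one-tailed false-positive rate at −1.96); the per-sample aberrance
burdens of the two layers are strongly co-regulated (r = 0.65); BIC picks
the planted four subtypes and the latent-space clustering reproduces them
exactly; nearest-template classification re-derives the cluster labels;
all 12 planted subtype-specific drugs are called with no false calls; and
the planted hazard differences separate the survival curves.

The same run is available as a shell command from a YAML config:

```bash
epireg run --config cfg.yaml        # plus per-stage subcommands:
epireg simulate / screen / aberrance / cluster / signatures / ntp /
       submap / ssgsea / drugscreen / survival
```

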