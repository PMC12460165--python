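# statscore

STAT-pathway activity scoring for cytokine-stimulation bulk RNA-seq.

Cytokines signal through characteristic STAT transcription factors
(IFNα → STAT1; IL-10, IL-21 → STAT3; IL-2, IL-7 → STAT5; IL-4 → STAT6), and
engineered chimeric cytokine receptors typically reproduce a native STAT
program at *attenuated* strength — partial agonism. `statscore` quantifies
how strongly each sample engages each STAT program, for anyone profiling
T cells (or other cells) stimulated through native or engineered cytokine
receptors:

1. **Differential expression.** For each reference cytokine condition
   versus the unstimulated control (a receptor with no intracellular
   domain, "no-ICD"), a negative-binomial Wald test with median-of-ratios
   normalization and Benjamini–Hochberg correction calls *driven* genes at
   FDR < 0.05, induced or repressed.
2. **Signature algebra.** Per-STAT driven sets: STAT1 = IFNα set,
   STAT6 = IL-4 set, STAT3 = IL-10 ∩ IL-21, STAT5 = IL-2 ∩ IL-7 (sign-
   concordant intersection). The STAT's *exclusive* set removes genes
   driven by any other STAT.
3. **STAT scores.** With TPM-normalized expression (log2(TPM+1) by
   default), the score of sample *s* for STAT *k* is the mean Pearson
   correlation over the exclusive gene set E_k to that STAT's reference
   samples R_k:

       score(s, k) = mean over r in R_k of corr( x_s[E_k], x_r[E_k] )

   A reference sample never correlates against itself (self-exclusion).
4. **Summaries.** Condition means, fold changes versus the control
   condition, and PCA of the per-sample score vectors.

Because real stimulation experiments are large, the package ships a
negative-binomial simulator of the whole design (control + six reference
cytokines + chimera conditions with a per-STAT activation factor
α ∈ [0, 1], n = 3 replicates, NB variance μ + φμ²) with full ground truth,
so every stage is testable against known programs.

## Worked example

The packaged configuration simulates 2,000 genes with four 150-gene STAT
programs (log2 effect 2, dispersion 0.1), the six reference cytokines, and
a chimera grid activating STAT3 at α = 0, 0.25, 0.5, 0.75, 1:

```sh
statscore run --config fixtures/default_run.yaml --out demo
statscore report demo
```

prints, among other tables,

```
## Condition mean STAT scores (control: no_ICD)
                    STAT1  STAT3  STAT5  STAT6
no_ICD             0.6815 0.7036 0.7128 0.7363
IFNa               0.9643 0.7216 0.7317 0.7538
IL10               0.6942 0.9665 0.7192 0.7371
...
chimera_STAT3_a025 0.6824 0.8181 0.7429 0.7496
chimera_STAT3_a050 0.6957 0.9183 0.7203 0.7643
chimera_STAT3_a075 0.6834 0.9505 0.7221 0.7400
chimera_STAT3_a100 0.7079 0.9599 0.7297 0.7519
```

Each reference condition peaks on its own STAT (IFNα scores 0.96 on STAT1
against ~0.72 elsewhere), and the chimera's STAT3 score climbs
monotonically with α — from the control baseline 0.70 toward the native
IL-10/IL-21 level 0.97 — the partial-agonism readout. Fold changes versus
the no-ICD control (the companion table) rise from 1.02 at α = 0 to 1.36
at α = 1, while the other three STATs stay at ~1.0.

The run directory also contains `scores.tsv` (per-sample scores with the
number of genes and reference samples used), `condition_scores.tsv`
(means, fold changes, differences), `pca.tsv` / `pca_variance.tsv`, the
per-STAT signature tables, all DE tables, and a `manifest.json` with
SHA-256 checksums — re-running the same config and seed reproduces every
file byte-for-byte.

Individual stages are available as `statscore simulate | de | signatures |
score`, and everything is importable from Python (`statscore.de.de_table`,
`statscore.scoring.score_all`, ...).

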