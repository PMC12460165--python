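# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical edge-case policies.

## Simulated experiment

The generator emulates a short cytokine-stimulation design on engineered
T cells: one control condition (receptor without an intracellular domain,
stimulated with the orthogonal ligand, so no signalling), six reference
cytokine conditions each activating one STAT program at full strength
(IFNα → STAT1; IL-10 and IL-21 → STAT3; IL-2 and IL-7 → STAT5;
IL-4 → STAT6), and any number of chimeric-receptor query conditions whose
activation vector α scales each program's effect — the partial-agonism
model. Three biological replicates per condition by default.

Counts are negative binomial with variance μ + φμ² around

    μ_gs = b_g · 2^( Σ_k s_gk · α_ck · Δ · 1[g ∈ P_k] ) · d_s

with baseline b_g, per-gene sign s_gk ∈ {+1, −1} (a configurable fraction
of each program is repressed, default 0.3), full-strength log2 effect Δ
(default 2), program membership P_k, and a per-sample depth factor d_s.

Defaults, with units and rationale:

| parameter | default | why |
|---|---|---|
| `n_genes` | 2,000 | desk-scale while leaving a large null gene background |
| `program_sizes` | 150 per STAT | comparable to cytokine-response signatures after FDR filtering |
| `effect_log2fc` Δ | 2 (log2 units) | a strong but realistic 4× response at full activation |
| `dispersion` φ | 0.1 | typical bulk RNA-seq biological coefficient of variation (~0.3) |
| `baseline_log2_mean_sd` | (6, 2) log2 units | log-normal baselines spanning the usual bulk dynamic range |
| `library_size_range` | [0.7, 1.3] (multiplicative) | moderate depth variation; exercises normalization |
| `frac_repressed` | 0.3 | cytokine programs contain both induced and repressed genes |
| `offtarget_fraction` | 0.1 | see below |
| `gene_length_range` | [500, 10,000] bases | typical mRNA lengths; exercises TPM length correction |
| `n_replicates` | 3 | standard design size for this kind of experiment |

Each reference cytokine of a *shared* STAT (IL-10, IL-21, IL-2, IL-7)
additionally activates a small private off-target program (10 % of its
STAT's program size). Without this, the two cytokines' DE sets would be
statistically identical and the intersection step would be vacuous; with
it, the intersection genuinely removes cytokine-private genes.

STAT programs are disjoint by default; `overlap_fraction` > 0 makes each
program (after the first, in sorted STAT order) share ⌈f · size⌉ genes
with the previous one, to exercise the exclusivity subtraction. A shared
gene keeps one global sign so the truth stays self-consistent.

What the simulator does **not** emulate: read-level noise and alignment
artifacts, isoform structure, gene–gene correlation within programs,
batch effects beyond depth factors, length-dependent counting bias, and
outlier samples. Passing tests therefore demonstrate correctness of the
*procedure* under a clean NB generative model, not robustness to every
failure mode of real libraries.

## Differential expression

A deliberately simple NB Wald test stands where a full DESeq2 analysis
would be used on real data — no dispersion shrinkage, no LFC shrinkage,
no independent filtering, no outlier replacement. The simplification is a
design choice: every component is specified exactly, testable against
ground truth, and adequate at the simulator's effect sizes.

* **Size factors** — median-of-ratios: per sample, the median over
  all-positive genes of count / geometric-mean(gene). If no gene is
  positive everywhere, total-count scaling normalized to geometric mean 1.
* **Dispersion** — per-gene method of moments pooled over the two groups,
  φ̂ = max(0, (within-group variance − mean)/mean²), floored at 10⁻⁴ to
  avoid zero-variance degeneracy. Noisy at n = 3, but unbiased enough for
  the recovery-level claims made here; on the 2,000-gene calibration null
  with n = 20/group the resulting test holds its nominal 0.05 level
  (measured type-I ≈ 0.05, KS ≈ 0.03; recomputed by the test suite).
* **Wald statistic** — log2 fold change of normalized group means with a
  pseudocount c = 0.5 (c = 0 available for exact-arithmetic fixtures);
  delta-method variance Var(ln μ̂) ≈ (1/n)(1/(μ̂+c) + φ̂) per group, summed,
  converted to log2; two-sided normal p-value. Genes at zero in both
  groups report log2fc = 0, p = 1.
* **Multiple testing** — Benjamini–Hochberg step-up (via statsmodels),
  order-preserving, capped at 1; significance is `padj < alpha`
  (default 0.05), both directions retained with their sign.

An optional minimum-total-count filter exists and is off by default.

## Signature construction

Driven sets: STAT1 and STAT6 inherit their single cytokine's DE set;
STAT3 and STAT5 intersect their two cytokines' sets by gene id. Two open
choices, both configurable, defaults documented here as this package's
own:

* **Sign concordance** (default `concordant`): a gene induced by one
  cytokine and repressed by the other cannot represent a shared STAT
  program, so discordant genes are dropped and logged; `id-only` keeps
  them with the first cytokine's sign.
* **Exclusivity against driven sets**: exclusive(k) = driven(k) minus the
  union of the *driven* (not exclusive) sets of all other STATs, the
  literal reading of "driven by the STAT of interest but not by others".

Exclusive sets smaller than `min_size` (default 10) are flagged and their
scores reported missing: a Pearson correlation over a handful of genes is
too unstable to interpret.

## Scoring

TPM: rate_gs = count_gs/(length_g/1000), column-normalized to 10⁶
(columns verified to 10⁻⁹ relative). Scores correlate **log2(TPM + 1)**
profiles by default. This is a deliberate design decision: with
log-normal baselines spanning several orders of magnitude, raw-TPM
Pearson correlations are dominated by the few most abundant genes — in
simulation all conditions scored ≈ 0.9 on every STAT and condition
differences drowned in replicate noise. On the log scale the shared
baseline contributes a bounded variance component and the activation
signal separates cleanly: reference conditions score ≈ 0.96 on their own
STAT versus ≈ 0.70 elsewhere, and attenuation grids order strictly.
`--raw-tpm` restores the untransformed behaviour.

Policies: a reference sample is excluded from its own panel
(self-correlation of 1 would inflate reference-condition scores);
zero-variance pairs are dropped with a log entry; a score is missing —
with a machine-readable reason code — when the exclusive set is below
`min_size` or no valid reference pair remains. Condition means are
unweighted over replicates. Fold change versus the control condition is
guarded: when the control mean is ≤ ε (default 0.05) the ratio is
suppressed and only the always-emitted difference column carries the
signal, since a correlation ratio explodes near zero.

PCA operates on the per-sample score vectors (all four STATs, unscaled —
scores already share the [−1, 1] scale; z-scoring is available), by SVD
of the column-centered matrix. Samples with any missing score are dropped
and logged. Component signs follow the convention that each loading
vector's largest-magnitude entry is positive, making outputs
deterministic.

## Pipeline

One directory per run; each stage writes plain TSV so stages can be
re-run individually. `manifest.json` records the config snapshot, package
version, seed and SHA-256 of every output; `verify_manifest` re-checksums
a run and names any mutated file. With a fixed seed the entire run is
byte-reproducible (timestamps live only in the manifest, never in data
files or the report body).

The packaged `fixtures/default_run.yaml` (YAML rather than a flat
key-value file — the nested condition list does not flatten naturally)
encodes the default design plus a STAT3 attenuation grid
α ∈ {0, 0.25, 0.5, 0.75, 1}; the simulator regenerates its counts
deterministically at run time, so no count matrix is stored.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full design at
2,000 genes × 36 samples, the calibration null at 2,000 genes ×
20 replicates/group, moment checks on 10⁵ NB draws, BH-oracle comparisons
on 100 vectors of length ≤ 1,000, and PCA oracles on 12 × 4 matrices —
sizes chosen so the whole validation completes in a few minutes on one
core while keeping Monte-Carlo bands tight enough to be meaningful.

## Known limitations

* The DE stage is not DESeq2; on real data its calls will differ in the
  tails (no shrinkage, no outlier handling). Signatures derived from it
  should be treated as FDR-controlled approximations.
* Method-of-moments dispersion at n = 3 is noisy; power claims at that
  depth rest on the simulator's moderate dispersion (φ = 0.1).
* Scores compare transcriptome *shape* over exclusive genes; they do not
  measure absolute pathway flux, and a query whose response is scaled but
  not reshaped can score near a full agonist.
* STAT4 (and other STATs without reference cytokines in the design) has
  no signature by construction.
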