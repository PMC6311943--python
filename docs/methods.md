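# Methods

This note documents the models, parameters and numerical choices behind
`cancerlnc`, and what its synthetic benchmark does and does not show.

## Problem and model

The task is binary classification of lncRNA genes: curated cancer-related
lncRNAs (positives) against lncRNAs presumed unrelated to cancer.
Because no negative labels exist, negatives are *constructed*: intergenic
lncRNAs with no cancer-trait GWAS SNP within a 10 kb window around the
gene body (`[body.start − 10 kb, body.end + 10 kb)`). This proxy is
conservative in one direction only — genes near cancer SNPs are removed —
so residual mislabeling of true cancer genes as negatives is expected;
the resampling design below makes single mislabeled negatives
low-leverage.

With ~150 positives against thousands of pool negatives, each model is
trained on a balanced problem: 100 negative sets (default) of 150 genes
drawn uniformly without replacement, independently per set, from the
pool. One classifier per set is trained on positives vs that set; the
ensemble prediction for an unseen gene is the mean positive-class
probability across members. The slight 158-vs-150-style class imbalance
in a training set is left as is (no reweighting).

## Features

All coordinates are 0-based half-open. "TSS ± w" is one merged window
`[tss − w, tss + w)` clipped at the chromosome origin and including
gene-body bases; this single-window reading is what makes the category
sizes self-consistent (5 GC + 3 conservation + 8 repeat + 1 miRNA + 1
micropeptide = 18 genomic; 9 tracks × 3 regions = 27 epigenetic).
Exon/intron features use the union of exons and the gaps between them;
intron features of intronless genes are *missing*, never zero. Signal
tracks have bedGraph semantics: uncovered bases are signal 0. GC content
excludes N bases from the denominator. The micropeptide feature is the
longest ATG-initiated, stop-terminated open reading frame over the three
forward frames of the spliced transcript; a user-supplied peptide-length
table takes precedence when available.

Expression is normalized by median-of-ratios size factors: per sample,
the median over all-positive-count genes of the ratio to the gene's
geometric mean. Note this estimator is defined only up to a global
constant — rescaling one sample rescales the reference geometric means —
so only *ratios* of size factors (and of normalized values) are
identified. Tests assert exactly those invariants.

Network features use the raw signed Spearman Rs with each driver gene
(no edge cutoff), plus counts over the thresholded network (degree,
cancer-protein neighbors) and the miRNA interaction table. The driver
list ships with 18 mutational-hotspot genes (BRAF … U2AF1) and is a
config item; feature counts always follow the manifest (83 by default),
never a hard-coded total.

## Co-expression network

For a pair with Spearman correlation Rs over n samples,
`F(Rs) = ½ ln((1+Rs)/(1−Rs))` and `Z = √((n−3)/1.06)·F(Rs)`; Z is
treated as standard normal (two-sided p). The 1.06 factor is the
classical variance correction for ranked data. p-values are adjusted by
Benjamini–Hochberg across **all** tested pairs; an edge needs signed
Rs ≥ 0.6 and adjusted p ≤ 0.01. Constant-expression genes cannot be
ranked and are excluded from testing (logged); they stay isolated nodes
with zero degree and missing driver correlations. |Rs| = 1 maps to
p = 0 with an infinite-Z flag.

## Classification and evaluation

Stratified ten-fold cross-validation per negative set; the AUC of one
set is computed on the pooled out-of-fold scores (not the mean of
per-fold AUCs), which is stabler with ~15 held-out genes per class per
fold. AUC uses the trapezoidal/Mann–Whitney convention (tied pairs count
½). SVM, logistic regression and k-NN see columns standardized with
statistics fitted on the training folds only; tree and naive-Bayes
models consume raw features. Hyperparameters are explicit and serialized
into every report; the shipped training default for forests is 500
trees. Evaluation runs in the test-suite and acceptance script use 100
trees — at 300 samples × 83 features the AUC difference is below the
cross-validation noise, and it keeps the 5-algorithm × 20-set × 10-fold
grids fast on one core.

Missing feature values are median-imputed per column on the assembled
population before model fitting (mask retained); `zero` and `none`
policies are available.

Feature importance is extremely-randomized-trees impurity importance,
averaged over the negative sets and normalized to sum to 1. Candidate
calling uses the full per-set ensemble by default (mean probability >
0.5); `single_best` retrains on the negative set with the highest CV
AUC, for the reading of "best model" as one model.

Candidate evaluation: two-sample Kolmogorov–Smirnov tests use the
asymptotic p-value with effective size n₁n₂/(n₁+n₂) (exact option for
small samples). Differential expression uses
log2((mean tumor + 1)/(mean normal + 1)) with the fraction exceeding
|log2FC| > 1. GO transfer tests each term annotating ≥ 1 network
neighbor by the one-sided hypergeometric (Fisher's exact) upper tail,
neighbors as sample, all GO-annotated protein-coding network nodes as
background; terms with p < 0.05 are assigned, with no multiple-testing
correction at this per-gene step (a BH option exists for set-level
analyses). Distance backgrounds sample uniform positions per chromosome,
10× the usable query count, seeded.

## Synthetic benchmark

The generator builds a complete toy study: 4 chromosomes sized to fit
150 positive, 600 pool, 200 held-out unknown lncRNAs (50/50 true class)
and 120 coding genes (gene bodies 2–6 kb, 2–4 exons, 5 kb flanks, 2 kb
gaps — flanks of adjacent genes never overlap), plus 60 miRNAs hosted
inside lncRNA bodies. Ten declared planted contrasts mirror the
top-ranked real-data feature differences: SINE and LINE body counts
(Poisson 4.5 vs 2.0 and 3.25 vs 1.5), H1hesc H3K4me1/H3K4me3 body
signal (+0.5 on a base of 1.0 with per-gene SD 0.3 and per-bin SD 0.4),
exon conservation (+0.08), intron GC (+0.02), Spearman correlation with
three driver genes (latent-factor coupling 0.45 for positives, 0.95 for
drivers and 30 cancer proteins, log-noise SD 0.3), and cancer-miRNA
interactions (Poisson 2.5 vs 1.0). Effect sizes were set so each
planted feature's Bayes-optimal univariate AUC,
`Φ(δ/(σ√2))` for the Gaussian effects (`truth_auc_bound`), is ≈ 0.8:
strong enough that the ensemble recovers them, weak enough that no
single feature or category saturates and the integrative gain is
visible. Additional class contrasts used only by the evaluation stage:
somatic mutation rate 5 vs 1 per gene, differential-expression
probability 0.4 vs 0.2, and a +0.2 log2 expression shift in four
tissues.

Expression profiles of *uncoupled* genes are constructed orthogonal to
the latent tissue factor and the tissue-shift pattern. Without this,
chance correlation between the latent factor and an arbitrary gene's
profile leaks class signal into every undeclared co-expression feature,
violating the design contract that the classes differ only in the
declared effects (a small variance-contraction artifact remains and is
visible as occasional non-planted driver correlations ranking high in
importance). SNPs that disqualify pool genes are placed within 1.5 kb
of the gene body, inside the gene's own 10 kb window but outside every
neighbor's, so the truth table exactly predicts the pool filter; window
boundary behavior is tested on hand-built fixtures instead. Setting
every contrast to its null value (`SimulationConfig.null()`) makes the
classes exchangeable by construction.

What passing on this benchmark does **not** show about real data: real
lncRNA features are heavy-tailed, batch-confounded and correlated in
ways a Poisson/Gaussian generator with one latent expression factor does
not produce; real negatives are contaminated; real effect sizes are
unknown and smaller. The benchmark validates the machinery (formulas,
filters, resampling, ranking, calling) and its calibration under known
truth — not the real-world AUC.

## Problem sizes used

Cross-validation grids in the tests and the acceptance script use 20
negative sets of 150 (not the shipped 100) and 100-tree forests; the
null and importance checks use 10 and 5 generator seeds respectively.
These are the package's standard desk-scale settings; all counts are
parameters.

## Known limitations

- The Fisher-z edge test assumes independent samples; tissues are not.
- GO transfer tests terms marginally (no ontology propagation, no
  per-gene multiplicity control), as the per-gene annotation rule
  intends; enrichment p-values are exploratory.
- The SNP proximity filter is assembly-blind: caller must supply
  annotations on one assembly.
- `probability=True` SVMs use Platt scaling fitted inside training folds
  (sklearn internal CV), which adds noise to SVM scores at this sample
  size.
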