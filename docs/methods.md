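# Methods

## The problem

Mature miRNAs occur as families of sequence isoforms (isomiRs) produced by
alternative Drosha/Dicer cleavage and nucleotide additions. Isoforms that
differ at the 5' end shift the seed region (nucleotides ~2–7) and can
therefore retarget the miRNA, so 5' isoforms are biologically distinct in a
way 3' isoforms largely are not. This package implements a multiclass
tumor-classification analysis over *5'isomiR profiles*: all isoforms sharing
the same strand-aware genomic 5'-end base are collapsed into one feature,
and a genetic-algorithm (GA) wrapper with a random-forest (RF) classifier
searches for small fixed-size sets of 5'isomiR loci that discriminate tumor
types.

## Profile construction

Input is one TCGA-dialect `isoform.quantification.txt` file per sample
(miRNA ID, `assembly:chrom:start-end:strand` coordinates, read count, RPM,
cross-mapped flag, region annotation) plus a manifest with TCGA barcodes and
tumor-type labels.

* **Sample filter.** Primary solid tumors carry the barcode sample-type
  infix `01`; LAML (acute myeloid leukemia) is blood-derived and carries
  `03` instead, and is the only class admitted with that infix. Samples on a
  problematic list and samples with unparseable barcodes are dropped, each
  with a recorded reason, so retained + dropped always partitions the
  manifest.
* **5' locus.** A record's locus is `(chromosome, strand, 5'-most base)`:
  the interval start on `+`, the interval end on `-` (transcription on the
  minus strand runs high→low coordinate). 3' ends never enter feature
  identity.
* **Aggregation.** Per sample, a locus's expression is the exact sum of RPM
  over all records mapping to it. Cross-mapped records are dropped by
  default (a read counted at several loci would otherwise be double-counted;
  configurable). Mixing genome assemblies in one run is a fatal error.
  Region annotations (mature/star/precursor) are kept — aggregation is
  purely positional.
* **Expression filter.** A locus is retained iff its summed RPM is ≥ 10 in
  *strictly more than* 10 samples. Both thresholds are parameters; the
  threshold is on RPM, not raw counts.
* **Transform.** Matrix entries are `log2(max(RPM, 1))` — values below 1 RPM
  are treated as noise and floored, so absent loci and sub-1-RPM loci are
  identically 0. Columns are sorted by `(chromosome string, strand,
  position)`; chromosome strings compare lexicographically (`chr10 < chr2`),
  which is arbitrary but reproducible, and column indices are the stable
  feature IDs used everywhere downstream.

## GA/RF wrapper selection

A candidate solution ("chromosome") is a set of exactly *k* feature IDs
(default k = 50, matching the full-scale protocol of 50-feature signatures,
population 50, 300 generations). Operators:

* **Fitness** — macro-averaged per-class sensitivity of an RF restricted to
  the set's columns, estimated *without the held-out test set*: by default
  from the forest's out-of-bag (OOB) predictions on the training rows
  (samples never out of bag are excluded from scoring), optionally by
  stratified internal cross-validation. Using the test set inside the search
  would leak; OOB keeps one forest fit per evaluation. Macro sensitivity
  (not accuracy) is the objective because per-type sensitivity is the
  quantity of interest under heavy class imbalance.
* **Selection** — tournament of size 3, ties to the first contestant drawn.
* **Crossover** (probability 0.9) — set-valued uniform crossover: shared
  genes go to both children, each non-shared gene to one child uniformly at
  random, then children are repaired to exact cardinality (draws from the
  parents' union first, then the global pool; oversized children drop random
  non-shared genes). A positional bit-string crossover would not preserve
  the fixed-cardinality semantics.
* **Mutation** — each member independently replaced with probability 0.02
  by a uniformly chosen non-member.
* **Elitism** — the single best individual is copied unchanged, which makes
  the best-fitness trace provably non-decreasing (a tested invariant).

The operator parameters (tournament 3, crossover 0.9, mutation 0.02,
elitism 1) are conventional wrapper-selection defaults; all are in
`GAConfig`. Fitness values are cached by feature set within a run, so
converged populations re-evaluate cheaply. Everything is deterministic
under `rng_seed`.

## Evaluation protocol

Each run draws a stratified split: per class, `floor(0.75·n)` training
samples, remainder test (a 1-sample class cannot be split and is a fatal
error). The GA runs on the training partition only; a final 500-tree forest
(or a linear-kernel SVM for comparison) is trained on the selected set and
scored on the test partition. Reported per run: the confusion matrix (rows
= actual), per-class sensitivity `confusion[c,c] / row-sum(c)`, their
unweighted (macro) mean, and the average one-vs-rest Matthews correlation
coefficient (binary MCC of each class's 2×2 collapse, 0 substituted when a
denominator term vanishes, unweighted mean across classes). Run-averaged
row-normalized confusion matrices give the misclassification heatmap.

## Selection-frequency importance

The experiment repeats the split→search→evaluate cycle `n_runs` times
(full-scale: 100) with child seeds derived by hashing
`(master_seed, purpose, index)`, so runs are independent but exactly
reproducible. A locus's importance is its selection frequency across the
runs' optimal sets. Under the null that each run's set is a uniform random
k-subset of the p candidates, a given locus is selected per run with
probability k/p and its frequency is Binomial(n_runs, k/p); the upper-tail
probability is Bonferroni-multiplied by p (capped at 1). At full scale
(100 runs, k = 50, p = 2231), appearing more than 11 times has adjusted
p ≈ 0.006 < 0.01 — computed at run time and checked against a
200,000-replicate Monte Carlo of per-run subset membership. The *flagging*
cutoff (frequency ≥ 11 at full scale) and the *significance* statement
("more than 11", i.e. ≥ 12) are deliberately distinct configuration values.

**Reduced sets.** The top-k most frequent loci (ties broken by feature-ID
order, recorded in the output) are re-evaluated over many fresh stratified
splits (full-scale: k = 9, 1000 splits), optionally after removing chosen
loci — the ablation used to ask whether non-canonical 5' isoforms carry
information beyond redundant copies of the canonical locus.

## Synthetic data

The generator emulates the statistical shape of the real corpus, not its
biology: no reads, no adapters, no real genome coordinates.

* **Expression model.** Log-normal RPM: `log2 RPM = μ_locus +
  σ·(√ρ·z_block + √(1−ρ)·ε) (+ effect)`, exponentiated. μ for expressed
  loci ~ N(6, 1) (~64 RPM); a `low_expression_fraction` (default 0.4) of
  loci get μ ~ N(1, 0.75) and sit below the 10-RPM filter regime. σ
  (`baseline_log2_sd`) defaults to 1. A log-normal with an additive shared
  factor was chosen over a negative-binomial read model because the
  pipeline consumes RPM, not raw counts, and the correlation structure is
  then analytic: ρ (`block_correlation`, default 0.5) is exactly the
  within-block correlation on the log scale. Blocks (default size 3) stand
  in for clustered miRNA families with shared expression.
* **Classes.** Default 6 classes with sizes (8, 10, 12, 14, 20, 40) —
  the order-of-magnitude imbalance of real tumor cohorts at desk scale.
  One class is labelled LAML so the `03`-infix barcode rule is exercised
  end to end.
* **Markers.** `n_informative` loci (default 12) get `effect_size` added to
  their log2 mean in exactly one class. Default assignment is round-robin
  (every class gets markers, each in a distinct block); the `grouped`
  mode instead gives each class a contiguous run of markers inside a single
  block, creating genuinely collinear redundant copies for the ablation
  experiment. Effect size defaults to 4 log2 units (16-fold) — the scale of
  strong tissue-specific miRNA markers — chosen so that a set containing
  all markers is close to Bayes-separable (OOB fitness ≥ 0.9); at 0 the
  design is an exact null.
* **File emission.** Each locus's RPM is split into 1–3 records sharing the
  5' end with differing 3' ends, written at 17 significant digits, so the
  parser→aggregator→filter→log2 path reproduces the generated matrix to
  ~1 ulp (tested at 1e-12). One decoy normal-tissue sample (infix `11`) is
  planted to exercise the sample filter.

What passing tests on this generator do *not* show: robustness to
count-level overdispersion, batch effects, unnormalized library sizes, or
misannotated coordinates — real-data properties outside the model.

## Problem sizes for the shipped experiments

The full-scale protocol (32 classes, ~9000 samples, 2231 candidate loci,
100 runs × 300 generations) is a cluster-scale computation. The shipped
experiment protocol (`experiments.py`), used by the analysis drivers, the
test suite and the acceptance script, runs the identical code path at desk
scale: the default synthetic cohort (104 samples × 300 loci, 12 planted),
15-feature chromosomes, population 20, 30 generations, 10 runs, 25-tree
fitness forests and 200-tree evaluation forests. At this size a full
repeated experiment takes a few minutes on one CPU. The chance baseline is
estimated by re-running the identical protocol on label-permuted data
(6 runs) and the planted-recovery claim is the z-score of the real mean
sensitivity against that permutation distribution, plus a one-sided
rank-sum test of planted vs noise selection frequencies.

## Numerical conventions and degenerate inputs

* MCC denominator of 0 → 0 (constant predictions score 0, not NaN).
* Macro sensitivity averages only classes present in the test set; a class
  predicted but absent from `class_order` counts as a plain error.
* `filter_loci` with nothing retained warns rather than fails.
* RPM sums are plain float accumulation in file order; round-trip equality
  is asserted at 1e-12, not bit-exactness.
* All RNG is `numpy.random.default_rng`; child seeds are 8-byte BLAKE2b
  hashes of `(master_seed, tag, index)` reduced mod 2^31, so sub-seeds are
  deterministic, distinct across purposes, and independent of execution
  order.

## Known limitations

* The binomial null treats runs as exchangeable and loci as equally likely
  under randomness; correlated loci violate independence across *loci*
  (the Bonferroni correction is conservative there), though the per-locus
  tail itself is exact under the stated null.
* OOB fitness is slightly pessimistic at small tree counts; the shipped
  25-tree setting trades a little bias for a ~4× speedup inside the GA.
* Selection frequency conflates a marker's strength with the redundancy of
  its block: collinear copies split frequency mass, which is precisely the
  effect the ablation experiment measures.
* The SVM comparison re-scores GA/RF-selected sets by default; re-running
  the whole search with SVM fitness is supported but expensive.
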