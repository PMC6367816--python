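# isomir-gaselect

Multiclass tumor classification from 5'isomiR expression profiles, using a
genetic-algorithm (GA) wrapper with random-forest (RF) fitness to select
small fixed-size biomarker panels, and selection-frequency statistics to
rank individual loci.

miRNA isoforms (isomiRs) that differ at the 5' end shift the seed region
and can target different transcripts than their canonical miRNA. This
package collapses all isoforms sharing a strand-aware genomic 5'-end base
into one *5'isomiR locus*, builds a samples × loci matrix of floored
log2(RPM) values from TCGA-dialect `isoform.quantification.txt` files, and
then answers three questions for a multi-class tumor cohort:

1. **Can a small panel classify tumor types?** A GA searches over sets of
   exactly *k* loci; fitness is the macro-averaged per-class sensitivity of
   a random forest estimated from out-of-bag predictions on the training
   partition (no test leakage). Each independent run uses a fresh
   stratified 75/25 split and reports test-set per-class sensitivity, macro
   sensitivity and mean one-vs-rest Matthews correlation coefficient (MCC).
2. **Which loci matter?** The selection frequency of each locus over all
   runs, against the null that each run's panel is a uniform random
   k-subset of the p candidates — frequency ~ Binomial(n_runs, k/p), upper
   tail, Bonferroni-corrected by p.
3. **Do non-canonical 5' isoforms add information?** Reduced panels of the
   top-k most frequent loci are re-evaluated over many fresh splits, with
   ablations that remove distinct-signal loci versus redundant collinear
   copies.

A fully-tested synthetic-data generator (unbalanced classes, collinear
locus blocks, planted class markers, a low-expression tail, and emission of
genuine per-sample quantification files) provides ground truth for every
claim, so the whole pipeline is exercisable end to end without any external
data. See `docs/methods.md` for the model and all conventions.

## Worked example

The numbered drivers under `analysis/` run the desk-scale study in order
(each takes `--seed`, default 2026) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py        # synthetic cohort + ground truth
python analysis/02_build_matrix_from_files.py # file-level pipeline round trip
python analysis/03_run_ga_experiment.py      # 10 GA/RF runs (~2.5 min)
python analysis/04_selection_frequency.py    # frequency table + binomial null
python analysis/05_reduced_set_ablation.py   # reduced panels + ablation
```

Output of steps 03–05 at the default seed:

```
10 runs on 104 samples x 300 loci
mean test sensitivity 82.9%  mean MCC 0.829
per-run sensitivities: 0.911 0.861 0.889 0.514 0.917 0.661 0.889 0.792 0.967 0.889

10 runs x 15-locus sets over 300 candidates (frequency mass 150)
flagged at frequency >= 3: 10 loci, 9 of them planted
planted mean frequency 4.17 vs noise 0.347; rank-sum p = 5.46e-11

all 9 markers                                  95.0% +/- 5.3 (9 features, 60 splits)
minus 3 redundant copies (6 loci)              94.4% +/- 5.5 (6 features, 60 splits)
minus 3 distinct-signal markers (6 loci)       62.0% +/- 4.3 (6 features, 60 splits)
redundant-copy sets beat distinct-signal-ablated sets by 32.4 points of sensitivity
```

Reading this: panels of 15 loci found by the GA classify the six synthetic
tumor classes at 83% mean macro sensitivity (chance is ~17%); the 12
planted markers dominate the selection-frequency ranking (rank-sum
p ≈ 5e-11 against the 288 noise loci); and removing a class's only marker
costs ~33 points of sensitivity while removing redundant collinear copies
costs ~0.6 — distinct 5' loci carry non-redundant information.

The library surface mirrors the pipeline: `io` (quantification parsing,
barcode filtering, 5'-locus derivation), `matrix` (aggregation, expression
filter, log2 matrix), `ga` (operators and search), `evaluate` (splits,
classifiers, metrics), `frequency` (repeated runs, binomial null, reduced
sets), `simulate` (generator) and `experiments` (the desk-scale protocols).

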