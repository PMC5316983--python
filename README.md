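# adaptseq

Analysis and simulation toolkit for **poly-ligand (ssODN/aptamer) profiling
of plasma samples** — the SELEX-style approach in which a large library of
single-stranded oligodeoxynucleotides (each a 35-nt random region between
fixed primer-binding sites) is first *enriched* against pooled plasma from a
disease and a control cohort, and the trained library is then *profiled*
against individual patients: recovered ssODNs are sequenced, counted per
variable-region sequence, and the resulting count profiles are used to
classify patients.

The package is aimed at computational biologists who want to analyse such
amplicon count data — or to study the statistical behaviour of the whole
design under controlled, simulated conditions.

## What it implements

* **Read processing** (`adaptseq.reads`, `adaptseq.design`) — the staggered
  amplicon layout (`[pad 0–3 nt][35-nt variable][20-nt constant anchor][i7]`),
  valid-read detection by matching the constant anchor within a mismatch
  tolerance, demultiplexing, and library QC (unique sequences at count
  cutoffs, mean copies per sequence, fraction of bases ≥ Q30 against an
  85 % gate).
* **Normalization and concordance** (`adaptseq.counts`) — for count
  `c_{ij}` of sequence *i* in sample *j* with sample total `T_j`,

  `norm_{ij} = c_{ij} / T_j × mean_k(T_k)`

  so every column sums to the global mean of totals; fold changes with a
  pseudocount; Pearson *r*/*r²* between technical replicates and between
  patients.
* **Differential statistics** (`adaptseq.stats`) — per-feature one-way
  ANOVA F-tests and the *count-of-significant* label-permutation test
  (`#{p < 0.05}` on real vs permuted labels, plus-one p-value
  `(1 + #{null ≥ obs})/(1 + n_perm)`); the feature-selection battery
  (Welch t, Wilcoxon rank-sum, Kolmogorov–Smirnov, fold change > 1.2,
  combined by union); the ≥ 5-fold high/low-recovery screen.
* **Classification** (`adaptseq.classify`) — random forest (1000 trees,
  `mtry = ⌊√p⌋`) scored by the AUC of out-of-bag probabilities, with a
  label-permutation AUC test that re-runs feature selection inside every
  permutation (honest null), and pairwise cohort comparisons.
* **Synthetic data** (`adaptseq.simulate`) — a generative model of the
  whole experiment: naive library → iterated positive/counter/positive
  selection with PCR (Poisson-thinning capture with weight
  `background + affinity × target abundance`) → equimolar sub-library →
  per-patient multinomial profiling counts with technical-replicate
  overdispersion → FASTQ emission with sequencing error. Ground truth
  (planted binders, affinities) is exposed for testing.
* **Pipeline + CLI** (`adaptseq.pipeline`, `adaptseq` command) —
  `simulate / parse / normalize / concordance / stats / classify / report /
  run-all` over a single seeded YAML/JSON config.

## Worked example

```bash
cat > demo.yaml <<'EOF'
seed: 7
outdir: demo_run
simulate:
  n_sequences: 200
  n_targets: 80
  patients: {cancer: 8, biopsy_negative: 4, healthy: 4}
  n_replicates: 2
  depth: 5000
  effect_fold: 2.5
stats: {n_perm: 200}
classify: {n_trees: 200, n_perm: 49}
EOF
adaptseq run-all -c demo.yaml
```

which prints (abridged):

```
INFO adaptseq: simulate: 32 samples, 160000 reads
INFO adaptseq: parse: 160000 reads, 160000 valid, 0 invalid, 0 unassigned
INFO adaptseq: concordance:
   label  count      mean       min       max
0  inter     50  0.873996  0.732445  0.959742
1  intra     16  0.991029  0.985964  0.996248
INFO adaptseq: stats: observed=36 p=0.00995
INFO adaptseq: classify: OOB AUC 1.000 (perm p 0.02)
```

Reading the output: 16 patients were simulated with 20 % of the molecular
targets elevated 2.5-fold in the cancer cohort.  All 160,000 error-free
reads demultiplex as valid.  Technical replicates of the same patient
correlate at *r* ≈ 0.99 while different patients correlate at ~0.87 — the
profile carries patient-specific biology above the technical noise floor.
36 of 200 sequences are ANOVA-significant across the three cohorts, more
than in 198 of 200 label permutations (p ≈ 0.01), and the union-screen +
random-forest classifier separates cancer from control patients perfectly
out-of-bag (AUC 1.0, permutation p = 0.02 — the floor at 49 permutations is
0.02).  Artifacts (counts, normalized table, QC, JSON results) are written
under `demo_run/`.

## Layout

```
src/adaptseq/    design, reads, counts, simulate, stats, classify, pipeline, cli
tests/           pytest suite (unit, property, end-to-end acceptance checks)
scripts/         acceptance.py
docs/methods.md  model assumptions, parameter choices, limitations
```
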