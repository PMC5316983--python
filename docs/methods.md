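# Methods

This note documents the models, defaults and numerical choices behind
`adaptseq`, and what the synthetic-data generator does and does not
emulate.

## The experimental design being modelled

A poly-ligand profiling experiment has two phases.  In *training*, a
high-diversity ssODN library (35-nt random region flanked by constant
primer-binding sites) is incubated with pooled plasma from two cohorts in
parallel arms; vesicle-associated molecules and their bound ssODNs are
recovered, each arm is counter-selected against the opposing cohort's
plasma (bound fraction discarded), positively selected again, and
PCR-amplified.  Iterating this collapses library diversity by orders of
magnitude while enriching sequences that bind cohort-associated targets;
the two arm products are mixed into a single profiling library.  In
*profiling*, that library (or an equimolar resynthesized subset of its
top-ranked members) is incubated with individual patient plasma, recovered
ssODNs are sequenced, and per-sequence counts become a patient profile
used for group statistics and classification.

## Read model and parsing

A read is laid out as `[stagger pad, 0–3 nt][variable, 35 nt][constant
anchor, 20 nt][i7 index][adapter]`.  The pad exists so the constant region
does not reach the sequencer in the same cycle for every cluster; its
exact base content is not informative, so the parser identifies a read by
searching the 20-nt anchor at each offset `pad + 35` (pads tried in
increasing order, first hit wins) and treats the preceding 35 bases as the
feature.  Coordinates are 0-based half-open throughout.

Defaults: `anchor_mismatch_tol = 1` and `index_mismatch_tol = 1` — one
sequencing error is tolerated while index sets are required to stay
unambiguous at that radius (generated index sets use pairwise Hamming
distance ≥ 3).  A read whose index matches no sample, or more than one
within tolerance, is counted as unassigned; a read without the anchor is
counted as invalid; neither is silently dropped, and
`valid + invalid + unassigned = total` always holds.  The run-level Q30
gate is 85 % of bases at Phred ≥ 30, reported per sample and per run.

## Normalization

`norm[i,j] = counts[i,j] / total[j] × global_mean`, with `global_mean`
taken as the **arithmetic mean of per-sample totals within the analysis
batch**.  The alternative reading (grand mean of all normalized counts)
differs only by a constant factor and would not change any correlation,
test statistic or classifier built on these values; the chosen form makes
every normalized column sum to a common depth, which is the property the
tests assert (relative tolerance 1e-9; in practice the identity holds to
machine precision).  Samples with zero totals are an error, named
explicitly.  The default fold-change pseudocount is 1.0 normalized count —
enough to guard sparse features without distorting typical depths of
10³–10⁶.

Concordance is Pearson correlation of untransformed normalized counts
(the scatter being summarized is linear), with r undefined — flagged, not
fabricated — for constant vectors.

## Permutation statistics

Per-feature tests run on untransformed normalized counts.  The
count-of-significant test computes one-way ANOVA F p-values per feature
(zero-variance features get p = 1; perfectly separated features with zero
within-group variance get p = 0), counts `#{p < 0.05}` strictly, and
compares against the same count under uniformly drawn label permutations.
The null is evaluated in vectorized blocks (one-hot label matrices, a
single matrix product per block); a unit test verifies the block
computation equals a literal per-permutation ANOVA loop on the same
permutation stream.  P-values use the plus-one rule
`(1 + #{null ≥ observed})/(1 + n_perm)`, which is unbiased and can never
be zero (minimum `1/(n_perm+1)`).

The two-group battery uses Welch's t (the variant is a package choice;
unequal variances are the safe default for count profiles), the
tie-corrected Wilcoxon rank-sum (exact for combined n ≤ 20 without ties),
and the two-sample Kolmogorov–Smirnov test.  KS is computed by a
vectorized implementation whose statistic and asymptotic p-value match
scipy's `ks_2samp(method="asymp")` exactly, including ties; the exact
small-sample method remains available per feature via `ks_method`.
Feature selection is the **union** of the three p-value screens at
alpha = 0.05 and a fold-change departure `max(FC, 1/FC) > 1.2` (strict);
an intersection mode exists behind a flag.  The union is deliberately
anticonservative — it is a screen, not an inference; false discovery is
controlled downstream by the permutation tests.  The high/low-recovery
screen labels features at `ratio ≥ 5` (inclusive) as H and `≤ 1/5` as L.

## Classification

Random forest with 1000 trees and `mtry = ⌊√p⌋` by default; tree settings
not otherwise pinned are scikit-learn defaults (unlimited depth, min leaf
1, Gini).  Model quality is the AUC of **out-of-bag** probabilities — each
sample scored only by trees whose bootstrap excluded it — computed by the
rank (Mann–Whitney) formula with ties counted ½.  OOB-on-all-samples is
the primary procedure; no separate train/test split is taken, since OOB
already provides honest internal validation.  Samples in-bag for every
tree (vanishingly rare beyond ~50 trees) are excluded from the AUC with a
warning.

The AUC permutation test re-runs the *entire* pipeline — feature screen
then forest — on each permuted label vector.  This is the default
("honest") null: because the screen sees the permuted labels, the null
correctly absorbs the optimism that full-data feature selection induces in
OOB estimates.  `fixed_selection=True` instead freezes the features selected on
the original labels, reproducing the simpler historical procedure; its
null AUCs are lower and its p-values accordingly smaller.  If a screen
selects nothing (possible under permuted labels), the forest falls back to
all features rather than failing.

## Synthetic-data generator

### Enrichment

`EnrichmentConfig` defaults define the simulated study: 10⁵ unique
sequences at mean copy number 3 (log-normal, sdlog 0.3) stand in for the
experimental 10¹¹ → 10⁶ regime at desk scale; 1 % of sequences are planted
binders (40 % to disease-specific targets, 40 % control-specific, 20 %
shared) with log-normal affinities (mean 50, sdlog 0.3) against 200
targets; cohort-specific targets are present at ~10⁻³ relative abundance
in the opposing cohort's plasma.

Capture is linear with an additive floor: per-molecule weight
`w = background + affinity × abundance`, scaled so a positive round
captures an expected 25 % of molecules and a counter round 25 % (the
supernatant is kept).  Molecule sampling is Poisson thinning — the
multinomial-without-replacement limit appropriate when capture
probabilities are small.  PCR multiplies copies by `(1+efficiency)^cycles`
(defaults 0.6 and 10) with small log-normal noise; a fixed-size aliquot
(the naive pool's total) seeds each later iteration, mirroring the bench
practice of carrying an aliquot of the PCR product forward and providing
the bottleneck through which low-copy sequences drop out.

These defaults were set together, before the acceptance runs, so that the
three canonical dynamics hold: unique count strictly decreases every
iteration, mean copies per survivor rises far more than 10-fold, and
planted disease binders end with higher median share in the disease arm
than the control arm (the counter-selected arm retains them at share ~0).
The capture fraction matters most: at 10 % per positive round the
second positive selection becomes a ~1 % molecule bottleneck per iteration
and genuine binders die by drift; 25 % keeps the collapse sharp while
retaining ~70 % of planted binders.

### Profiling

The profiling generator emulates an equimolar resynthesized library in
which every member is a binder: one target each among 500, log-normal
affinity (sdlog 1.0), target abundances log-normal (sdlog 0.5), background
5 % of the mean specific signal.  A patient is the cohort plasma profile
times per-target log-normal biological noise (sdlog 0.4); replicates pass
the expected recovery through gamma overdispersion (CV 2 %) and a
multinomial at exactly the sequencing depth (default 10⁶).

The biological-noise default comes from the log-normal correlation
identity: for shared per-sequence signal with log-variance s² and
independent per-patient target noise with log-variance σ², the expected
Pearson correlation between two patients' profiles is
`(e^{s²} − 1)/(e^{s²+σ²} − 1)`.  With s² = 1.0² + 0.5² and σ = 0.4 this
sits at ~0.8, inside the 0.74–0.90 band technical-replicate/biological
scatter plots show for such assays, while multinomial noise at depth 10⁶
over 2000 features leaves technical-replicate correlation above 0.99.
Simulated values land at r ≈ 0.76–0.84 (inter-patient) and ≥ 0.998
(technical).

### What the generator does not model

Aptamer folding and sequence-dependent structure; PCR mutation and
chimera formation; differences between ultracentrifugation and
PEG-precipitation partitioning (one capture step); index hopping;
quality-score variation within reads (qualities are constant per read and
consistent with the error rate); multi-target binding per sequence.
Passing tests therefore demonstrate that the *statistical machinery*
behaves correctly under a faithful count-generating process — not that any
particular wet-lab signal exists.

## Problem sizes in the checks

The end-to-end recovery checks use a 2000-feature, 100-vs-100-sample
cohort with 50 informative features at a 0.5-SD log-scale shift, 199
permutations for the signal arm, and 150 trees — at these sizes the OOB
AUC estimate is stable and a full honest-null permutation run completes in
minutes on one CPU.  The matched no-signal calibration uses 19
permutations per seed across 20 seeds: 19 permutations exactly resolve the
p ≤ 0.05 boundary (p ≤ 0.05 iff the observed AUC beats all 19 nulls), so
more permutations would add cost without changing the decision.
Permutation-null calibration of the ANOVA count statistic uses 200
permutations per seed across 50 seeds.  All randomness descends from
explicit integer seeds via `numpy` seed sequences; identical configs give
byte-identical outputs.

## Known limitations

* The parser assumes single-end reads in the fixed layout above; indels in
  the variable region shift the anchor and make a read invalid rather than
  recovered.
* Distinct 35-mers are distinct features; no clustering of near-identical
  sequences is attempted (one substitution error in a variable region
  creates a spurious singleton feature — at realistic error rates this
  inflates the singleton count but barely perturbs normalized profiles of
  abundant features).
* The enrichment simulator's one-target-per-sequence affinity map cannot
  represent cross-reactive ssODNs.
* `select_l2000` ranks by smallest p across tests then fold-change
  departure; with fewer candidates than requested it returns all with a
  warning rather than padding.
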