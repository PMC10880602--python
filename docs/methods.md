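# Methods

## Duplex-stability encoding

A nucleotide sequence of length *n* is represented by the *n* − 1 stacking
free energies of its overlapping dinucleotide steps, read 5'→3' on the
provided strand.  The shipped parameter set is the unified nearest-neighbor
ΔG°37 scale (kcal/mol); it is complement-symmetric — value(XY) =
value(reverse complement of XY) — which gives the encoder the law
`encode(revcomp(s)) = reverse(encode(s))`, asserted by property tests.  The
table is a plain two-column file and every operation accepts an alternative
table, so the thermodynamic scale is a swappable, auditable parameter rather
than a constant baked into code.  The exact numeric scale matters little for
classification: any complement-symmetric table that separates A:T-rich from
G:C-rich steps exposes the same promoter architecture.

Ambiguity handling: strict mode (default) rejects non-ACGT characters;
permissive mode imputes affected steps with the mean of the 16 table values
and counts them per record, so genome files containing N runs can be
processed without silently fabricating signal.  Lowercase (soft-masked)
input is uppercased before validation.  No automatic reverse-complementing
is done — window extraction is responsible for strand.

## Window conventions

Promoter numbering has no position 0, so the span "−60 to +1" is exactly 60
nucleotides.  Internally the positive window is the last 60 nt of the
upstream string, i.e. the 0-based half-open interval [anchor − 60, anchor).
Dinucleotide step *i* (1-based from the window's 5' end) is displayed at
promoter coordinate *i* − 60, so a 59-step profile spans −59..−1 and the
planted −10 box centers on step −10.

Negatives are 60-nt substrings of the downstream region at a 1-based start
offset uniform on [1, min(500, len − 59)]; the upper bound is clamped for
short regions rather than discarding the record.  A record contributes a
(positive, negative) pair or nothing, so balance is structural.  Duplicate
(sequence, label) windows — operons sharing a start — are removed before
splitting to prevent leakage of identical strings across the train/test
boundary, and the larger class is downsampled (seeded) to restore balance.

## The cascade

Stage 1 is an XGBoost binary classifier.  Its default configuration —
200 estimators, learning rate 0.2, maximum depth 7 — is the winner of an
exhaustive 3×3×3 grid ({50, 100, 200} × {0.01, 0.1, 0.2} × {3, 5, 7})
scored by stratified 5-fold CV accuracy; the grid-search utility re-runs
this selection on any dataset, breaking ties toward the simplest model
(fewer trees, then shallower, then slower learning rate).

Error collection is out-of-fold: stratified 10-fold over the full training
set, each record predicted once by a model trained without its fold.  This
reproduces whole-dataset error counts while guaranteeing stage 2 never
trains on predictions a model made about its own training data.  Stage 2
takes the false negatives (label 1) versus the false positives (label 0),
downsamples the larger set uniformly without replacement to the smaller
one's size, and trains an XGBoost with library-default hyperparameters —
tuning this stage was found not to help, so the defaults are kept
deliberately.  If either error set is empty the cascade degenerates to
stage 1 alone.

Prediction uses the rescue-union rule: stage 2 is consulted only for
stage-1 negatives, and `final = stage1 OR stage2`.  Both stages threshold
predicted probability at 0.5 (configurable).  The union rule makes recall
monotonically non-decreasing and specificity non-increasing relative to
stage 1; both directions are asserted on labeled data.  ROC analysis for
the cascade is defined on stage-1 scores only, since union labels induce no
natural ranking.

All randomness flows from one top-level seed expanded through
`numpy.random.SeedSequence` into named sub-seeds (fold shuffling, stage
fits, stage-2 downsampling), so a saved manifest plus the data reproduces
the model bit-for-bit.  Model archives embed both stages, the manifest, and
the DDS table with its SHA-256 checksum; loading verifies format version
and checksum and refuses tampered archives.

## Evaluation

Metrics are the standard confusion-matrix quantities; a zero-denominator
metric is reported as undefined (None), never coerced to 0.  The
six-family algorithm screen (Random Forest, SVM, logistic regression,
gradient boosting, XGBoost, k-NN, all at library defaults) selects by
held-out accuracy.  Cross-validation is stratified k-fold with per-fold
metrics, their mean ± sd, and per-fold ROC points.  The external-validation
protocol scores a set of known promoters and reports stage-1 hits, stage-2
rescues among stage-1 rejects, and the recovered fraction — the accounting
identity `total = hits + rescues` is exact by construction.

## Profile statistics

Outcome groups (TP/TN/FP/FN, by stage-1 labels by default) get per-position
mean DDS profiles.  The unit of analysis for hypothesis tests is the
per-sequence mean DDS — one independent observation per sequence — rather
than per-position values, which are correlated within a sequence; the
per-position profiles are descriptive.  The stack is Shapiro–Wilk on the
pooled means, a Kruskal–Wallis omnibus across groups, and a pairwise
post-hoc.  Tukey's HSD is the default post-hoc for fidelity with the
original analysis even though pairing a rank-based omnibus with a
parametric post-hoc is statistically unusual; Dunn's rank-based test
(tie-corrected z statistics, Holm adjustment, implemented in-package) is
provided as the internally consistent alternative, and both label their
method in the output.  Degenerate input in which every observation is
identical returns omnibus statistic 0 and p = 1 (no evidence of any
difference) rather than an error.

## Synthetic benchmarks

The generator emulates the one property of promoter corpora the method
exploits: localized AT-rich, thermodynamically weak elements at fixed
offsets.  Positives are i.i.d. background (default GC 0.5) with TATAAT
centered at step −10 and TTGACA at step −35; negatives are pure background.
Each motif position is redrawn uniformly over ACGT with probability equal
to the mutation rate, so rate 0 plants exact consensus and rate 1 is
indistinguishable from background — classifier accuracy decays
monotonically toward 0.5 as the rate rises, which is asserted at three rate
points.  The default rate is 0.10, a regime where stage 1 exceeds 0.98
held-out accuracy.  A `weak_fraction` subpopulation (default rate 0.45 when
enabled) has measurably higher stage-1 FN rates, supplying the errors the
rescue stage needs.  The upstream-genome fixture embeds positive or
negative windows as the final 60 nt of 400-nt records, with
`round(n_genes × fraction)` promoter genes chosen by the seeded rng.

What passing on this benchmark does *not* show: real promoters have
σ-factor diversity, correlated background composition, operon structure,
and curation noise, none of which are simulated.  Synthetic results
validate the machinery (encoding laws, cascade algebra, statistical
calibration, pipeline consistency), not field performance; on real corpora
the same pipeline is expected to show substantially higher error rates, and
the balance of the stage-2 training set then matters more.

## Problem sizes and numerical choices

Headline runs use 2000 sequences per class with a 20% held-out test — large
enough that a ±0.05 accuracy band is ~4.5 sd of binomial noise — and the
grid search re-selection uses 600 per class.  The genome-scan demonstration
uses 1000 upstream records.  Stage thresholds default to 0.5; fold counts
are 10 (error collection, CV) and 5 (grid search).  XGBoost runs
single-threaded for bitwise reproducibility across machines.

Known limitations: on nearly separable data stage 2 trains on a handful of
errors and generalizes poorly, so the union rule can cost substantial
specificity for a small recall gain — visible in the genome-scan
demonstration, where most non-promoter upstream regions are rescued into
positive calls.  This mirrors the method's design bias toward sensitivity;
users wanting precision should inspect stage-level labels, which are always
retained in the output.
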