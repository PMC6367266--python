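# Methods

## Problem and model

Given a non-coding RNA and a protein, the package predicts whether the two
molecules interact, using only their primary sequences. Each pair is encoded
by *fused composition features*: the RNA is summarized by its m-mer
frequency vector `R = (r_1..r_{4^m})` over ACGU, and the protein — after
translation into the 7-letter reduced alphabet given by the physiochemical
grouping {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C} — by
its n-gram frequency vector `P = (p_1..p_{7^n})`. For every cell (i, j) of
the outer product, four non-linear fusions are computed:

    GM_ij    = sqrt(r_i p_j)
    HM_ij    = 2 r_i p_j / (r_i + p_j)         (0 at r_i = p_j = 0)
    PowRP_ij = log_{r_i} p_j = ln p_j / ln r_i
    PowPR_ij = log_{p_j} r_i = ln r_i / ln p_j

giving a 4·4^m·7^n-dimensional vector per pair. The rationale is that an
interaction is a property of the *pair*: a fused cell responds to the joint
abundance of an RNA word and a protein word, which a plain concatenation
`[R, P]` cannot express without the classifier learning the interaction
term itself. The fused vector is then pruned to the top-k features by
random-forest importance (mean decrease in impurity averaged over trees),
and a classifier (random forest by default; SVM and logistic regression are
available) is trained on the selected features.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| m | 4 | RNA k-mer length; 4^m base features |
| n | 3 | protein (reduced) k-mer length; 7^n base features |
| normalization | windows | divide counts by L−k+1 (frequencies sum to 1); `length` divides by L |
| ambiguity_policy | skip_window | windows containing a nonstandard residue are dropped and the denominator reduced; `error` raises |
| epsilon | 1e-6 | additive smoothing of both log-power inputs (zero frequencies are otherwise outside the domain) |
| log_guard | 1e-6 | half-width of the exclusion band around base 1; smoothed bases inside it are nudged to the nearer edge, so no logarithm's denominator vanishes and every emitted value is finite |
| k (selection) | 100 | features kept after importance ranking |
| forest_trees | 500 | trees in the ranking forest |
| scope | per_fold | ranking fitted on each CV training split only; `global` ranks once on the full data (leaks selection information into held-out folds, but reproduces the simpler whole-dataset protocol) |
| n_folds | 10 | stratified cross-validation folds; 3 also common |
| threshold | 0.5 | class-1 probability cutoff for the confusion-based metrics |

The m=4 / n=3 defaults follow the cross-validated settings that performed
best in benchmark studies of this feature family; the examples and
acceptance runs here use m=2 / n=2 (3,136 fused dimensions), which matches
the 2-mer motifs the synthetic generator plants and keeps a full
cross-validated run on 400 pairs around a minute of CPU.

Evaluation reports Accuracy, Sensitivity, Specificity, Precision, MCC
(all from the confusion matrix at the threshold), AUC (computed as the
normalized Mann–Whitney rank statistic with ties averaged), and their
arithmetic total ("Sum", range −1..6), each averaged over folds
(macro-averaging, not pooled predictions). MCC is defined as 0 when its
denominator vanishes, Precision as 0 when nothing is predicted positive;
a single-class evaluation set is a hard error because AUC is undefined.

## Numerical and design choices

- Feature order is deterministic: family-major (GM, HM, PowRP, PowPR), then
  RNA k-mers lexicographic over ACGU, then protein n-grams lexicographic
  over group digits 1–7; names are `FAMILY:<rna-kmer>:<protein-ngram>`, so
  a persisted selection is portable across runs.
- Importance ties are broken by ascending original column index, making
  rankings reproducible bit-for-bit given the forest seed.
- Fused matrices are built row-by-row with the protein axis chunked, so the
  only full-size allocation is the output matrix; m=4, n=3 (351,232
  dimensions per pair) stays feasible on a desktop.
- The SVM emits probabilities through a Platt sigmoid calibrated on the
  training split; logistic regression and SVM inputs are standardized
  inside the model pipeline. Classifier hyperparameters are library
  defaults and are recorded in each run's manifest.
- Negative pairs are sampled uniformly without replacement from the
  RNA × protein cross product excluding all pairs already present, with a
  mandatory explicit seed. No degree constraints are imposed (whether every
  RNA must be reused is an open protocol question; uniform sampling is the
  neutral choice).

## The synthetic benchmark generator

`simulate_dataset` emulates the shape of the public RPI benchmark tables:
a few hundred labelled pairs in which nearly every positive pair has its
own RNA (100–200 nt) and protein (150–300 aa), both drawn from a uniform
background composition. Each positive pair is assigned one of ten
(RNA 2-mer, protein group 2-gram) motif pairs, and occurrences of both
motifs are inserted at random positions into that pair's sequences until
the realized occurrence count reaches `enrichment` times its background
expectation (insertions are topped up because a later random overwrite can
destroy an earlier occurrence). Negatives are uniform non-positive
cross-pairs. The ground-truth manifest names the ten planted GM cells
(`GM:<motif_r>:<motif_p>`; the other families share the same cells) and
all seeds.

Because the signal is planted in the *joint* occurrence of an RNA word and
a protein word, a negative pairing of two signal-bearing sequences only
mimics a positive when both carry the same motif pair (probability ~1/10
under the default ten motifs). This is deliberate: it makes the benchmark
sensitive to exactly the pairwise structure the fused features encode, and
it is why the concatenated-baseline variant performs near chance on these
data — the baseline sees both margins but not their co-occurrence. Real
benchmarks are *not* like this: real interactions also carry marginal
composition signal (binding-protein families, RNA classes), secondary
structure, and shared sequences across pairs, so passing on this generator
demonstrates that the pipeline recovers pairwise composition signal, not
that it attains any particular accuracy on real data.

At `enrichment = 1.0` nothing is inserted, so the generator plants no
label–feature association.

### Below-chance cross-validation on unenriched data

An unenriched (enrichment 1.0) benchmark nevertheless yields
cross-validated AUC systematically *below* 0.5 (≈ 0.28–0.44 over seeds,
with or without feature selection). The mechanism is sequence reuse in the
negative-sampling protocol, not planted signal: negatives are cross-product
pairs over the same sequence pool as the positives, a k-mer frequency
vector is a near-unique fingerprint of its sequence, and a random forest
readily memorizes fingerprints. When a pair is held out, its own label is
excluded from training, so the training labels attached to that pair's two
sequences tilt the *opposite* way (a held-out positive's sequences appear
in training only inside negatives, and vice versa), and predictions on the
held-out fold are systematically inverted. Two controls isolate the
mechanism: permuting labels (which breaks the coupling between labels and
the pairing structure while keeping all sequences and features) restores
AUC ≈ 0.5 through the identical pipeline, and rebuilding the unenriched
benchmark with disjoint sequence pools for positives and negatives also
restores AUC ≈ 0.49.

This is a property of the evaluation protocol that the public RPI
benchmarks share — their negatives are likewise random re-pairings of the
positive-set sequences, and their pair counts are close to their sequence
counts — so per-pair cross-validation on such data mixes genuine
composition signal with sequence-identity effects in both directions.
Users evaluating small paired datasets should compare against
permutation baselines run through the identical pipeline rather than
assuming 0.5 as the chance level.

## Problem sizes used in tests and the acceptance script

Signal-recovery runs use the generator defaults (400 pairs, enrichment
3.0, m=n=2, 10-fold CV, 500-tree ranking forests, k=100); the recovery
median uses 20 generator seeds and the paired variant comparison 10 seeds.
Unit and property tests use smaller instances (60–120 pairs, 3-fold) to
keep the default suite fast.

## Known limitations

- Composition-only: no secondary structure, no physicochemical profiles,
  no binding-site localization.
- The generator's uniform background and dedicated-sequence design make it
  easier than real benchmarks (no shared sequences across pairs, no
  compositional confounds between classes).
- `scope="global"` selection reproduces a leaky protocol on purpose;
  per-fold is the honest default and the two can differ substantially on
  small datasets.
- Forest-importance selection inherits impurity-importance biases (e.g.,
  toward high-cardinality/high-variance features); within a single fused
  family on frequencies this is mild, but comparisons across families
  should not over-interpret small count differences.
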