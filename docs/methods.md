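# Methods

## Pipeline

A labeled corpus flows through five stages: (1) text normalization —
lower-casing and replacement of every character outside `[a-z0-9]` and
whitespace by a space, so punctuation, quotation marks and hyphens all
become token boundaries ("p53-mediated" → `p53`, `mediated`; digits are
kept because biomedical vocabulary leans on symbols like p53 or HER2);
(2) whitespace tokenization; (3) stop-word removal against a bundled
English function-word list (`data/stopwords_en.txt`, one term per line,
user-replaceable); (4) an optional, default-off pass collapsing runs of
three or more identical characters ("coooool" → "col"); (5) Porter
stemming. Rare-word removal happens later, at vocabulary construction,
via the `min_df` threshold.

## Stemming

The stemmer is the 1980 suffix-stripping algorithm with the author's
published revisions to the rule table: step 2 uses `(m>0) bli → ble`
rather than `abli → able`, and gains a `logi → log` rule. For the latter
we count the `l` with the stem when evaluating the measure condition
(the reading NLTK documents), so short scientific stems behave uniformly:
`biology`/`geology` → `biolog`/`geolog` exactly as `archaeology` →
`archaeolog`. Without that reading the measure of the remaining stem
("bio") is zero and the rule could never fire for these words. Words of
length ≤ 2 and digit-bearing tokens pass through unchanged. The
implementation is verified against 87 hand-traceable vectors taken from
the algorithm's own published examples; note that faithful step-3
behavior stems "negative" to "neg" (the `(m>0) ative → ''` rule, the
same one that maps formative → form).

## Features

Vocabularies index unigrams and adjacent-pair bigrams (joined with `-`)
in lexicographic order, so rebuilding from the same corpus is
deterministic. Bigrams are formed over the whole stop-word-filtered
document; sentence boundaries are not tracked, which only affects the
handful of bigrams spanning them. `DF` is counted per document (set
semantics), and `min_df = 2` by default: a term must appear in at least
two training documents. TF is the raw in-document count, with no length
normalization, and the weight is `TF · log10(N/DF)`. IDF statistics come
from the training portion only — in cross-validation the vocabulary is
rebuilt inside every fold — so no test document can influence the
feature space it is scored in; terms unseen in training are dropped at
prediction time.

## Classifiers and optimization

The linear models minimize `a·R(w) + (1/n) Σ L(w; xᵢ, yᵢ)` by
subgradient descent from `w = 0`, full-batch by default with an optional
seeded mini-batch fraction, step size `η/√t`. Defaults (100 iterations,
`η = 1.0`, `a = 0.01`, L2) are the long-standing defaults of the
large-scale linear-classifier tooling this pipeline descends from; all
are exposed in `TrainConfig`. The objective value is recorded every
iteration for convergence monitoring; with decaying steps it is
non-increasing on convex toy problems up to small oscillations, which
the tests monitor with a tolerance rather than asserting strict descent.
No intercept is fitted by default (scores are exactly `wᵀx`); a
constant-one bias feature can be enabled with `add_bias`.

Binary decisions threshold at `z > 0` — for logistic regression
equivalently `σ(z) > 0.5` — with ties resolved to the negative (pivot)
class. One-vs-rest reduction handles multiclass for the linear models
(argmax of per-class scores, exact ties to the lexicographically
smallest label); naive Bayes is natively multiclass. Naive Bayes
consumes the TF-IDF values themselves as pseudo-counts so that all three
classifiers share one representation; its ROC score is the top1 − top2
log-posterior margin, while SVM uses `z` and logistic regression the
probability.

## Evaluation

`ACC = (TP+TN)/(P+N)`, `PPV = TP/(TP+FP)`, `TPR = TP/(TP+FN)`; a ratio
with zero denominator is reported as absent with a warning, never
silently zero. Multiclass precision/recall are macro-averaged over
one-vs-rest reductions (micro available). Cross-validation is stratified
by class by default (an unstratified mode exists): balanced folds keep
the small-corpus runs stable. Repeats default to 10, repeat *r* seeding
every stochastic component with `seed + r`. ROC curves sweep the unique
scores, grouping ties into single threshold steps, so the trapezoidal
AUC equals the Mann–Whitney pairwise statistic with ties counted ½ —
the tests check this identity by brute force and against scikit-learn.

## Synthetic corpora

The generator emulates the one structural assumption the pipeline makes:
classes differ in the frequency of class-specific vocabulary. Each
document of class *c* draws its content tokens from a mixture putting
probability *s* (the signal) on *c*'s private marker terms and `1 − s`
on a shared background vocabulary; stop-words are injected at rate 0.2
and punctuation attached at rate 0.1 so preprocessing is genuinely
exercised. Document lengths are negative-binomial (mean 150 tokens,
dispersion 10 — abstract-like; full-text emulation would use a mean
near 3000). The background vocabulary (500 pronounceable alphabetic
words) is Zipf-distributed, so the most common background words approach
`DF = N` and exercise the TF-IDF zero-weighting of ubiquitous terms;
marker terms carry digits (like gene symbols), which keeps them disjoint
across classes under stemming. The study corpus used by the end-to-end
tests is 3 × 200 documents at signal 0.5 with seed 1 — large enough for
stable fold statistics, small enough that the full repeated-CV suite
runs in about a minute on one CPU.

What passing on such corpora shows — and does not. The generator
produces exchangeable multinomial text with perfectly disjoint marker
vocabularies, no synonymy, no topic drift, no label noise and no
correlated features, so near-perfect accuracy at signal 0.5 demonstrates
that the pipeline's plumbing (fold hygiene, featurization, optimization)
is correct, not that real MEDLINE corpora would be classified at that
accuracy; conversely the chance-level result under permuted labels shows
the pipeline cannot manufacture signal. On the regularization sweep, the
direction seen on large real corpora (L2 best, then L1, then none) is
not reliably reproduced at the miniature fixture sizes used here, where
all variants sit within noise of one another; the sweep is therefore
reported rather than asserted.

## Degenerate inputs and tie-breaking

Empty documents are accepted with a warning and vectorize to the zero
vector; an all-zero vector under naive Bayes falls back to the priors.
Duplicate document ids, single-class training sets, non-finite feature
values, dimension mismatches and out-of-range fractions are hard errors.
Train/test splitting rounds the training size half-up after a seeded
uniform shuffle.

## Known limitations

No lemmatization, named-entity recognition or feature reduction; no
kernel SVMs or softmax multinomial logistic regression; no significance
testing between classifiers. MEDLINE ingestion takes class labels from a
sidecar file rather than deriving them from MeSH headings. The
subgradient optimizer is the plain decaying-step variant: it converges
on the problems at hand but is not a modern proximal or variance-reduced
method, and L1 runs produce small weights rather than exact zeros.
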