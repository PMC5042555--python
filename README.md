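# litclf — biomedical literature classification on one machine

`litclf` assigns scientific abstracts (or full-text articles) to disease
categories — breast, lung or prostate cancer being the motivating example —
using the classic bag-of-words pipeline: Porter-stemmed unigram/bigram
TF-IDF features feeding three classifiers trained from their convex
objectives. It is aimed at text-mining researchers who want a small,
fully tested, reproducible implementation of this pipeline without any
distributed-computing infrastructure.

## The model

Each document *d* becomes an equal-length sparse vector whose entry for
term *t* is the TF-IDF weight

```
W_{t,d} = TF_{t,d} · log10(N / DF_t)
```

where `TF_{t,d}` is the raw count of *t* in *d*, *N* the number of
training documents and `DF_t` the number of them containing *t*. Terms
are Porter stems and hyphen-joined stem bigrams; a term occurring in
every document (e.g. "almost") gets weight 0 and is thereby discarded as
uninformative.

Three classifiers consume the same vectors:

* **Linear SVM** — minimizes `f(w) = a·R(w) + (1/n) Σᵢ max(0, 1 − yᵢ wᵀxᵢ)`;
* **Logistic regression** — loss `log(1 + exp(−y wᵀx))`, probabilities via
  the logistic link `f(z) = 1/(1 + e^{−z})`, `z = wᵀx`;
* **Multinomial naive Bayes** — Laplace-smoothed, with the TF-IDF values
  as pseudo-counts, assuming class-conditional feature independence.

`R(w)` is none, `‖w‖₁` or `½‖w‖₂²` with trade-off `a ≥ 0` (default L2,
`a = 0.01`). The linear models are fitted by seeded full-batch
subgradient descent with step size `1/√t` decay (100 iterations by
default); multiclass problems are reduced one-vs-rest. Evaluation is
repeated stratified 5-fold cross-validation (10 repeats by default) with
accuracy, macro precision/recall and ROC/AUC.

## Worked example

Generate a 3-class synthetic corpus of 600 documents whose classes put
half their token mass on class-specific marker terms (signal 0.5), then
cross-validate an L2-regularized SVM:

```
litclf -q generate --classes 3 --n 600 --signal 0.5 --seed 1 -o corpus.jsonl
litclf -q cv -i corpus.jsonl --clf svm --reg l2 --k 5 --repeats 10 --seed 1 -o results.csv
```

which prints

```
Repeated 5-fold cross-validation (10 repeats, 50 folds)
====================================================
classifier:     svm (l2)
mean accuracy:  1.0000 (sd 0.0000)
mean precision: 1.0000
mean recall:    1.0000
```

At signal 0.5 the classes are easily separable, so all 50 folds classify
every held-out document correctly; `results.csv` holds the per-fold
accuracy/precision/recall in tidy form. Shuffling the labels drops the
mean accuracy to ≈ 1/3 (chance for three balanced classes). The same
pipeline is available as a library:

```python
from litclf import generate_corpus, cross_validate, PipelineConfig
corpus = generate_corpus()                      # 600 docs, signal 0.5
res = cross_validate(corpus, PipelineConfig(classifier="nb"), k=5, repeats=10, seed=1)
print(res.summary())
```

Real corpora enter through `read_medline` (MEDLINE flat files, labels
from a sidecar `doc_id<TAB>label` file) or `read_labeled` (JSONL/CSV with
`id`, `text`, `label` fields).

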