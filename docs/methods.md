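# Methods

## Problem setting

Free-text neuroradiology reports are classified into eight binary
categories: *abnormal*, and seven specialised abnormality categories
(acute stroke, mass, atrophy, vascular, small vessel disease, white
matter inflammation, encephalomalacia). Report-derived labels are then
treated as proxies for image labels, so the package also quantifies how
label noise in the reference standard bounds what any text classifier can
achieve.

## Classifier

**Pre-processing.** Reports are lower-cased and tokenised; nothing else
(no stemming, stop-word removal or spelling correction) — only the steps
a transformer encoder requires. Vocabularies come in a word-level
(`whitespace`) mode and a byte-pair (`subword`) mode learned from the
corpus. Sequences are bracketed by boundary tokens, padded with a
reserved pad id, and truncated to `max_len` (default ceiling 512; the
desk-scale configuration trains at 128). Truncation drops the **tail** by
default: findings sentences dominate early, conclusions repeat them late.
A `head` policy is available; behaviour on over-length reports is a
documented configuration rather than a fixed rule.

**Architecture.** Token ids → learned token + position embeddings → N
post-norm transformer blocks (multi-head self-attention with key padding
masks, ReLU feed-forward) → additive attention pooling → classification
head. The pooling scorer is the standard additive form
`u_i = vᵀ tanh(W h_i + b)` with a softmax over non-padding positions;
padding receives exactly zero weight, weights are non-negative and sum to
one, and the pooled vector is the weighted sum of token vectors. The head
is one hidden ReLU layer (default width 256) with a single sigmoid output.
Sequence-boundary tokens participate in pooling; `attention_report`
renormalises the weights over surface tokens when mapping them back to
words. Desk-scale encoder defaults: 2 layers, d = 64, 4 heads,
feed-forward width 256, randomly initialised. Eight independent models
share code but not parameters.

The network is implemented in NumPy (float64) with hand-written
reverse-mode gradients, verified against central finite differences in
the test suite. There is no dropout; inference is exactly deterministic,
which the evaluation contracts rely on.

**Training.** Binary cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), batch
size 16. The per-epoch shuffle is reseeded deterministically from the run
seed, the final partial batch is averaged per example, a checkpoint is
recorded after every epoch, and the checkpoint with minimum validation
loss is returned. The `Hyperparams` default learning rate is 1e-5 — the
fine-tuning rate appropriate when the encoder carries pretrained weights
whose knowledge a larger rate would catastrophically overwrite. The
randomly initialised desk-scale encoder has nothing to forget, so
`desk_hyperparams()` uses 1e-3; desk-scale experiments in the tests and
the acceptance script train for 4–5 epochs. Epoch count is configurable
(default ceiling 10); no learning-rate schedule is applied. Training
refuses patient overlap between train and validation tables and warns on
single-class training labels.

## Baseline comparator

The classical recipe: a report is featurised as the arithmetic mean of
static (context-independent) word embeddings over in-vocabulary tokens
(zero vector if every token is out of vocabulary) concatenated with
N-gram counts (N = 1, 2, 3), fed to logistic regression (unregularised by
default, L2 optional; counts rather than tf-idf, weighting configurable).
Static tables come as fixed random vectors or as PPMI co-occurrence
factorised by truncated SVD — both context-independent, which is the
property under study: the mean-embedding block of a report depends only
on its bag of words, so a distantly negated finding contributes the same
features as an asserted one.

## Evaluation protocol

* **Patient-level splits.** Patients (never reports) are shuffled and
  assigned to train/validation/test at 60/20/20 by cumulative report
  count, so bucket sizes match the targets within one patient group and
  no patient spans buckets. An image-labelled hold-out set is excluded
  from splitting entirely and stays fixed across the repeated splits
  (default 10 repeats).
* **Metrics.** AUC-ROC is the Mann–Whitney statistic with ties credited
  ½, computed from midranks. Sensitivity, specificity, balanced accuracy
  and F1 are computed at threshold 0.5 by default; a Youden-J threshold
  chosen on validation data only is available. Across repeats each metric
  is summarised as mean ± 1.96·sd/√n (normal approximation); printed "±"
  values in the literature are ambiguous between SD/SE/CI, so the chosen
  definition is echoed in the output metadata, and a single repeat
  reports its CI half-width as NaN.
* **DeLong tests.** Paired comparisons (two classifiers on one test set)
  use the covariance of the per-positive and per-negative structural
  components of the Mann–Whitney statistic; unpaired comparisons (e.g.
  report-label vs image-label test sets) sum the two independent
  variances. Zero estimated variance with equal AUCs defines p = 1; with
  unequal AUCs it raises a degenerate-variance error. The paired p-value
  is validated against a 20,000-draw pair-swap permutation oracle, and
  the paired variance against a bootstrap.
* **Fleiss' kappa** follows the standard count-table formula; a table
  whose ratings all fall in one category has no chance-corrected
  agreement and raises an error. Validated against statsmodels and a
  direct re-implementation.
* **2-D embedding export** delegates t-SNE to scikit-learn under a fixed
  seed. Identical input vectors are deduplicated before projection so
  they land on identical points (t-SNE breaks such ties arbitrarily);
  with fewer than three distinct vectors a PCA layout is used.

## Synthetic corpus generator

Hospital report corpora cannot be redistributed, so all tests run on a
seeded generator that emulates their structure: 5–10 sentence reports
(optional protocol or clinical-history sentence, findings block,
neutral/filler sentences, conclusion), several reporter styles that
favour different phrasings, multiple reports per patient
(1 + Geometric(0.5), capped at 6), and eight label columns.

**Finding mentions.** Every mention — asserted or negated — uses one
grammar: `{opener} {det} {m1} {m2} {m3} {connector} {finding}` with
`det = "a"` (asserted) or `"no"` (negated). The polarity cue therefore
sits at least four tokens upstream of the finding lexicon: distant
negation by construction. All mentions within one report share a single
(opener, modifiers, connector) draw — reporters phrase consistently — and
benign findings (prominent perivascular spaces, incidental arachnoid
granulation, …) are asserted or negated with the same grammar in normal
and abnormal reports alike. The consequence, deliberate and load-bearing:
every word window of three tokens or fewer has class-ambiguous
statistics, so a bag of ≤3-grams can count asserted and negated mentions
but cannot attribute a determiner to a particular finding, while a
contextual model reading the whole sentence can. This realises, in a
controlled corpus, the mechanism that makes context-independent
embeddings mishandle negated findings; residual honest cues (explicit
"normal intracranial appearances" statements in some normal reports,
hedging words) keep the baseline competitive rather than useless.

**Labels and calibration.** A report is abnormal with configurable
prevalence (default 0.384, the rate observed in a 3,000-report
expert-labelled binary dataset). Abnormal reports receive
`1 + Poisson(mean − 1)` distinct granular categories, truncated at 5,
with the default mean 1.56 — matching the published mean/max/mode shape
with one parameter — drawn without replacement with weights proportional
to published per-category counts. The implied marginal prevalence of each
category is available exactly via `GeneratorConfig.expected_prevalence`
(a 2⁷-state dynamic programme over the weighted draws). Pairwise
co-occurrence beyond these marginals is not modelled (the underlying
correlation structure is unpublished); categories are conditionally
independent given the count. Other defaults, fixed a priori: distant
negation rate 0.3 (probability a report negates at least one absent
category), hedging rate 0.15, 3 reporter styles, history/protocol
sentence probability 0.5.

**Rater tables.** Simulated raters report a subject's true category with
probability 1 − d and otherwise draw uniformly over all categories;
d = 0 reproduces perfect agreement, d = 1 pure noise.

**What the generator does not emulate.** Voice-recognition artefacts,
spelling errors, true clinical vocabulary breadth (template corpora have
tiny vocabularies, so lexical-richness statistics on synthetic text are
orders of magnitude below real corpora), inter-report label correlation
within a patient, and style drift over time. Tests passing on this
corpus demonstrate the architecture and protocol contracts — notably that
attention pooling exploits long-range negation where bag-of-words cannot
— not clinical-grade performance on real reports.

## Lexical statistics

Words for lexical statistics are lower-cased, punctuation-stripped
whitespace tokens (independent of the model tokenizer; "word" is
otherwise undefined in this setting). From the frequency spectrum V(i):
M1 = Σ V(i) types, N = Σ i·V(i) tokens, M2 = Σ i²·V(i); TTR = M1/N;
Yule's I = M1²/(M2 − M1), the inverse of Yule's characteristic K up to
the 10⁴ factor (the statistic admits variants; this one is adopted and
documented). An all-singleton corpus reports Yule's I as infinite.
`metrics_from_totals` computes the summary-level figures (TTR, unique
words per report) when only corpus totals are known, e.g. from a
published complexity table; note that for the published head-MRI row the
printed TTR (0.019) does not equal unique/total from the same row's
counts (≈ 0.0145) — the computation behind that printed value is
ambiguous, and this package uses M1/N throughout without attempting to
resolve the discrepancy.

## Numerical choices and degenerate inputs

* Masked softmax subtracts the row maximum and multiplies by the mask, so
  padding weight is exactly 0.0, not merely small.
* All-padding pooling masks, empty reports, single-class label vectors,
  out-of-vocabulary encoder ids, fraction vectors not summing to 1, and
  rater tables with unequal row sums raise typed errors rather than
  returning NaN.
* float64 everywhere; determinism contracts (same seed ⇒ identical
  corpus bytes, identical training history, identical inference) are
  tested, not assumed.
* Problem sizes used by the test suite and acceptance script — 2,000
  report corpora for the comparative experiment, 6,000 for calibration,
  500/250 for the learning-curve check, 4–5 training epochs at desk
  scale — were chosen as the smallest sizes at which the statistical
  assertions have comfortable margins.

## Known limitations

* No pretrained biomedical encoder weights are bundled; full-scale
  fine-tuning behaviour (catastrophic forgetting, 768-d embeddings) is
  represented by configuration, not reproduced.
* The baseline is the classical mean-embedding + N-gram recipe, not a
  line-by-line replication of any specific published pipeline.
* Granular-label co-occurrence is calibrated to marginal statistics only.
* The CLI trains and evaluates at desk scale; it is orchestration around
  the library, not a production service.
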