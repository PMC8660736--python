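# radlabel

Deriving image labels for large head-MRI datasets by classifying the
free-text neuroradiology reports that accompany them — and measuring, with
an honest protocol, how far such report-derived labels can be trusted.

Manually labelling tens of thousands of MRI examinations for computer
vision research is infeasible; the reports radiologists already wrote are
an untapped label source. The catch is that unstructured neuroradiology
prose is full of *distant negation* ("there is **no** convincing imaging
feature … in keeping with **acute infarction**"): a classifier built on
context-independent word statistics sees the finding lexicon but not the
faraway cue that negates it. `radlabel` implements and evaluates the
architecture that solves this, for the binary *abnormal* flag plus seven
specialised abnormality categories (acute stroke, mass, atrophy, vascular,
small vessel disease, white matter inflammation, encephalomalacia).

## The model

A report is lower-cased, tokenised to integer ids, and passed through a
contextual transformer encoder producing one d-dimensional vector per
token, h_i. A learned additive attention scorer

    u_i = v^T tanh(W h_i + b),    α = softmax(u) over non-padding tokens

pools the token vectors into a single report representation
r = Σ_i α_i h_i, and a fully connected network with one hidden layer maps
r to the probability that the report describes the category of interest.
One model is trained per category (eight in total), end-to-end on binary
cross-entropy with Adam, with per-epoch checkpoints and selection by
minimum validation loss. The attention weights α_i double as word-level
interpretability: `attention_report` returns (token, weight) pairs.

The shipped encoder is a compact randomly initialised transformer
(2 layers, d = 64, 4 heads); the package does not bundle pretrained
biomedical encoder weights — the architecture contract and the evaluation
machinery are the point, and both are scale-independent.

Around the model the package provides:

* **corpus** — a seeded generator of synthetic neuroradiology corpora
  (multi-style 5–10 sentence reports, distant negation, multiple reports
  per patient, calibrated label co-occurrence) plus simulated multi-rater
  annotation tables, since real hospital corpora cannot be redistributed;
* **baseline** — the classical comparator: mean static word embeddings +
  N-gram counts (N = 1, 2, 3) into logistic regression;
* **evaluation** — patient-level 60/20/20 splitting (no patient leakage),
  repeated splits with a fixed image-labelled hold-out, AUC-ROC as the
  Mann–Whitney statistic, DeLong tests (paired and unpaired), Fleiss'
  kappa, and t-SNE export of report embeddings;
* **lexical** — word-frequency spectra, type-token ratio and Yule's I;
* **cli / pipeline** — `radlabel generate | train | evaluate | label |
  lexstats | agreement`, with streaming batch label assignment.

## Worked example

```python
from radlabel.corpus import GeneratorConfig, generate_corpus, to_frame
from radlabel.evaluation import patient_level_split, roc_auc
from radlabel.training import desk_hyperparams, train_model
from radlabel.baseline import BaselineClassifier

frame = to_frame(*generate_corpus(
    GeneratorConfig(n_reports=2000, distant_negation_rate=0.4, seed=11)))
parts = patient_level_split(frame, seed=0).apply(frame)
tr, va, te = parts["train"], parts["val"], parts["test"]

model, history = train_model(tr, va, "abnormal", desk_hyperparams(max_epochs=4))
ctx = roc_auc(model.predict_proba(te["text"].tolist()), te["abnormal"])

base = BaselineClassifier(embedding_mode="random").fit(
    tr["text"].tolist(), tr["abnormal"])
bow = roc_auc(base.predict_proba(te["text"].tolist()), te["abnormal"])
print(f"contextual AUC {ctx:.4f}  bag-of-words AUC {bow:.4f}")
```

On this corpus — ~40 % of reports carry a distantly negated finding —
this prints

```
contextual AUC 1.0000  bag-of-words AUC 0.9913
```

the attention classifier resolves the long-range polarity cues that the
context-independent baseline cannot, which is exactly the gap the
architecture exists to close. Word-level attribution for a single report:

```python
from radlabel.model import attention_report
for token, weight in attention_report(te["text"].iloc[0], model):
    print(f"{weight:.3f}  {token}")
```

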