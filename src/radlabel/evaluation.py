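"""Patient-level evaluation protocol and statistics.

Splitting is performed at the patient level so that no patient contributes
reports to more than one of train/validation/test — preventing data
leakage — while an image-labelled hold-out set stays fixed across
repeated splits. AUC-ROC is computed as the Mann-Whitney statistic (ties
credited one half); paired and unpaired AUC differences are tested with
DeLong's method via the structural components of the Mann-Whitney
statistic; inter-rater agreement uses Fleiss' kappa.

Confidence intervals across repeated splits are reported as
``mean +/- 1.96 * sd / sqrt(n_repeats)`` (normal approximation); whether
printed "+/-" values in the field are SDs, SEs or CI half-widths is
ambiguous, so the choice is recorded in the output metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .training import LeakageError, desk_hyperparams, train_model

__all__ = [
    "SplitSpec", "MetricsSummary",
    "UndefinedAUCError", "DegenerateVarianceError", "UndefinedKappaError",
    "patient_level_split", "roc_auc", "classification_metrics",
    "delong_test", "repeated_evaluation", "fleiss_kappa",
    "export_2d_embeddings", "flip_labels",
]

CI_DEFINITION = "mean +/- 1.96*sd/sqrt(n_repeats) (normal approximation)"


class UndefinedAUCError(ValueError):
    """AUC requested with a single class present."""


class DegenerateVarianceError(ValueError):
    """DeLong variance estimate is zero while the AUCs differ."""


class UndefinedKappaError(ValueError):
    """Fleiss' kappa undefined: all ratings fall in one category."""


# -- patient-level splitting -------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Exhaustive, disjoint assignment of patients to
    train/val/test/excluded."""

    assignment: dict
    fractions: tuple
    seed: int

    def bucket(self, patient_id):
        return self.assignment[patient_id]

    def patients(self, bucket):
        return [p for p, b in self.assignment.items() if b == bucket]

    def apply(self, frame):
        """Partition a report table; every report inherits its patient's
        bucket."""
        buckets = frame["patient_id"].map(self.assignment)
        if buckets.isna().any():
            missing = frame.loc[buckets.isna(), "patient_id"].unique()
            raise ValueError(f"patients missing from split: {missing[:5]}")
        return {
            b: frame.loc[buckets == b].reset_index(drop=True)
            for b in ("train", "val", "test", "excluded")
        }


def patient_level_split(frame, fractions=(0.6, 0.2, 0.2), holdout_patients=(),
                        seed=0):
    """Assign every patient to train/val/test (or excluded, for hold-out
    patients); report-count fractions match the targets within one patient
    group."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three numbers summing to 1")
    holdout = set(holdout_patients)
    counts = frame.groupby("patient_id", sort=True).size()
    unknown = holdout - set(counts.index)
    if unknown:
        raise ValueError(f"holdout patients not in corpus: {sorted(unknown)[:5]}")
    eligible = [p for p in counts.index if p not in holdout]
    rng = np.random.default_rng(seed)
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    total = int(counts.loc[eligible].sum())
    t_train = fractions[0] * total
    t_val = (fractions[0] + fractions[1]) * total
    assignment = {p: "excluded" for p in holdout}
    cum = 0
    for p in order:
        if cum < t_train:
            assignment[p] = "train"
        elif cum < t_val:
            assignment[p] = "val"
        else:
            assignment[p] = "test"
        cum += int(counts[p])
    return SplitSpec(assignment=assignment, fractions=fractions, seed=seed)


# -- threshold metrics and AUC -----------------------------------------------


def _check_two_classes(labels):
    y = np.asarray(labels).astype(int)
    if y.size == 0 or y.min() == y.max():
        raise UndefinedAUCError("both classes must be present")
    return y


def roc_auc(scores, labels):
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 * P(tie)."""
    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    ranks = rankdata(s)
    m = int(y.sum())
    n = y.size - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def classification_metrics(scores, labels, threshold=0.5):
    """Sensitivity, specificity, balanced accuracy and F1 at a threshold."""
    y = _check_two_classes(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": 0.5 * (sens + spec),
        "f1": f1,
    }


def youden_threshold(scores, labels):
    """Operating point maximising sensitivity + specificity - 1 (choose on
    validation data only)."""
    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    cuts = np.unique(s)
    best_t, best_j = 0.5, -np.inf
    for t in cuts:
        m = classification_metrics(s, y, threshold=t)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


# -- DeLong test -------------------------------------------------------------


def _structural_components(scores, y):
    """AUC plus per-positive (V10) and per-negative (V01) structural
    components of the Mann-Whitney statistic."""
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _variance_single(v10, v01):
    var10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    var01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return var10 / v10.size + var01 / v01.size


def delong_test(scores_a, scores_b, labels, labels_b=None, mode="paired"):
    """DeLong comparison of two AUCs; returns ``(delta_auc, z, p)``.

    ``paired``: both score vectors grade the same cases (``labels``);
    the variance of the difference uses the covariance of the structural
    components. ``unpaired``: independent test sets; pass the second set's
    labels as ``labels_b``; variances add.
    """
    if mode == "paired":
        y = _check_two_classes(labels)
        a_auc, a10, a01 = _structural_components(scores_a, y)
        b_auc, b10, b01 = _structural_components(scores_b, y)
        m, n = a10.size, a01.size
        if m > 1:
            s10 = np.cov(np.vstack([a10, b10]), ddof=1)
        else:
            s10 = np.zeros((2, 2))
        if n > 1:
            s01 = np.cov(np.vstack([a01, b01]), ddof=1)
        else:
            s01 = np.zeros((2, 2))
        var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
               + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    elif mode == "unpaired":
        if labels_b is None:
            raise ValueError("unpaired mode requires labels_b")
        ya = _check_two_classes(labels)
        yb = _check_two_classes(labels_b)
        a_auc, a10, a01 = _structural_components(scores_a, ya)
        b_auc, b10, b01 = _structural_components(scores_b, yb)
        var = _variance_single(a10, a01) + _variance_single(b10, b01)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    delta = a_auc - b_auc
    if var <= 0:
        if abs(delta) < 1e-12:
            return 0.0, 0.0, 1.0
        raise DegenerateVarianceError(
            "zero variance estimate with unequal AUCs")
    z = delta / np.sqrt(var)
    p = float(min(2 * norm.sf(abs(z)), 1.0))
    return float(delta), float(z), p


# -- repeated evaluation -----------------------------------------------------


@dataclass
class MetricsSummary:
    """Per-repeat metrics with mean and 95% CI half-width for each."""

    per_repeat: pd.DataFrame
    n_repeats: int
    ci_definition: str = CI_DEFINITION
    threshold: float = 0.5

    METRICS = ("auc", "balanced_accuracy", "sensitivity", "specificity", "f1")

    def mean(self, metric):
        return float(self.per_repeat[metric].mean())

    def ci_half_width(self, metric):
        if self.n_repeats < 2:
            return float("nan")  # spread undefined for a single repeat
        sd = float(self.per_repeat[metric].std(ddof=1))
        return 1.96 * sd / np.sqrt(self.n_repeats)

    def summary_frame(self):
        rows = [
            {"metric": m, "mean": self.mean(m),
             "ci_half_width": self.ci_half_width(m)}
            for m in self.METRICS
        ]
        return pd.DataFrame(rows)

    def to_json(self):
        return json.dumps({
            "n_repeats": self.n_repeats,
            "ci_definition": self.ci_definition,
            "threshold": self.threshold,
            "metrics": {
                m: {"mean": self.mean(m), "ci_half_width": self.ci_half_width(m)}
                for m in self.METRICS
            },
        })

    def to_csv(self, path):
        per = self.per_repeat.copy()
        summary = self.summary_frame().set_index("metric")
        row = {"repeat": "mean"}
        row.update({m: summary.loc[m, "mean"] for m in self.METRICS})
        per = pd.concat([per, pd.DataFrame([row])], ignore_index=True)
        per.to_csv(path, index=False)


def _default_train_fn(train_frame, val_frame, category, hp, seed):
    hp = hp or desk_hyperparams()
    hp = type(hp)(learning_rate=hp.learning_rate, batch_size=hp.batch_size,
                  max_epochs=hp.max_epochs, seed=seed)
    model, _ = train_model(train_frame, val_frame, category, hp)
    return model


def _score_frame(model, frame, category, threshold):
    scores = model.predict_proba(frame["text"].tolist())
    y = frame[category].to_numpy(dtype=int)
    out = {"auc": roc_auc(scores, y)}
    out.update(classification_metrics(scores, y, threshold=threshold))
    return out


def repeated_evaluation(corpus_frame, category, holdout_frame, *, hp=None,
                        n_repeats=10, seed=0, train_fn=None, threshold=0.5):
    """Repeat the patient-level split ``n_repeats`` times, train a model
    per split, and evaluate on (i) that split's report-label test set and
    (ii) the fixed image-label hold-out.

    ``train_fn(train_frame, val_frame, category, hp, seed) -> model`` may
    replace the default end-to-end training (e.g. for protocol tests with
    a cheap classifier). Returns a dict with ``report`` and ``image``
    :class:`MetricsSummary` plus the hold-out identity check.
    """
    overlap = set(corpus_frame["patient_id"]) & set(holdout_frame["patient_id"])
    if overlap:
        raise LeakageError(
            f"hold-out shares patients with the corpus: {sorted(overlap)[:5]}")
    train_fn = train_fn or _default_train_fn
    holdout_ids = tuple(holdout_frame["report_id"]) if "report_id" in holdout_frame \
        else tuple(holdout_frame.index)
    rows_report, rows_image = [], []
    for r in range(n_repeats):
        split_seed = (seed * 1009 + r) % (2 ** 31)
        spec = patient_level_split(corpus_frame, seed=split_seed)
        parts = spec.apply(corpus_frame)
        model = train_fn(parts["train"], parts["val"], category, hp, split_seed)
        rows_report.append({"repeat": r, **_score_frame(model, parts["test"],
                                                        category, threshold)})
        rows_image.append({"repeat": r, **_score_frame(model, holdout_frame,
                                                       category, threshold)})
    return {
        "report": MetricsSummary(pd.DataFrame(rows_report), n_repeats,
                                 threshold=threshold),
        "image": MetricsSummary(pd.DataFrame(rows_image), n_repeats,
                                threshold=threshold),
        "holdout_report_ids": holdout_ids,
    }


def flip_labels(labels, rate, seed=0):
    """Corrupt binary labels by independent flips at ``rate`` (models
    report/image label disagreement)."""
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    flips = rng.random(y.size) < rate
    return np.where(flips, 1 - y, y)


# -- inter-rater agreement ---------------------------------------------------


def fleiss_kappa(matrix):
    """Fleiss' kappa for an N subjects x k categories count table.

    kappa = (P_bar - P_e) / (1 - P_e) with
    P_i = (sum_j n_ij^2 - r) / (r (r - 1)), p_j = sum_i n_ij / (N r),
    P_e = sum_j p_j^2.
    """
    counts = np.asarray(getattr(matrix, "counts", matrix), dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 categories")
    r = counts.sum(axis=1)
    if not np.all(r == r[0]) or r[0] < 2:
        raise ValueError("every subject needs the same number (>= 2) of raters")
    r = float(r[0])
    n_subjects = counts.shape[0]
    p_i = ((counts ** 2).sum(axis=1) - r) / (r * (r - 1))
    p_j = counts.sum(axis=0) / (n_subjects * r)
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0 - 1e-12:
        raise UndefinedKappaError("all ratings fall in a single category")
    return float((p_i.mean() - p_e) / (1.0 - p_e))


# -- 2-D embedding export ----------------------------------------------------


def export_2d_embeddings(vectors, labels, seed=0, perplexity=None):
    """t-SNE projection of pooled report vectors to a plottable table.

    The reduction itself is delegated to scikit-learn; this operation owns
    the contract (one 2-D point per report, seed determinism).
    """
    from sklearn.manifold import TSNE

    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 vectors")
    # identical inputs must land on identical points; t-SNE breaks such
    # ties arbitrarily, so project unique rows only
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    nu = uniq.shape[0]
    if nu < 3:
        centred = uniq - uniq.mean(axis=0)
        u, s, _ = np.linalg.svd(centred, full_matrices=False)
        pts_u = np.zeros((nu, 2))
        pts_u[:, : min(2, s.size)] = (u * s)[:, : min(2, s.size)]
    else:
        if perplexity is None:
            perplexity = min(30.0, max(1.5, (nu - 1) / 3.0))
        tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                    init="pca")
        pts_u = tsne.fit_transform(uniq)
    pts = pts_u[inverse]
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1],
                         "label": np.asarray(labels)})
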