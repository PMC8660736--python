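"""Synthetic neuroradiology report corpus generator.

Real hospital report corpora cannot be redistributed, so this module
fabricates corpora with the statistical and linguistic structure the
classifier and the evaluation statistics assume: 5-10 sentence unstructured
reports in several reporter styles, optional protocol/clinical-history
sentences, findings described positively (sometimes hedged) or negated at a
distance from the polarity cue, eight binary labels (abnormal plus seven
specialised abnormality categories), several reports per patient, and an
average of more than one specialised label per abnormal report.

Everything is driven by a single :class:`GeneratorConfig` and a seed; the
same configuration always yields a byte-identical corpus.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import templates as T

__all__ = [
    "Report",
    "LabelSet",
    "GeneratorConfig",
    "RaterMatrix",
    "ConfigError",
    "generate_corpus",
    "generate_rater_annotations",
    "to_frame",
    "write_jsonl",
    "read_jsonl",
    "write_csv",
    "read_csv",
]

CATEGORIES = T.CATEGORIES
ALL_LABELS = T.ALL_LABELS

#: Granular selection weights proportional to the published category counts
#: in the 2,000-report specialised-label dataset.
DEFAULT_GRANULAR_WEIGHTS = {
    "small_vessel_disease": 266,
    "acute_stroke": 251,
    "mass": 351,
    "vascular": 287,
    "white_matter_inflammation": 257,
    "atrophy": 264,
    "encephalomalacia": 384,
}

#: Abnormal prevalence of the 3,000-report binary dataset (1152/3000).
DEFAULT_ABNORMAL_PREVALENCE = 1152 / 3000

MAX_GRANULAR_PER_REPORT = 5
MAX_REPORTS_PER_PATIENT = 6


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class Report:
    """One free-text report with patient linkage and provenance.

    ``negated`` records the categories whose finding lexicon appears inside
    a negation frame — generator ground truth used to audit
    negation soundness; it is not available for real reports.
    """

    report_id: str
    patient_id: str
    site_id: str
    style_id: int
    text: str
    negated: tuple = ()


@dataclass(frozen=True)
class LabelSet:
    """Eight binary labels for one report.

    ``granular`` maps each of the seven specialised categories to a bool;
    any true granular flag implies ``abnormal``. ``provenance`` records how
    the labels arose: report-derived, image-derived, consensus or predicted.
    """

    abnormal: bool
    granular: tuple  # tuple of (category, bool) pairs, fixed order
    provenance: str = "report"

    def __post_init__(self):
        if self.provenance not in ("report", "image", "consensus", "predicted"):
            raise ConfigError(f"unknown provenance {self.provenance!r}")
        if any(v for _, v in self.granular) and not self.abnormal:
            raise ConfigError("granular label set requires abnormal=True")

    def granular_dict(self):
        return dict(self.granular)

    def as_row(self):
        row = {"abnormal": int(self.abnormal)}
        row.update({c: int(v) for c, v in self.granular})
        row["provenance"] = self.provenance
        return row


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``granular_prevalence`` holds relative selection weights for the seven
    categories; an abnormal report receives ``1 + Poisson(mean - 1)``
    distinct categories (truncated at 5) drawn without replacement with
    these weights, so the implied marginal prevalence of category *c* is
    ``abnormal_prevalence * sum_k P(K=k) * inclusion(c, k)`` — exposed as
    :meth:`expected_prevalence`.
    """

    n_reports: int
    n_patients: int | None = None
    abnormal_prevalence: float = DEFAULT_ABNORMAL_PREVALENCE
    granular_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_GRANULAR_WEIGHTS)
    )
    distant_negation_rate: float = 0.3
    hedging_rate: float = 0.15
    n_styles: int = 3
    mean_granular_per_abnormal: float = 1.56
    site_id: str = "site_a"
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if not 0.0 <= self.abnormal_prevalence <= 1.0:
            raise ConfigError("abnormal_prevalence must lie in [0, 1]")
        for rate in (self.distant_negation_rate, self.hedging_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if set(self.granular_prevalence) != set(CATEGORIES):
            raise ConfigError("granular_prevalence must cover all 7 categories")
        if any(w < 0 for w in self.granular_prevalence.values()):
            raise ConfigError("granular weights must be non-negative")
        if self.mean_granular_per_abnormal < 1.0:
            raise ConfigError("mean_granular_per_abnormal must be >= 1")
        if self.n_styles < 1:
            raise ConfigError("n_styles must be >= 1")
        if self.n_patients is not None:
            if self.n_patients > self.n_reports and self.n_reports > 0:
                raise ConfigError("n_patients must be <= n_reports")
            if self.n_reports > MAX_REPORTS_PER_PATIENT * max(self.n_patients, 1):
                raise ConfigError("too few patients for the per-patient cap")

    # -- implied prevalence -------------------------------------------------

    def _count_pmf(self):
        """P(K = k) for K = min(1 + Poisson(mean-1), 5), k = 1..5."""
        lam = self.mean_granular_per_abnormal - 1.0
        pmf = {}
        for k in range(1, MAX_GRANULAR_PER_REPORT):
            pmf[k] = math.exp(-lam) * lam ** (k - 1) / math.factorial(k - 1)
        pmf[MAX_GRANULAR_PER_REPORT] = 1.0 - sum(pmf.values())
        return pmf

    def expected_prevalence(self, category):
        """Exact marginal prevalence implied by the configuration."""
        if category == "abnormal":
            return self.abnormal_prevalence
        weights = [self.granular_prevalence[c] for c in CATEGORIES]
        idx = CATEGORIES.index(category)
        pmf = self._count_pmf()
        cond = sum(p * _inclusion_probability(weights, k)[idx] for k, p in pmf.items())
        return self.abnormal_prevalence * cond


def _inclusion_probability(weights, k):
    """P(category i among k successive weighted draws w/o replacement).

    Dynamic programme over chosen subsets; 2^7 states, exact.
    """
    n = len(weights)
    total = float(sum(weights))
    if total <= 0:
        raise ConfigError("at least one granular weight must be positive")
    probs = {frozenset(): 1.0}
    for _ in range(k):
        nxt = {}
        for chosen, p in probs.items():
            rem = total - sum(weights[i] for i in chosen)
            for i in range(n):
                if i in chosen or weights[i] == 0:
                    continue
                key = chosen | {i}
                nxt[key] = nxt.get(key, 0.0) + p * weights[i] / rem
        probs = nxt
    incl = [0.0] * n
    for chosen, p in probs.items():
        for i in chosen:
            incl[i] += p
    return incl


# -- text assembly ----------------------------------------------------------


def _style_pool(seq, style_id):
    """Rotated, truncated view of a template tuple: styles overlap but
    favour different phrasings."""
    off = style_id % len(seq)
    rotated = seq[off:] + seq[:off]
    keep = max(3, len(seq) - 1)
    return rotated[:keep]


def _pick(rng, seq):
    return seq[int(rng.integers(len(seq)))]


def _sentence_case(rng, sentence):
    if rng.random() < 0.8:
        return sentence[0].upper() + sentence[1:]
    return sentence


def _draw_mention_template(rng, style_id):
    """One (opener, modifiers, connector) phrasing, drawn per report and
    shared by every mention in it — reporters phrase consistently within a
    report, and the shared phrasing means a bag of short n-grams cannot
    attribute a determiner to a particular finding."""
    return (
        _pick(rng, _style_pool(T.OPENERS, style_id)),
        _pick(rng, T.MOD1),
        _pick(rng, T.MOD2),
        _pick(rng, T.MOD3),
        _pick(rng, T.CONNECTORS),
    )


def _mention_sentence(rng, tmpl, finding, polarity, hedged=False):
    """One finding mention: {opener} {det} {m1} {m2} {m3} {connector}
    {finding}. The determiner carries the polarity and sits >= 4 tokens
    upstream of the finding lexicon (distant negation when 'no')."""
    opener, m1, m2, m3, connector = tmpl
    det = "a" if polarity else "no"
    hedge = f"{_pick(rng, T.HEDGES)} " if hedged else ""
    return f"{opener} {hedge}{det} {m1} {m2} {m3} {connector} {finding}."


def _compose_report(rng, style_id, positive, negated, hedging_rate):
    sentences = []
    if rng.random() < 0.5:
        block = T.PROTOCOL_SENTENCES if rng.random() < 0.5 else T.HISTORY_SENTENCES
        sentences.append(_pick(rng, block))
    tmpl = _draw_mention_template(rng, style_id)
    for cat in positive:
        hedged = rng.random() < hedging_rate
        finding = _pick(rng, T.FINDING_PHRASES[cat])
        sentences.append(_mention_sentence(rng, tmpl, finding, True, hedged))
    for cat in negated:
        finding = _pick(rng, T.FINDING_PHRASES[cat])
        sentences.append(_mention_sentence(rng, tmpl, finding, False))
    # benign findings, asserted or negated, in both classes
    if rng.random() < 0.6:
        hedged = rng.random() < hedging_rate
        benign = _pick(rng, T.BENIGN_FINDING_PHRASES)
        sentences.append(_mention_sentence(rng, tmpl, benign, True, hedged))
    if rng.random() < 0.3:
        benign = _pick(rng, T.BENIGN_FINDING_PHRASES)
        sentences.append(_mention_sentence(rng, tmpl, benign, False))
    for _ in range(int(rng.binomial(2, 0.35))):
        sentences.append(_pick(rng, T.NEUTRAL_DET_SENTENCES))
    if positive:
        if rng.random() < 0.3:
            sentences.append(_pick(rng, T.REASSURANCE_STATEMENTS))
    elif rng.random() < 0.6:
        sentences.append(_pick(rng, T.NORMAL_STATEMENTS))
    target = int(rng.integers(5, 11))
    fillers = list(T.FILLER_SENTENCES)
    while len(sentences) + 1 < target and fillers:
        fillers_idx = int(rng.integers(len(fillers)))
        sentences.append(fillers.pop(fillers_idx))
    sentences.append(_pick(rng, _style_pool(T.CONCLUSION_SENTENCES, style_id)))
    return " ".join(_sentence_case(rng, s) for s in sentences)


def _patient_sizes(rng, n_reports, n_patients):
    """Reports-per-patient ~ 1 + Geometric(0.5), capped, so patient-level
    splitting is non-trivial."""
    if n_reports == 0:
        return []
    if n_patients is None:
        sizes = []
        covered = 0
        while covered < n_reports:
            s = int(rng.geometric(0.5))  # support {1, 2, ...}
            s = min(s, MAX_REPORTS_PER_PATIENT, n_reports - covered)
            sizes.append(s)
            covered += s
        return sizes
    sizes = [1] * n_patients
    spare = n_reports - n_patients
    while spare > 0:
        i = int(rng.integers(n_patients))
        if sizes[i] < MAX_REPORTS_PER_PATIENT:
            sizes[i] += 1
            spare -= 1
    return sizes


def generate_corpus(config):
    """Generate ``(reports, labels)`` under ``config``.

    Returns parallel lists of :class:`Report` and :class:`LabelSet`. Same
    config (including seed) gives identical output.
    """
    if not isinstance(config, GeneratorConfig):
        raise ConfigError("config must be a GeneratorConfig")
    rng = np.random.default_rng(config.seed)
    sizes = _patient_sizes(rng, config.n_reports, config.n_patients)
    weights = np.asarray(
        [config.granular_prevalence[c] for c in CATEGORIES], dtype=float
    )
    if weights.sum() <= 0:
        raise ConfigError("at least one granular weight must be positive")
    lam = config.mean_granular_per_abnormal - 1.0

    reports, labels = [], []
    ridx = 0
    for pidx, size in enumerate(sizes):
        patient_id = f"p{pidx:05d}"
        style_id = int(rng.integers(config.n_styles))
        for _ in range(size):
            abnormal = bool(rng.random() < config.abnormal_prevalence)
            positive = []
            if abnormal:
                k = 1 + int(rng.poisson(lam)) if lam > 0 else 1
                k = min(k, MAX_GRANULAR_PER_REPORT)
                w = weights.copy()
                for _ in range(k):
                    p = w / w.sum()
                    j = int(rng.choice(len(CATEGORIES), p=p))
                    positive.append(CATEGORIES[j])
                    w[j] = 0.0
            negated = []
            if rng.random() < config.distant_negation_rate:
                candidates = [c for c in CATEGORIES if c not in positive]
                n_neg = 1 + int(rng.random() < 0.4)
                for _ in range(min(n_neg, len(candidates))):
                    j = int(rng.integers(len(candidates)))
                    negated.append(candidates.pop(j))
            text = _compose_report(
                rng, style_id, positive, negated, config.hedging_rate
            )
            reports.append(
                Report(
                    report_id=f"r{ridx:06d}",
                    patient_id=patient_id,
                    site_id=config.site_id,
                    style_id=style_id,
                    text=text,
                    negated=tuple(negated),
                )
            )
            labels.append(
                LabelSet(
                    abnormal=abnormal,
                    granular=tuple((c, c in positive) for c in CATEGORIES),
                    provenance="report",
                )
            )
            ridx += 1
    return reports, labels


# -- multi-rater annotation tables ------------------------------------------


@dataclass(frozen=True)
class RaterMatrix:
    """Subjects x categories table of rating counts, each row summing to
    the (fixed) number of raters."""

    counts: np.ndarray
    n_raters: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ConfigError("counts must be 2-D")
        if (counts < 0).any():
            raise ConfigError("counts must be non-negative")
        if not (counts.sum(axis=1) == self.n_raters).all():
            raise ConfigError("every row must sum to n_raters")


def generate_rater_annotations(labels, n_raters, disagreement_rate, seed):
    """Simulate independent raters over the subjects in ``labels``.

    Each rater reports the subject's true category (normal=0 / abnormal=1
    when given :class:`LabelSet` objects, or integer categories directly)
    with probability ``1 - disagreement_rate``, otherwise a uniform draw
    over all categories.
    """
    if n_raters < 2:
        raise ConfigError("n_raters must be >= 2")
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ConfigError("disagreement_rate must lie in [0, 1]")
    truth = np.asarray(
        [int(s.abnormal) if isinstance(s, LabelSet) else int(s) for s in labels]
    )
    if truth.size == 0:
        raise ConfigError("need at least one subject")
    k = max(int(truth.max()) + 1, 2)
    rng = np.random.default_rng(seed)
    n = truth.size
    counts = np.zeros((n, k), dtype=int)
    for _ in range(n_raters):
        deviate = rng.random(n) < disagreement_rate
        rated = np.where(deviate, rng.integers(0, k, size=n), truth)
        np.add.at(counts, (np.arange(n), rated), 1)
    return RaterMatrix(counts=counts, n_raters=n_raters)


# -- serialisation ----------------------------------------------------------


def to_frame(reports, labels):
    """Canonical tabular view: one row per report, label columns as 0/1."""
    rows = []
    for rep, lab in zip(reports, labels, strict=True):
        row = {
            "report_id": rep.report_id,
            "patient_id": rep.patient_id,
            "site_id": rep.site_id,
            "style_id": rep.style_id,
            "text": rep.text,
            "negated": ";".join(rep.negated),
        }
        row.update(lab.as_row())
        rows.append(row)
    columns = [
        "report_id", "patient_id", "site_id", "style_id", "text", "negated",
        "abnormal", *CATEGORIES, "provenance",
    ]
    return pd.DataFrame(rows, columns=columns)


def from_frame(frame):
    """Inverse of :func:`to_frame`."""
    reports, labels = [], []
    for row in frame.itertuples(index=False):
        negated = tuple(x for x in str(getattr(row, "negated", "") or "").split(";") if x)
        reports.append(
            Report(
                report_id=str(row.report_id),
                patient_id=str(row.patient_id),
                site_id=str(getattr(row, "site_id", "")),
                style_id=int(getattr(row, "style_id", 0)),
                text=str(row.text),
                negated=negated,
            )
        )
        labels.append(
            LabelSet(
                abnormal=bool(int(row.abnormal)),
                granular=tuple((c, bool(int(getattr(row, c)))) for c in CATEGORIES),
                provenance=str(getattr(row, "provenance", "report")),
            )
        )
    return reports, labels


def write_jsonl(path, reports, labels):
    with open(path, "w", encoding="utf-8") as fh:
        for rep, lab in zip(reports, labels, strict=True):
            obj = dataclasses.asdict(rep)
            obj["negated"] = list(rep.negated)
            obj["labels"] = lab.as_row()
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_jsonl(path):
    reports, labels = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            lab = obj.pop("labels")
            obj["negated"] = tuple(obj.get("negated", ()))
            reports.append(Report(**obj))
            labels.append(
                LabelSet(
                    abnormal=bool(lab["abnormal"]),
                    granular=tuple((c, bool(lab[c])) for c in CATEGORIES),
                    provenance=lab.get("provenance", "report"),
                )
            )
    return reports, labels


def write_csv(path, reports, labels):
    to_frame(reports, labels).to_csv(path, index=False, encoding="utf-8")


def read_csv(path):
    return from_frame(pd.read_csv(path, encoding="utf-8", keep_default_na=False))
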