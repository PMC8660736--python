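"""Corpus lexical-complexity statistics.

A corpus is summarised by its word-frequency spectrum V(i) — the number of
word types occurring exactly i times — from which the type-token ratio
(TTR = M1 / N), Yule's I = M1^2 / (M2 - M1) (the inverse of Yule's
characteristic K up to the 10^4 factor), and unique words per report are
derived. "Word" here means a lower-cased, punctuation-stripped whitespace
token, independent of the model tokenizer. Yule's I is larger for richer
(less repetitive) vocabularies; an all-singleton corpus drives M2 -> M1
and the statistic to infinity, reported as ``inf``.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FrequencySpectrum", "frequency_spectrum", "lexical_metrics",
    "metrics_from_totals", "lexical_words", "summary_frame",
]

_LEX_WORD_RE = re.compile(r"[a-z0-9']+")


def lexical_words(text):
    return _LEX_WORD_RE.findall(str(text).lower())


@dataclass(frozen=True)
class FrequencySpectrum:
    """V maps occurrence count i -> number of types with that count.

    M1 = total types, N_tokens = total tokens, M2 = sum_i i^2 V(i).
    """

    V: dict
    n_reports: int

    def __post_init__(self):
        for i, v in self.V.items():
            if i < 1 or v < 1 or i != int(i) or v != int(v):
                raise ValueError("spectrum entries must be positive integers")

    @property
    def M1(self):
        return sum(self.V.values())

    @property
    def N_tokens(self):
        return sum(i * v for i, v in self.V.items())

    @property
    def M2(self):
        return sum(i * i * v for i, v in self.V.items())


def frequency_spectrum(corpus):
    """Word-frequency spectrum of a corpus of reports (or raw strings)."""
    texts = [getattr(r, "text", r) for r in corpus]
    if not texts:
        raise ValueError("corpus must be non-empty")
    counts = Counter()
    for t in texts:
        counts.update(lexical_words(t))
    if not counts:
        raise ValueError("corpus contains no words")
    spectrum = Counter(counts.values())
    return FrequencySpectrum(V=dict(spectrum), n_reports=len(texts))


def lexical_metrics(spectrum):
    """TTR, Yule's I and unique words per report from a spectrum."""
    m1, m2, n = spectrum.M1, spectrum.M2, spectrum.N_tokens
    yule_i = math.inf if m2 == m1 else m1 * m1 / (m2 - m1)
    return {
        "ttr": m1 / n,
        "yule_i": yule_i,
        "unique_per_report": m1 / spectrum.n_reports,
    }


def metrics_from_totals(n_reports, total_words, unique_words):
    """Summary-level metrics when only corpus totals are known (e.g. from
    a published corpus-complexity table): TTR and unique words per report;
    Yule's I needs the full spectrum and is not computable from totals."""
    if n_reports < 1 or total_words < 1 or unique_words < 1:
        raise ValueError("totals must be positive")
    if unique_words > total_words:
        raise ValueError("unique words cannot exceed total words")
    return {
        "ttr": unique_words / total_words,
        "unique_per_report": unique_words / n_reports,
    }


def summary_frame(name, spectrum):
    """One-row corpus-complexity table (CSV-friendly)."""
    m = lexical_metrics(spectrum)
    return pd.DataFrame([{
        "corpus": name,
        "n_reports": spectrum.n_reports,
        "total_words": spectrum.N_tokens,
        "unique_words": spectrum.M1,
        "yule_i": m["yule_i"],
        "ttr": m["ttr"],
        "unique_per_report": m["unique_per_report"],
    }])
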