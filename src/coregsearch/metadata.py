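"""Text mining over sample and dataset metadata.

Two analyses are provided. At the dataset level, the per-sample query profile
(average expression of the query genes) is correlated against binary
word-presence vectors built from each sample's free-text metadata
(point-biserial / Pearson correlation). At the ranking level, terms extracted
from dataset descriptions are tested for overrepresentation among the
top-ranked datasets with a one-sided Fisher exact test, followed by
Benjamini-Hochberg adjustment.

Term extraction is a deliberately simple unigram + adjacent-bigram scheme; the
term list passed to :func:`term_enrichment` is pluggable so curated terms can
be supplied instead.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.stats import hypergeom

from ._stopwords import STOPWORDS

__all__ = [
    "WordCorrelation",
    "WordCorrelationResult",
    "TermEnrichmentRow",
    "tokenize",
    "correlate_words",
    "extract_terms",
    "fisher_one_sided",
    "term_enrichment",
    "bh_adjust",
]

_MIN_TOKEN_LEN = 3
_SEGMENT_SPLIT = re.compile(r"[^\w\s]+")
_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")


def tokenize(text: str) -> set[str]:
    """Bag-of-words tokenization of free metadata text.

    Lowercases, splits on non-alphanumeric characters, drops tokens shorter
    than three characters and tokens on the built-in stopword list, and
    deduplicates.
    """
    tokens = _TOKEN_SPLIT.split(text.lower())
    return {t for t in tokens if len(t) >= _MIN_TOKEN_LEN and t not in STOPWORDS}


def _token_runs(text: str) -> list[list[str]]:
    """Ordered kept-token runs; punctuation and dropped tokens break a run."""
    runs: list[list[str]] = []
    for segment in _SEGMENT_SPLIT.split(text.lower()):
        run: list[str] = []
        for raw in _TOKEN_SPLIT.split(segment):
            if len(raw) >= _MIN_TOKEN_LEN and raw not in STOPWORDS:
                run.append(raw)
            elif run:
                runs.append(run)
                run = []
        if run:
            runs.append(run)
    return runs


def extract_terms(text: str) -> set[str]:
    """Extract candidate terms (unigrams plus adjacent bigrams) from text.

    Bigrams are formed only between tokens that are adjacent in the original
    word sequence: punctuation and dropped tokens (stopwords, short tokens)
    break adjacency.
    """
    terms: set[str] = set()
    for run in _token_runs(text):
        terms.update(run)
        terms.update(f"{a} {b}" for a, b in zip(run, run[1:]))
    return terms


@dataclass(frozen=True)
class WordCorrelation:
    """A metadata word with its profile correlation and sample support."""

    word: str
    r: float
    n_present: int


class WordCorrelationResult(NamedTuple):
    positive: list[WordCorrelation]
    negative: list[WordCorrelation]
    constant_profile: bool


def correlate_words(
    profile: np.ndarray,
    sample_words: Sequence[Iterable[str]],
    top_n_words: int = 10,
) -> WordCorrelationResult:
    """Correlate the query profile with per-sample word presence.

    For every word present in at least 2 and at most ``m - 2`` samples, the
    Pearson correlation between ``profile`` and the binary presence vector is
    computed (the point-biserial correlation). The ``top_n_words`` most
    positively and most negatively correlated words are returned.

    A constant profile has no defined correlation: both lists are empty and
    ``constant_profile`` is set.
    """
    profile = np.asarray(profile, dtype=float)
    m = profile.size
    if m < 4:
        raise ValueError("need at least 4 samples for word correlation")
    if len(sample_words) != m:
        raise ValueError("sample_words length must match profile length")

    centered = profile - profile.mean()
    denom_profile = float(np.sqrt((centered**2).sum()))
    if denom_profile <= 1e-12 * max(1.0, float(np.abs(profile).max())):
        return WordCorrelationResult([], [], True)

    counts: dict[str, list[int]] = {}
    for j, words in enumerate(sample_words):
        for w in set(words):
            counts.setdefault(w, []).append(j)

    rows: list[WordCorrelation] = []
    for word, present in counts.items():
        n_present = len(present)
        if n_present < 2 or n_present > m - 2:
            continue
        x = np.zeros(m)
        x[present] = 1.0
        xc = x - x.mean()
        r = float(xc @ centered / (np.sqrt((xc**2).sum()) * denom_profile))
        rows.append(WordCorrelation(word=word, r=r, n_present=n_present))

    rows.sort(key=lambda wc: (-wc.r, wc.word))
    positive = [wc for wc in rows[:top_n_words] if wc.r > 0]
    rows_neg = sorted(rows, key=lambda wc: (wc.r, wc.word))
    negative = [wc for wc in rows_neg[:top_n_words] if wc.r < 0]
    return WordCorrelationResult(positive, negative, False)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (overrepresentation) Fisher exact P-value for [[a, b], [c, d]].

    Returns the hypergeometric tail probability ``P(X >= a)`` where ``X`` is
    the top-left cell under fixed margins. Degenerate tables (a zero row or
    column margin) return 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return 1.0
    return float(min(1.0, hypergeom.sf(a - 1, n_total, col1, row1)))


@dataclass(frozen=True)
class TermEnrichmentRow:
    """Overrepresentation of one term among the top-ranked datasets."""

    term: str
    a: int  # datasets in the top set carrying the term
    b: int  # datasets in the remainder carrying the term
    top_size: int
    bg_size: int  # size of the remainder
    odds_ratio: float
    p: float
    padj: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any(pvalues <= 0) or np.any(pvalues > 1):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="fdr_bh")[1]


def term_enrichment(
    ranking: Sequence[str],
    dataset_terms: Mapping[str, Iterable[str]],
    top_n: int = 300,
    min_count: int = 5,
) -> list[TermEnrichmentRow]:
    """Test term overrepresentation in the top of a dataset ranking.

    The top set is the first ``min(top_n, N)`` datasets of ``ranking``. Every
    term occurring in at least ``min_count`` datasets overall is tested with a
    one-sided Fisher exact test on the 2x2 membership table, and P-values are
    BH-adjusted across the tested terms. Rows are sorted by P ascending (term
    name breaks ties).
    """
    if not ranking:
        raise ValueError("ranking must be non-empty")
    n_total = len(ranking)
    top_size = min(top_n, n_total)
    top_ids = set(ranking[:top_size])
    bg_size = n_total - top_size

    term_sets = {ds: set(dataset_terms.get(ds, ())) for ds in ranking}
    counts_top: dict[str, int] = {}
    counts_rest: dict[str, int] = {}
    for ds in ranking:
        target = counts_top if ds in top_ids else counts_rest
        for term in term_sets[ds]:
            target[term] = target.get(term, 0) + 1

    rows: list[TermEnrichmentRow] = []
    terms = sorted(set(counts_top) | set(counts_rest))
    for term in terms:
        a = counts_top.get(term, 0)
        b = counts_rest.get(term, 0)
        if a + b < min_count:
            continue
        cell_b = top_size - a
        cell_d = bg_size - b
        p = fisher_one_sided(a, cell_b, b, cell_d)
        if b * cell_b > 0:
            odds = (a * cell_d) / (cell_b * b)
        else:
            odds = math.inf if a * cell_d > 0 else 0.0
        rows.append(
            TermEnrichmentRow(
                term=term, a=a, b=b, top_size=top_size, bg_size=bg_size,
                odds_ratio=odds, p=p, padj=np.nan,
            )
        )
    if rows:
        adjusted = bh_adjust([row.p for row in rows])
        rows = [
            TermEnrichmentRow(
                term=row.term, a=row.a, b=row.b, top_size=row.top_size,
                bg_size=row.bg_size, odds_ratio=row.odds_ratio, p=row.p,
                padj=float(adj),
            )
            for row, adj in zip(rows, adjusted)
        ]
    rows.sort(key=lambda row: (row.p, row.term))
    return rows
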