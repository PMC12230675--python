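"""The dataset relevance score and compendium ranking.

Each sample of a row-centered expression matrix ``E`` (n genes x m samples)
is a point in gene space. A query gene set of size k defines the unit
direction ``p / sqrt(k)`` where ``p`` is the binary membership indicator over
the dataset's genes. The relevance score is the percentage of the dataset's
total variance captured by projecting the samples onto that direction:

    pctVar(E, p) = ||E^T p||^2 / (||E||^2 k) * 100

A high score means the query genes move up and down together across the
samples (coregulation). The score depends on ``E`` only through ``E E^T``, so
it can be computed on the SVD-reduced representation stored in the
compendium without loss (exactly, for matrices of rank at most the reduction
width).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import significance
from .preprocess import ProcessedDataset
from .signatures import GeneSignature, intersect_signature

__all__ = ["RankedResult", "RankingOutput", "ExcludedDataset", "pct_var", "query_profile", "rank_compendium"]


@dataclass(frozen=True)
class RankedResult:
    """Per-dataset search result."""

    dataset_id: str
    k: int
    score: float  # percent of dataset variance explained by the query direction
    pvalue: Optional[float]
    padj: Optional[float]
    rank: int
    log10_p: Optional[float] = None


@dataclass(frozen=True)
class ExcludedDataset:
    dataset_id: str
    k: int
    reason: str


@dataclass(frozen=True)
class RankingOutput:
    results: list[RankedResult]
    excluded: list[ExcludedDataset]


def pct_var(ds: ProcessedDataset, indicator: np.ndarray, k: int) -> float:
    """Percent of dataset variance explained by the query direction.

    ``indicator`` is the binary membership vector over ``ds.genes`` with
    exactly ``k`` ones. Equals the variance of the sample projections onto
    ``indicator / sqrt(k)`` divided by the total variance, times 100.
    """
    if k < 1:
        raise ValueError("query has no overlap with the dataset (k = 0)")
    indicator = np.asarray(indicator, dtype=float)
    if indicator.size != ds.n_genes:
        raise ValueError("indicator length does not match the dataset gene count")
    if int(round(indicator.sum())) != k:
        raise ValueError("indicator must contain exactly k ones")
    if ds.total_ss <= 0:
        return 0.0
    v = indicator @ ds.scores  # length r
    return float(v @ v / (ds.total_ss * k) * 100.0)


def query_profile(ds: ProcessedDataset, indicator: np.ndarray, k: int) -> np.ndarray:
    """Per-sample mean expression of the query genes (length m, mean ~ 0).

    Reconstructed through the stored loadings so it is available even for
    SVD-reduced datasets; used by the metadata word-correlation analysis.
    """
    if k < 1:
        raise ValueError("query has no overlap with the dataset (k = 0)")
    indicator = np.asarray(indicator, dtype=float)
    return (indicator @ ds.scores) @ ds.loadings.T / k


def _dataset_seed(master_seed: int, dataset_id: str) -> int:
    """Stable per-dataset seed independent of iteration order."""
    return (master_seed * 1_000_003 + zlib.crc32(dataset_id.encode())) % (2**31 - 1)


def rank_compendium(
    store,
    sig: GeneSignature,
    with_pvalues: bool = False,
    k_min: int = 1,
    seed: int = 0,
    pvalue_method: str = "multilevel",
    sample_size: int = 101,
    n_iter: int = 10_000,
) -> RankingOutput:
    """Score every dataset in a compendium against a signature and rank.

    Datasets overlapping the signature in fewer than ``k_min`` genes are
    excluded (reported separately with the reason). Ranking is by descending
    score; when ``with_pvalues`` is set, a Monte Carlo P-value is estimated
    per dataset (``pvalue_method`` is ``"multilevel"`` or ``"simple"``),
    ranking switches to ascending P with score as tiebreaker, and
    Benjamini-Hochberg adjusted values are computed across all scored
    datasets. Ties are broken by dataset id.
    """
    if len(sig) == 0:
        raise ValueError("signature contains no genes")
    if len(store) == 0:
        raise ValueError("compendium store is empty")

    scored: list[tuple[str, int, float, Optional[significance.PValueEstimate]]] = []
    excluded: list[ExcludedDataset] = []
    for dataset_id in store.ids():
        ds = store.get(dataset_id)
        indicator, k = intersect_signature(sig, ds.genes)
        if k < max(k_min, 1):
            excluded.append(
                ExcludedDataset(dataset_id=dataset_id, k=k, reason=f"overlap {k} below k_min {k_min}")
            )
            continue
        score = pct_var(ds, indicator, k)
        estimate = None
        if with_pvalues:
            ds_seed = _dataset_seed(seed, dataset_id)
            if pvalue_method == "multilevel":
                estimate = significance.multilevel_pvalue(
                    ds, k, score, sample_size=sample_size, rng_seed=ds_seed
                )
            elif pvalue_method == "simple":
                estimate = significance.simple_mc_pvalue(
                    ds, k, score, n_iter=n_iter, rng_seed=ds_seed
                )
            else:
                raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
        scored.append((dataset_id, k, score, estimate))

    if with_pvalues and scored:
        padj = significance.bh_adjust([est.p for _, _, _, est in scored])
        order_key = lambda item: (item[0][3].p, -item[0][2], item[0][0])
        rows = sorted(zip(scored, padj), key=order_key)
        results = [
            RankedResult(
                dataset_id=ds_id, k=k, score=score, pvalue=est.p, padj=float(adj),
                rank=rank, log10_p=est.log10_p,
            )
            for rank, ((ds_id, k, score, est), adj) in enumerate(rows, start=1)
        ]
    else:
        rows = sorted(scored, key=lambda item: (-item[2], item[0]))
        results = [
            RankedResult(dataset_id=ds_id, k=k, score=score, pvalue=None, padj=None, rank=rank)
            for rank, (ds_id, k, score, _) in enumerate(rows, start=1)
        ]
    return RankingOutput(results=results, excluded=excluded)
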