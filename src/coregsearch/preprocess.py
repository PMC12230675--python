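"""Per-dataset preprocessing: normalization, filtering, centering, reduction.

A raw gene-by-sample matrix is turned into the representation the relevance
score operates on:

* RNA-seq counts get a logCPM transform; microarray intensities get a log2
  transform when they look linear-scale (matrix max > 100) followed by
  quantile normalization;
* only the most highly expressed genes are retained (default cap 10 000,
  ranked by row mean);
* rows (genes) are centered;
* when a dataset has more than ``r`` samples (default 20), a truncated SVD
  compresses the sample dimension to ``r`` columns while preserving the score
  exactly for matrices of rank <= r.

The stored representation is ``scores`` (genes x reduced columns, i.e.
``U_r S_r``) together with column-orthonormal ``loadings`` (samples x reduced
columns, ``V_r``), so the centered matrix is approximately
``scores @ loadings.T`` and per-sample query profiles remain reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd

from .metadata import tokenize

__all__ = [
    "RawDataset",
    "ProcessedDataset",
    "log_cpm",
    "maybe_log2",
    "quantile_normalize",
    "select_top_expressed",
    "center_rows",
    "reduce_samples",
    "preprocess_dataset",
    "load_raw_tsv",
]

DEFAULT_N_KEEP = 10_000
DEFAULT_REDUCED_COLS = 20
LOG_SCALE_THRESHOLD = 100.0


@dataclass
class RawDataset:
    """A raw gene-by-sample expression matrix with free-text sample metadata.

    ``values`` holds non-negative counts (``kind="rnaseq"``) or intensities
    (``kind="microarray"``). ``sample_metadata`` is one free-text string per
    sample; ``description`` is dataset-level text (title/summary) used by the
    ranking-level term analysis.
    """

    id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    kind: str  # "rnaseq" | "microarray"
    sample_metadata: list[str] = field(default_factory=list)
    description: str = ""

    def validate(self) -> None:
        if self.kind not in ("rnaseq", "microarray"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        n, m = self.values.shape
        if len(self.genes) != n or len(self.samples) != m:
            raise ValueError("gene/sample label lengths do not match matrix shape")
        if len(set(self.genes)) != n:
            raise ValueError(f"{self.id}: duplicate gene identifiers")
        if len(set(self.samples)) != m:
            raise ValueError(f"{self.id}: duplicate sample identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.id}: matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError(f"{self.id}: matrix contains negative entries")
        if self.sample_metadata and len(self.sample_metadata) != m:
            raise ValueError(f"{self.id}: sample_metadata length mismatch")


@dataclass
class ProcessedDataset:
    """One compendium entry: the centered (optionally reduced) representation.

    ``scores`` is the gene-by-reduced-sample matrix, ``loadings`` the
    column-orthonormal map back to samples, and ``total_ss`` the squared
    Frobenius norm of ``scores`` (the denominator of the relevance score).
    """

    id: str
    genes: list[str]
    scores: np.ndarray  # n x r
    loadings: np.ndarray  # m x r
    total_ss: float
    sample_ids: list[str]
    sample_words: list[frozenset[str]] = field(default_factory=list)
    description: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_reduced(self) -> int:
        return self.scores.shape[1]


def log_cpm(counts: np.ndarray) -> np.ndarray:
    """log2 counts-per-million with a +1 pseudocount.

    ``out[g, j] = log2(counts[g, j] / colsum(j) * 1e6 + 1)``; monotone in the
    counts within each column. A zero library size is an error naming the
    offending column.
    """
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if zero.size:
        raise ValueError(f"zero library size in sample column(s) {zero.tolist()}")
    return np.log2(counts / libsize * 1e6 + 1.0)


def maybe_log2(values: np.ndarray, threshold: float = LOG_SCALE_THRESHOLD) -> np.ndarray:
    """Apply log2(x+1) only when the matrix looks linear-scale (max > threshold)."""
    values = np.asarray(values, dtype=float)
    if values.size and values.max() > threshold:
        return np.log2(values + 1.0)
    return values.copy()


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the mean empirical distribution.

    The reference is the mean of the per-column sorted vectors; each column's
    values are replaced by the reference at their within-column ranks. Tied
    values receive the mean of the reference positions they span.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = reference
        # ties: average the reference values assigned to equal inputs
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        groups = np.split(np.arange(n), boundaries)
        for grp in groups:
            if grp.size > 1:
                ranked[order[grp]] = reference[grp].mean()
        out[:, j] = ranked
    return out


def select_top_expressed(
    values: np.ndarray, genes: Sequence[str], n_keep: int = DEFAULT_N_KEEP
) -> tuple[np.ndarray, list[str]]:
    """Keep the ``n_keep`` most highly expressed genes (by row mean).

    Ties at the cutoff keep the earlier row (stable sort); kept genes preserve
    their original relative order.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n <= n_keep:
        return values.copy(), list(genes)
    means = values.mean(axis=1)
    # stable sort descending: negate and rely on stability for ties
    top = np.sort(np.argsort(-means, kind="stable")[:n_keep])
    return values[top], [genes[i] for i in top]


def center_rows(values: np.ndarray) -> np.ndarray:
    """Subtract each row's mean so every gene has mean zero across samples."""
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=1, keepdims=True)


def reduce_samples(
    centered: np.ndarray, r: int = DEFAULT_REDUCED_COLS
) -> tuple[np.ndarray, np.ndarray]:
    """Compress the sample dimension to at most ``r`` columns via truncated SVD.

    Returns ``(scores, loadings)`` with ``scores = U_r' S_r'`` and
    ``loadings = V_r'`` where ``r' = min(r, m, rank)``. When ``m <= r`` no
    reduction is performed: scores are the input and loadings the identity.
    For inputs of rank <= r the relevance score is preserved exactly, because
    ``||scores.T p||^2 = ||centered.T p||^2`` for every query vector p.
    """
    centered = np.asarray(centered, dtype=float)
    n, m = centered.shape
    if m <= r:
        return centered.copy(), np.eye(m)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s[0] * max(n, m) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    r_eff = max(1, min(r, rank))
    return u[:, :r_eff] * s[:r_eff], vt[:r_eff].T


def preprocess_dataset(
    raw: RawDataset,
    r: int = DEFAULT_REDUCED_COLS,
    n_keep: int = DEFAULT_N_KEEP,
) -> ProcessedDataset:
    """Run the full preprocessing pipeline on a raw dataset.

    RNA-seq: logCPM. Microarray: log2 if linear-scale, then quantile
    normalization. Both: keep top ``n_keep`` genes by mean expression, center
    rows, reduce samples to ``r`` columns when there are more than ``r``.
    Per-sample metadata is tokenized into word bags for the correlation
    analysis. Each step is recorded in ``provenance``.
    """
    raw.validate()
    provenance: dict = {"kind": raw.kind}
    if raw.kind == "rnaseq":
        values = log_cpm(raw.values)
        provenance["normalization"] = "log_cpm"
    else:
        values = np.asarray(raw.values, dtype=float)
        logged = values.size and values.max() > LOG_SCALE_THRESHOLD
        values = maybe_log2(values)
        values = quantile_normalize(values)
        provenance["normalization"] = ("log2+" if logged else "") + "quantile"
        provenance["log2_applied"] = bool(logged)
    values, genes = select_top_expressed(values, raw.genes, n_keep=n_keep)
    provenance["n_kept"] = len(genes)
    centered = center_rows(values)
    scores, loadings = reduce_samples(centered, r=r)
    provenance["reduced"] = scores.shape[1] < centered.shape[1]
    metadata = raw.sample_metadata or [""] * len(raw.samples)
    return ProcessedDataset(
        id=raw.id,
        genes=genes,
        scores=scores,
        loadings=loadings,
        total_ss=float((scores**2).sum()),
        sample_ids=list(raw.samples),
        sample_words=[frozenset(tokenize(text)) for text in metadata],
        description=raw.description,
        provenance=provenance,
    )


def load_raw_tsv(
    path: str | PathLike,
    kind: str,
    metadata_path: str | PathLike | None = None,
    description: str = "",
    dataset_id: str | None = None,
) -> RawDataset:
    """Load a gene-by-sample TSV (first column gene ids, header sample ids).

    ``metadata_path`` optionally points to a two-column TSV (sample id,
    free text) supplying per-sample metadata; samples without an entry get
    empty text.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    if frame.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    meta_map: dict[str, str] = {}
    if metadata_path is not None:
        meta = pd.read_csv(
            metadata_path, sep="\t", header=None, names=["sample", "text"], dtype=str
        )
        meta_map = dict(zip(meta["sample"], meta["text"].fillna("")))
    samples = [str(s) for s in frame.columns]
    if dataset_id is None:
        from pathlib import Path

        dataset_id = Path(path).stem
    raw = RawDataset(
        id=dataset_id,
        genes=[str(g) for g in frame.index],
        samples=samples,
        values=frame.to_numpy(dtype=float),
        kind=kind,
        sample_metadata=[meta_map.get(s, "") for s in samples],
        description=description,
    )
    raw.validate()
    return raw
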