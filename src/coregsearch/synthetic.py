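"""Synthetic compendia with known structure.

The generators emulate the statistical skeleton the search engine relies on:
log-scale microarray-like intensity matrices (iid Gaussian noise around a
constant baseline) in which an optional coregulated gene module follows a
latent per-sample factor z, and sample metadata words optionally tied to the
sign of z. Null datasets contain no module. The +10 baseline keeps values
non-negative and below the log-detection threshold, so the microarray
preprocessing branch stays linear and analytically tractable.

Module genes are always placed first and named ``MOD0001...`` so the matching
query signature can be constructed without bookkeeping
(:func:`module_signature`).
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Optional, Sequence

import numpy as np

from .preprocess import RawDataset, preprocess_dataset
from .signatures import GeneSignature, write_gmt
from .store import CompendiumStore, InMemoryCompendium

__all__ = [
    "PlantedSpec",
    "make_null_dataset",
    "make_planted_dataset",
    "make_compendium",
    "module_signature",
    "write_gmt_for_spec",
    "PLANTED_TERM",
]

BASELINE_SHIFT = 10.0
PLANTED_TERM = "treatment response"

# small vocabulary of filler metadata words so word-correlation has competitors
_FILLER_WORDS = (
    "liver", "kidney", "cortex", "spleen", "muscle",
    "serum", "biopsy", "culture", "fibroblast", "epithelial",
)
_NULL_DESCRIPTIONS = (
    "expression profiling of {w} tissue baseline",
    "transcriptome survey of {w} specimens control cohort",
    "gene expression atlas of {w} cells untreated",
)


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a dataset with a planted coregulated module.

    ``effect_a`` is the loading of the latent per-sample factor on every
    module gene; ``noise_sd`` the standard deviation of the iid Gaussian
    noise on all genes. ``marker_word`` (if set) is appended to the metadata
    of every sample whose latent factor is positive.
    """

    n_genes: int = 500
    m_samples: int = 20
    module_size: int = 30
    effect_a: float = 2.0
    noise_sd: float = 1.0
    marker_word: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if self.m_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_a < 0:
            raise ValueError("effect_a must be non-negative")


def _gene_names(n_genes: int, module_size: int = 0) -> list[str]:
    names = [f"MOD{i + 1:04d}" for i in range(module_size)]
    names += [f"G{i + 1:06d}" for i in range(n_genes - module_size)]
    return names


def module_signature(spec: PlantedSpec, name: str = "planted_module") -> GeneSignature:
    """The query signature matching a planted module."""
    return GeneSignature(
        name=name,
        description="synthetic planted coregulated module",
        genes=tuple(_gene_names(spec.module_size, spec.module_size)),
    )


def write_gmt_for_spec(spec: PlantedSpec, path) -> None:
    """Write the GMT query file matching a planted module spec."""
    write_gmt([module_signature(spec)], path)


def _sample_metadata(rng: np.random.Generator, sample_ids: Sequence[str]) -> list[str]:
    texts = []
    for sid in sample_ids:
        words = rng.choice(_FILLER_WORDS, size=2, replace=False)
        texts.append(f"sample {sid} {' '.join(words)}")
    return texts


def make_null_dataset(
    n_genes: int,
    m_samples: int,
    seed: int,
    dataset_id: Optional[str] = None,
    module_size: int = 0,
) -> RawDataset:
    """A structureless dataset: iid Gaussian intensities around the baseline.

    ``module_size`` only controls naming: the first that many genes get the
    shared ``MOD…`` names so null datasets live in the same gene universe as
    planted ones (and are scored, not excluded, under a module query); they
    carry no signal.
    """
    if n_genes < 1 or m_samples < 1:
        raise ValueError("n_genes and m_samples must be >= 1")
    if module_size > n_genes:
        raise ValueError("module_size cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, m_samples)) + BASELINE_SHIFT
    values = np.maximum(values, 0.0)
    sample_ids = [f"S{j + 1:03d}" for j in range(m_samples)]
    description = _NULL_DESCRIPTIONS[seed % len(_NULL_DESCRIPTIONS)].format(
        w=_FILLER_WORDS[seed % len(_FILLER_WORDS)]
    )
    return RawDataset(
        id=dataset_id or f"NULL{seed:06d}",
        genes=_gene_names(n_genes, module_size),
        samples=sample_ids,
        values=values,
        kind="microarray",
        sample_metadata=_sample_metadata(rng, sample_ids),
        description=description,
    )


def make_planted_dataset(spec: PlantedSpec, dataset_id: Optional[str] = None) -> RawDataset:
    """A dataset whose first ``module_size`` genes track a latent factor z.

    Module rows are ``effect_a * z + noise``; background rows are pure noise.
    Samples with z > 0 get ``marker_word`` appended to their metadata. The
    dataset description carries the fixed planted term so ranking-level term
    enrichment can be exercised.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.m_samples)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.m_samples))
    values = noise + BASELINE_SHIFT
    values[: spec.module_size] += spec.effect_a * z
    shift = min(0.0, float(values.min()))
    values = values - shift  # keep intensities non-negative even for large effects
    sample_ids = [f"S{j + 1:03d}" for j in range(spec.m_samples)]
    metadata = _sample_metadata(rng, sample_ids)
    if spec.marker_word:
        metadata = [
            text + (f" {spec.marker_word}" if z[j] > 0 else "")
            for j, text in enumerate(metadata)
        ]
    return RawDataset(
        id=dataset_id or f"PLANT{spec.seed:06d}",
        genes=_gene_names(spec.n_genes, spec.module_size),
        samples=sample_ids,
        values=values,
        kind="microarray",
        sample_metadata=metadata,
        description=f"{PLANTED_TERM} study of stimulated cells",
    )


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31 - 1))


def make_compendium(
    n_null: int,
    planted_specs: Sequence[PlantedSpec] = (),
    seed: int = 0,
    path: str | PathLike | None = None,
    null_n_genes: int = 500,
    null_m_samples: int = 12,
    r: int = 20,
    n_keep: int = 10_000,
):
    """Generate and preprocess a compendium of null and planted datasets.

    Returns an :class:`InMemoryCompendium` when ``path`` is None, otherwise
    writes (and returns) an HDF5 :class:`CompendiumStore` at ``path``. Fully
    deterministic given ``seed`` and the planted specs' own seeds.
    """
    if n_null + len(planted_specs) < 1:
        raise ValueError("compendium must contain at least one dataset")
    datasets = []
    shared_module = max((spec.module_size for spec in planted_specs), default=0)
    for i in range(n_null):
        raw = make_null_dataset(
            null_n_genes, null_m_samples, seed=_child_seed(seed, i),
            dataset_id=f"NULL{i + 1:04d}", module_size=min(shared_module, null_n_genes),
        )
        datasets.append(preprocess_dataset(raw, r=r, n_keep=n_keep))
    for i, spec in enumerate(planted_specs):
        raw = make_planted_dataset(spec, dataset_id=f"PLANT{i + 1:04d}")
        datasets.append(preprocess_dataset(raw, r=r, n_keep=n_keep))

    if path is None:
        return InMemoryCompendium(datasets)
    store = CompendiumStore(path, mode="w")
    for ds in datasets:
        store.add(ds)
    return store
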