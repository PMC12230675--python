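"""On-disk and in-memory collections of processed datasets.

The on-disk store is a single HDF5 file: one group per dataset holding the
scores and loadings matrices, the gene list, sample ids and per-sample word
bags (stored as space-joined token strings), with dataset-level metadata as
group attributes. A compendium index (id, n genes, m samples, reduced
columns, total sum of squares) is derivable from the groups.

Both store classes expose the same minimal interface — ``ids()``, ``get()``,
iteration and ``len()`` — which is all the search layer needs.
"""

from __future__ import annotations

from os import PathLike
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .preprocess import ProcessedDataset

__all__ = ["CompendiumStore", "InMemoryCompendium", "open_store"]

_STR = h5py.string_dtype(encoding="utf-8")


class InMemoryCompendium:
    """A dict-backed compendium, convenient for simulations and tests."""

    def __init__(self, datasets: list[ProcessedDataset] | None = None) -> None:
        self._data: dict[str, ProcessedDataset] = {}
        for ds in datasets or []:
            self.add(ds)

    def add(self, ds: ProcessedDataset) -> None:
        if ds.id in self._data:
            raise ValueError(f"duplicate dataset id {ds.id!r}")
        self._data[ds.id] = ds

    def ids(self) -> list[str]:
        return sorted(self._data)

    def get(self, dataset_id: str) -> ProcessedDataset:
        return self._data[dataset_id]

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self) -> Iterator[ProcessedDataset]:
        for dataset_id in self.ids():
            yield self._data[dataset_id]

    def index(self) -> pd.DataFrame:
        return _index_frame(self)


class CompendiumStore:
    """HDF5-backed compendium of processed datasets.

    Open with mode ``"r"`` to search an existing store or ``"w"``/``"a"`` to
    build one. Usable as a context manager.
    """

    def __init__(self, path: str | PathLike, mode: str = "r") -> None:
        self.path = str(path)
        self._file = h5py.File(path, mode)
        self._root = self._file.require_group("datasets") if mode != "r" else self._file["datasets"]

    # -- write ------------------------------------------------------------
    def add(self, ds: ProcessedDataset) -> None:
        if ds.id in self._root:
            raise ValueError(f"duplicate dataset id {ds.id!r}")
        grp = self._root.create_group(ds.id)
        grp.create_dataset("scores", data=np.asarray(ds.scores, dtype=np.float64))
        grp.create_dataset("loadings", data=np.asarray(ds.loadings, dtype=np.float64))
        grp.create_dataset("genes", data=np.array(ds.genes, dtype=_STR))
        grp.create_dataset("sample_ids", data=np.array(ds.sample_ids, dtype=_STR))
        words = [" ".join(sorted(bag)) for bag in ds.sample_words] or [""] * len(ds.sample_ids)
        grp.create_dataset("sample_words", data=np.array(words, dtype=_STR))
        grp.attrs["total_ss"] = float(ds.total_ss)
        grp.attrs["description"] = ds.description
        for key, value in ds.provenance.items():
            grp.attrs[f"prov_{key}"] = value

    # -- read -------------------------------------------------------------
    def ids(self) -> list[str]:
        return sorted(self._root.keys())

    def get(self, dataset_id: str) -> ProcessedDataset:
        grp = self._root[dataset_id]
        provenance = {
            key[len("prov_"):]: _plain(value)
            for key, value in grp.attrs.items()
            if key.startswith("prov_")
        }
        return ProcessedDataset(
            id=dataset_id,
            genes=[g.decode() if isinstance(g, bytes) else str(g) for g in grp["genes"][()]],
            scores=grp["scores"][()],
            loadings=grp["loadings"][()],
            total_ss=float(grp.attrs["total_ss"]),
            sample_ids=[
                s.decode() if isinstance(s, bytes) else str(s) for s in grp["sample_ids"][()]
            ],
            sample_words=[
                frozenset((w.decode() if isinstance(w, bytes) else str(w)).split())
                for w in grp["sample_words"][()]
            ],
            description=str(grp.attrs.get("description", "")),
            provenance=provenance,
        )

    def index(self) -> pd.DataFrame:
        return _index_frame(self)

    def __len__(self) -> int:
        return len(self._root)

    def __iter__(self) -> Iterator[ProcessedDataset]:
        for dataset_id in self.ids():
            yield self.get(dataset_id)

    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "CompendiumStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_store(path: str | PathLike) -> CompendiumStore:
    """Open an existing compendium store read-only."""
    return CompendiumStore(path, mode="r")


def _plain(value):
    if isinstance(value, (np.bool_, np.integer, np.floating)):
        return value.item()
    if isinstance(value, bytes):
        return value.decode()
    return value


def _index_frame(store) -> pd.DataFrame:
    rows = [
        {
            "dataset_id": ds.id,
            "n_genes": ds.n_genes,
            "n_samples": ds.n_samples,
            "n_reduced": ds.n_reduced,
            "total_ss": ds.total_ss,
        }
        for ds in store
    ]
    return pd.DataFrame(rows, columns=["dataset_id", "n_genes", "n_samples", "n_reduced", "total_ss"])
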