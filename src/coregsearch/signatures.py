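"""Gene signatures: GMT input/output and resolution against a dataset's genes.

A gene signature is a named set of gene identifiers (the search query).
Identifiers are opaque, case-sensitive strings; no Entrez/Ensembl mapping is
performed here — a mapping hook can be layered on top if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GeneSignature", "GmtFormatError", "read_gmt", "write_gmt", "intersect_signature"]


class GmtFormatError(ValueError):
    """Raised when a GMT line does not have the required fields."""


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, duplicate-free set of gene identifiers.

    Parameters
    ----------
    name
        Non-empty set name (first GMT field).
    description
        Free-text description (second GMT field).
    genes
        Gene identifiers; duplicates are collapsed keeping first occurrence.
    organism
        Optional organism tag (e.g. ``"human"``); purely informational.
    """

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | PathLike) -> list[GeneSignature]:
    """Read gene signatures from a GMT file (one tab-separated set per line).

    Each non-empty line must carry at least three fields: name, description,
    and one or more gene identifiers. Duplicate genes within a line are
    collapsed (order preserved); blank lines are skipped.

    Raises
    ------
    GmtFormatError
        If a non-empty line has fewer than three tab-separated fields; the
        message names the offending line number.
    """
    signatures: list[GeneSignature] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]  # tolerate trailing tabs
            signatures.append(GeneSignature(name=name, description=description, genes=tuple(genes)))
    return signatures


def write_gmt(signatures: Iterable[GeneSignature], path: str | PathLike) -> None:
    """Write signatures to GMT. ``read_gmt(write_gmt(x))`` preserves content."""
    with open(path, "w", encoding="utf-8") as handle:
        for sig in signatures:
            handle.write("\t".join([sig.name, sig.description, *sig.genes]) + "\n")


def intersect_signature(
    sig: GeneSignature, dataset_genes: Sequence[str]
) -> tuple[np.ndarray, int]:
    """Resolve a signature against a dataset's gene universe.

    Returns the binary indicator vector ``p`` over ``dataset_genes`` (1 where
    the gene belongs to the signature) and the overlap size ``k``. An empty
    intersection is a valid result with ``k == 0``.
    """
    members = set(sig.genes)
    indicator = np.fromiter(
        (1 if g in members else 0 for g in dataset_genes), dtype=np.int8, count=len(dataset_genes)
    )
    return indicator, int(indicator.sum())
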