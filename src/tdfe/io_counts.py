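"""Per-tissue count-table I/O.

Count tables are tab-separated text files, optionally gzip-compressed, one per
tissue: first column gene symbols, remaining columns raw read counts for one
(treatment, replicate) sample each.  The default column-header dialect is
``<treatment>_<replicate>`` (split on the last underscore); a
:class:`SampleMap` with a custom ``column_resolver`` overrides this for other
dialects.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleMap",
    "read_tissue_counts",
    "write_tissue_counts",
    "harmonize_genes",
]


def _default_resolver(header: str) -> tuple[str, int] | None:
    """Parse ``<treatment>_<replicate>`` headers; replicate is 1-based."""
    m = re.match(r"^(.*)_(\d+)$", header)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


@dataclass
class SampleMap:
    """Canonical sample layout of one study: treatments x replicates.

    Parameters
    ----------
    treatments
        Ordered treatment names (controls included).
    controls
        Subset of `treatments` designated as control conditions.
    n_replicates
        Replicates per treatment (1-based replicate indices).
    column_resolver
        Maps a raw column header to a ``(treatment, replicate)`` pair, or
        ``None`` if the header is not resolvable.
    """

    treatments: list[str]
    controls: list[str] = field(default_factory=list)
    n_replicates: int = 2
    column_resolver: Callable[[str], tuple[str, int] | None] = _default_resolver

    def __post_init__(self) -> None:
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment names must be unique")
        unknown = set(self.controls) - set(self.treatments)
        if unknown:
            raise ValueError(f"controls not in treatments: {sorted(unknown)}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def sample_labels(self) -> list[tuple[str, int]]:
        """Canonical (treatment, replicate) column order."""
        return [
            (t, r)
            for t in self.treatments
            for r in range(1, self.n_replicates + 1)
        ]

    def resolve(self, header: str) -> tuple[str, int] | None:
        pair = self.column_resolver(header)
        if pair is None:
            return None
        treatment, rep = pair
        if treatment not in self.treatments or not (1 <= rep <= self.n_replicates):
            return None
        return treatment, rep


@dataclass
class CountMatrix:
    """Raw counts for one tissue: genes x (treatment, replicate) samples."""

    tissue_name: str
    gene_ids: list[str]
    sample_labels: list[tuple[str, int]]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_labels)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique within one matrix")
        if len(set(self.sample_labels)) != len(self.sample_labels):
            raise ValueError("duplicate (treatment, replicate) sample label")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t}_{r}" for t, r in self.sample_labels]
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=cols)


def read_tissue_counts(path: str | Path, sample_map: SampleMap) -> CountMatrix:
    """Read one tissue's count table and reorder columns canonically.

    Columns whose headers do not resolve to a known (treatment, replicate)
    pair are reported and dropped.  Duplicate gene symbols keep the row with
    the largest total count.

    Raises
    ------
    FileNotFoundError
        If `path` does not exist.
    ValueError
        On non-numeric count cells (naming row and column) or when no column
        resolves.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, compression="infer")
    df.index = df.index.astype(str)

    resolved: dict[tuple[str, int], str] = {}
    for col in df.columns:
        pair = sample_map.resolve(str(col))
        if pair is None:
            logger.warning("%s: dropping unresolvable column %r", path.name, col)
            continue
        if pair in resolved:
            raise ValueError(f"{path}: sample {pair} mapped by two columns")
        resolved[pair] = col
    if not resolved:
        raise ValueError(f"{path}: no column header resolves against the sample map")

    for pair, col in resolved.items():
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise ValueError(f"{path}: non-numeric count at gene {row!r}, column {col!r}")

    order = [pair for pair in sample_map.sample_labels if pair in resolved]
    sub = df[[resolved[p] for p in order]].apply(pd.to_numeric)

    if sub.index.has_duplicates:
        totals = sub.sum(axis=1)
        keep = (
            pd.DataFrame({"total": totals})
            .assign(pos=np.arange(len(sub)))
            .sort_values(["total", "pos"], ascending=[False, True])
            .groupby(level=0, sort=False)
            .head(1)["pos"]
            .sort_values()
        )
        n_dropped = len(sub) - len(keep)
        logger.warning(
            "%s: %d duplicate gene rows dropped (kept largest total count)",
            path.name,
            n_dropped,
        )
        sub = sub.iloc[keep.to_numpy()]

    tissue = _tissue_from_filename(path.name)
    return CountMatrix(
        tissue_name=tissue,
        gene_ids=list(sub.index),
        sample_labels=order,
        counts=sub.to_numpy(dtype=float),
    )


def _tissue_from_filename(name: str) -> str:
    """Extract tissue from ``<prefix>_count_<Tissue>.txt[.gz]``; else stem."""
    m = re.match(r".*_count_(.+?)\.txt(\.gz)?$", name)
    if m:
        return m.group(1)
    return re.sub(r"\.txt(\.gz)?$", "", name)


def write_tissue_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write a tab-separated count table re-readable by :func:`read_tissue_counts`.

    Gzip compression is used when `path` ends in ``.gz``.
    """
    path = Path(path)
    df = matrix.to_frame()
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index_label="gene")


def harmonize_genes(matrices: Sequence[CountMatrix]) -> list[CountMatrix]:
    """Restrict all matrices to the shared gene set, in one canonical order.

    The canonical order is the first matrix's gene order restricted to the
    intersection.  The number of genes dropped per tissue is logged.

    Raises
    ------
    ValueError
        If no matrices are given or the gene intersection is empty.
    """
    if not matrices:
        raise ValueError("need at least one CountMatrix")
    shared = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise ValueError("gene intersection across tissues is empty")
    canonical = [g for g in matrices[0].gene_ids if g in shared]

    out = []
    for m in matrices:
        idx = {g: i for i, g in enumerate(m.gene_ids)}
        rows = [idx[g] for g in canonical]
        dropped = len(m.gene_ids) - len(rows)
        if dropped:
            logger.info("%s: %d genes dropped by harmonization", m.tissue_name, dropped)
        out.append(
            CountMatrix(
                tissue_name=m.tissue_name,
                gene_ids=list(canonical),
                sample_labels=list(m.sample_labels),
                counts=m.counts[rows, :],
            )
        )
    return out
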