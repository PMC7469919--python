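"""Assemble harmonized count matrices into the 4-way expression tensor and
standardize each sample's gene fiber.

The tensor is indexed ``(gene i, tissue j, treatment k, replicate m)``.
Standardization enforces, for every sample (j, k, m), zero mean over genes
and sum of squares equal to the gene count N — population (1/N) scaling, so
the sum-of-squares constraint holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_counts import CountMatrix, SampleMap

__all__ = ["ExpressionTensor", "assemble_tensor", "standardize"]


@dataclass
class ExpressionTensor:
    """4-way expression array with axis labels.

    ``values[i, j, k, m]`` is the expression of gene i in tissue j under
    treatment k, replicate m.
    """

    values: np.ndarray
    gene_ids: list[str]
    tissue_names: list[str]
    treatment_names: list[str]
    replicate_labels: list[int]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (
            len(self.gene_ids),
            len(self.tissue_names),
            len(self.treatment_names),
            len(self.replicate_labels),
        )
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != labels {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains NaN/Inf entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def save(self, path: str | Path) -> None:
        """Persist values + axis labels to one ``.npz`` container."""
        np.savez_compressed(
            path,
            values=self.values,
            gene_ids=np.array(self.gene_ids),
            tissue_names=np.array(self.tissue_names),
            treatment_names=np.array(self.treatment_names),
            replicate_labels=np.array(self.replicate_labels),
            standardized=np.array(self.standardized),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ExpressionTensor":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                gene_ids=[str(g) for g in z["gene_ids"]],
                tissue_names=[str(t) for t in z["tissue_names"]],
                treatment_names=[str(t) for t in z["treatment_names"]],
                replicate_labels=[int(r) for r in z["replicate_labels"]],
                standardized=bool(z["standardized"]),
            )


def assemble_tensor(
    matrices: Sequence[CountMatrix], sample_map: SampleMap
) -> ExpressionTensor:
    """Place harmonized per-tissue matrices into the 4-way tensor by label.

    Every (tissue, treatment, replicate) cell of the sample map must be
    covered exactly once across the input matrices; placement is label-driven,
    so the order of `matrices` is irrelevant.
    """
    if not matrices:
        raise ValueError("no matrices to assemble")
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise ValueError(
                f"{m.tissue_name}: gene order differs; run harmonize_genes first"
            )
    tissues = [m.tissue_name for m in matrices]
    if len(set(tissues)) != len(tissues):
        dup = sorted({t for t in tissues if tissues.count(t) > 1})
        raise ValueError(f"duplicate tissue matrices: {dup}")
    tissues = sorted(tissues)

    treatments = sample_map.treatments
    reps = list(range(1, sample_map.n_replicates + 1))
    shape = (len(genes), len(tissues), len(treatments), len(reps))
    values = np.full(shape, np.nan)

    t_idx = {t: j for j, t in enumerate(tissues)}
    k_idx = {t: k for k, t in enumerate(treatments)}
    for mat in matrices:
        j = t_idx[mat.tissue_name]
        for col, (treatment, rep) in enumerate(mat.sample_labels):
            if treatment not in k_idx or rep not in reps:
                raise ValueError(
                    f"{mat.tissue_name}: sample {(treatment, rep)} outside sample map"
                )
            k, m = k_idx[treatment], rep - 1
            if not np.isnan(values[0, j, k, m]):
                raise ValueError(
                    f"duplicate cell (tissue={mat.tissue_name}, "
                    f"treatment={treatment}, replicate={rep})"
                )
            values[:, j, k, m] = mat.counts[:, col]

    if np.isnan(values).any():
        missing = np.argwhere(np.isnan(values[0]))
        j, k, m = missing[0]
        raise ValueError(
            f"missing cell (tissue={tissues[j]}, treatment={treatments[k]}, "
            f"replicate={m + 1}); {len(missing)} cells uncovered"
        )

    return ExpressionTensor(
        values=values,
        gene_ids=list(genes),
        tissue_names=tissues,
        treatment_names=list(treatments),
        replicate_labels=reps,
        standardized=False,
    )


def standardize(
    tensor: ExpressionTensor,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> ExpressionTensor:
    """Standardize every sample's gene fiber to mean 0 and sum of squares N.

    With ``log_transform`` (the default), values become
    ``log2(x + pseudocount)`` first; raw counts are heavy-tailed and the
    chi-squared machinery downstream assumes roughly Gaussian loadings.

    Raises
    ------
    ValueError
        If the tensor is already standardized, N < 2, `pseudocount` is not
        positive under log transform, or any (j, k, m) fiber has zero
        variance (the scaling is then undefined).
    """
    if tensor.standardized:
        raise ValueError("tensor is already standardized")
    n = tensor.n_genes
    if n < 2:
        raise ValueError("standardization needs at least 2 genes")
    x = tensor.values
    if log_transform:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        x = np.log2(x + pseudocount)

    mean = x.mean(axis=0, keepdims=True)
    centered = x - mean
    ss = (centered**2).sum(axis=0, keepdims=True)
    zero = np.argwhere(ss[0] == 0)
    if zero.size:
        j, k, m = zero[0]
        raise ValueError(
            f"zero-variance fiber at (tissue={tensor.tissue_names[j]}, "
            f"treatment={tensor.treatment_names[k]}, replicate={m + 1})"
        )
    values = centered * np.sqrt(n / ss)

    return ExpressionTensor(
        values=values,
        gene_ids=list(tensor.gene_ids),
        tissue_names=list(tensor.tissue_names),
        treatment_names=list(tensor.treatment_names),
        replicate_labels=list(tensor.replicate_labels),
        standardized=True,
    )
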