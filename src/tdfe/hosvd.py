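"""Higher-order SVD (Tucker form) of the standardized expression tensor.

Each mode's factor matrix is the left singular matrix of that mode's
unfolding (economy form), and the core tensor is the multilinear projection
of the data onto all four factors:

    x[i,j,k,m] = sum_{l1 l2 l3 l4} G(l1,l2,l3,l4) u_tissue[j,l1]
                 u_treatment[k,l2] u_replicate[m,l3] u_gene[i,l4]

The decomposition is exact at full (economy) ranks.  The gene-mode factor is
economy-sized: N x r4 with r4 <= |tissues|*|treatments|*|replicates|, never
N x N.

Sign convention: every singular vector is flipped so its largest-magnitude
component is positive (ties broken by the first such component); the sum in
the reconstruction is sign-ambiguous per vector/core pair, and a fixed
convention makes runs and tests deterministic.  Core entries are reported
under this convention, so comparisons against externally printed core values
should use absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tensor import ExpressionTensor

__all__ = ["HOSVDResult", "hosvd", "reconstruct", "core_slice"]

# mode order: tissue (l1), treatment (l2), replicate (l3), gene (l4);
# tensor axis order is (gene, tissue, treatment, replicate)
_MODE_AXES = {"tissue": 1, "treatment": 2, "replicate": 3, "gene": 0}


@dataclass
class HOSVDResult:
    """Factor matrices and core tensor of one decomposition.

    Factor columns are indexed by 1-based ``l`` in user-facing APIs; the
    arrays themselves are 0-based.  ``core`` has shape
    ``(r1, r2, r3, r4)`` = (tissue, treatment, replicate, gene) ranks.
    """

    U_tissue: np.ndarray
    U_treatment: np.ndarray
    U_replicate: np.ndarray
    U_gene: np.ndarray
    core: np.ndarray
    singular_values: dict[str, np.ndarray]
    gene_ids: list[str]
    tissue_names: list[str]
    treatment_names: list[str]

    @property
    def mode_ranks(self) -> tuple[int, int, int, int]:
        return (
            self.U_tissue.shape[1],
            self.U_treatment.shape[1],
            self.U_replicate.shape[1],
            self.U_gene.shape[1],
        )

    def gene_vector(self, ell4: int) -> np.ndarray:
        """Gene-mode singular vector u_{l4, i} (1-based ``ell4``)."""
        return self.U_gene[:, _check_index(ell4, self.U_gene.shape[1], "ell4") - 1]

    def tissue_vector(self, ell1: int) -> np.ndarray:
        return self.U_tissue[:, _check_index(ell1, self.U_tissue.shape[1], "ell1") - 1]

    def treatment_vector(self, ell2: int) -> np.ndarray:
        return self.U_treatment[:, _check_index(ell2, self.U_treatment.shape[1], "ell2") - 1]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            U_tissue=self.U_tissue,
            U_treatment=self.U_treatment,
            U_replicate=self.U_replicate,
            U_gene=self.U_gene,
            core=self.core,
            sv_tissue=self.singular_values["tissue"],
            sv_treatment=self.singular_values["treatment"],
            sv_replicate=self.singular_values["replicate"],
            sv_gene=self.singular_values["gene"],
            gene_ids=np.array(self.gene_ids),
            tissue_names=np.array(self.tissue_names),
            treatment_names=np.array(self.treatment_names),
        )

    @classmethod
    def load(cls, path: str | Path) -> "HOSVDResult":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                U_tissue=z["U_tissue"],
                U_treatment=z["U_treatment"],
                U_replicate=z["U_replicate"],
                U_gene=z["U_gene"],
                core=z["core"],
                singular_values={
                    m: z[f"sv_{m}"]
                    for m in ("tissue", "treatment", "replicate", "gene")
                },
                gene_ids=[str(g) for g in z["gene_ids"]],
                tissue_names=[str(t) for t in z["tissue_names"]],
                treatment_names=[str(t) for t in z["treatment_names"]],
            )


def _check_index(ell: int, rank: int, name: str) -> int:
    if not 1 <= ell <= rank:
        raise IndexError(f"{name}={ell} outside 1..{rank}")
    return ell


def _unfold(values: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(values, axis, 0).reshape(values.shape[axis], -1)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-|.| entry is positive."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def hosvd(tensor: ExpressionTensor | np.ndarray, require_standardized: bool = True,
          **labels) -> HOSVDResult:
    """Decompose a 4-way tensor into per-mode factors and the core tensor.

    Parameters
    ----------
    tensor
        A standardized :class:`ExpressionTensor`, or a raw 4-way array
        (gene, tissue, treatment, replicate) with labels passed via
        ``gene_ids``/``tissue_names``/``treatment_names`` keywords.
    require_standardized
        Refuse an unstandardized :class:`ExpressionTensor` (default); the
        selection machinery downstream assumes the standardization contract.
    """
    if isinstance(tensor, ExpressionTensor):
        if require_standardized and not tensor.standardized:
            raise ValueError("hosvd requires a standardized tensor")
        values = tensor.values
        gene_ids = list(tensor.gene_ids)
        tissue_names = list(tensor.tissue_names)
        treatment_names = list(tensor.treatment_names)
    else:
        values = np.asarray(tensor, dtype=float)
        if values.ndim != 4:
            raise ValueError("expected a 4-way array")
        gene_ids = labels.get("gene_ids") or [f"g{i}" for i in range(values.shape[0])]
        tissue_names = labels.get("tissue_names") or [
            f"tissue{j}" for j in range(values.shape[1])
        ]
        treatment_names = labels.get("treatment_names") or [
            f"treatment{k}" for k in range(values.shape[2])
        ]
    if not np.all(np.isfinite(values)):
        raise ValueError("tensor contains non-finite entries")

    factors: dict[str, np.ndarray] = {}
    svals: dict[str, np.ndarray] = {}
    for mode, axis in _MODE_AXES.items():
        u, s, _ = np.linalg.svd(_unfold(values, axis), full_matrices=False)
        factors[mode] = _fix_signs(u)
        svals[mode] = s

    core = np.einsum(
        "ijkm,ja,kb,mc,id->abcd",
        values,
        factors["tissue"],
        factors["treatment"],
        factors["replicate"],
        factors["gene"],
        optimize=True,
    )
    return HOSVDResult(
        U_tissue=factors["tissue"],
        U_treatment=factors["treatment"],
        U_replicate=factors["replicate"],
        U_gene=factors["gene"],
        core=core,
        singular_values=svals,
        gene_ids=gene_ids,
        tissue_names=tissue_names,
        treatment_names=treatment_names,
    )


def reconstruct(result: HOSVDResult) -> np.ndarray:
    """Sum the decomposition back into a (gene, tissue, treatment, replicate)
    array; equals the input tensor to numerical precision at full ranks."""
    r1, r2, r3, r4 = result.core.shape
    if (
        result.U_tissue.shape[1] != r1
        or result.U_treatment.shape[1] != r2
        or result.U_replicate.shape[1] != r3
        or result.U_gene.shape[1] != r4
    ):
        raise ValueError("core shape does not match factor ranks")
    return np.einsum(
        "abcd,ja,kb,mc,id->ijkm",
        result.core,
        result.U_tissue,
        result.U_treatment,
        result.U_replicate,
        result.U_gene,
        optimize=True,
    )


def core_slice(result: HOSVDResult, ell1: int, ell2: int, ell3: int) -> np.ndarray:
    """Core fiber G(l1, l2, l3, .) over the gene-mode index (1-based)."""
    r1, r2, r3, _ = result.core.shape
    _check_index(ell1, r1, "ell1")
    _check_index(ell2, r2, "ell2")
    _check_index(ell3, r3, "ell3")
    return result.core[ell1 - 1, ell2 - 1, ell3 - 1, :]
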