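"""Model/Results front end for tensor-decomposition unsupervised feature
extraction.

``TensorFE`` wraps a gene x tissue x treatment x replicate expression tensor
(raw counts or already standardized); ``fit()`` computes the higher-order
SVD and returns a :class:`TensorFEResults` that exposes the factor matrices,
the core tensor, tissue-group/treatment-axis interpretation, chi-squared
gene selection and pooled two-group validation, plus a ``summary()`` table.

Example
-------
>>> from tdfe import synthetic, model
>>> spec = synthetic.default_study_spec(seed=1)
>>> matrices, truth = synthetic.generate_dataset(spec)
>>> res = model.TensorFE.from_count_matrices(matrices, spec.sample_map()).fit()
>>> sel = res.select_context(ell1=2, context_label="neuron")
>>> sel.n_selected  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import selection as _selection
from . import validation as _validation
from .hosvd import HOSVDResult as _HOSVDResult
from .hosvd import core_slice as _core_slice
from .hosvd import hosvd as _run_hosvd
from .io_counts import CountMatrix, SampleMap
from .tensor import ExpressionTensor, assemble_tensor, standardize


class TensorFE:
    """Unsupervised feature-extraction model over an expression tensor.

    Parameters
    ----------
    tensor
        An :class:`ExpressionTensor`.  If unstandardized, it is standardized
        at ``fit()`` time with the stored options.
    log_transform, pseudocount
        Standardization options applied when the input is raw counts.
    """

    def __init__(
        self,
        tensor: ExpressionTensor,
        log_transform: bool = True,
        pseudocount: float = 1.0,
    ):
        self.tensor = tensor
        self.log_transform = log_transform
        self.pseudocount = pseudocount

    @classmethod
    def from_count_matrices(
        cls,
        matrices: Sequence[CountMatrix],
        sample_map: SampleMap,
        log_transform: bool = True,
        pseudocount: float = 1.0,
    ) -> "TensorFE":
        """Harmonize, assemble and wrap per-tissue count matrices."""
        from .io_counts import harmonize_genes

        tensor = assemble_tensor(harmonize_genes(list(matrices)), sample_map)
        return cls(tensor, log_transform=log_transform, pseudocount=pseudocount)

    def fit(self) -> "TensorFEResults":
        tensor = self.tensor
        if not tensor.standardized:
            tensor = standardize(
                tensor, log_transform=self.log_transform, pseudocount=self.pseudocount
            )
        decomposition = _run_hosvd(tensor)
        return TensorFEResults(model=self, std_tensor=tensor,
                               decomposition=decomposition)


@dataclass
class TensorFEResults:
    """Fitted decomposition plus the interpretation/selection surface."""

    model: TensorFE
    std_tensor: ExpressionTensor
    decomposition: _HOSVDResult
    _selections: dict[str, _selection.GeneSelection] = field(default_factory=dict)

    # -- decomposition accessors -----------------------------------------
    @property
    def core(self) -> np.ndarray:
        return self.decomposition.core

    @property
    def mode_ranks(self) -> tuple[int, int, int, int]:
        return self.decomposition.mode_ranks

    def core_slice(self, ell1: int, ell2: int, ell3: int = 1) -> np.ndarray:
        return _core_slice(self.decomposition, ell1, ell2, ell3)

    def core_report(
        self, ell1_values: Sequence[int], ell2_values: Sequence[int] = (2, 3),
        ell3: int = 1, n_rows: int = 10,
    ) -> pd.DataFrame:
        """Top core-fiber entries per (l1, l2): the printed core-table analog."""
        cols = {}
        for l1 in ell1_values:
            for l2 in ell2_values:
                cols[f"G({l1},{l2},{ell3},l4)"] = self.core_slice(l1, l2, ell3)[:n_rows]
        df = pd.DataFrame(cols)
        df.index = pd.RangeIndex(1, len(df) + 1, name="l4")
        return df

    # -- interpretation ---------------------------------------------------
    def tissue_group(
        self, ell1: int, dominance: float = 0.5, side: str = "abs"
    ) -> _selection.GroupSplit:
        return _selection.identify_tissue_groups(
            self.decomposition, ell1, dominance, side
        )

    def treatment_split(
        self, ell2_pair: tuple[int, int] = (2, 3)
    ) -> tuple[_selection.GroupSplit, pd.DataFrame]:
        return _selection.classify_treatment_axes(self.decomposition, ell2_pair)

    def rank_gene_vectors(
        self, ell1: int, ell2_candidates: Sequence[int] = (2, 3), ell3: int = 1,
        top: int = 1, exclude_first: bool = True,
    ) -> list[tuple[int, float]]:
        return _selection.select_ell4(
            self.decomposition, ell1, ell2_candidates, ell3, top, exclude_first
        )

    # -- gene selection ----------------------------------------------------
    def select_genes(
        self, ell4_indices: Sequence[int], threshold: float = 0.01,
        context_label: str = "", combine: str = "chi2",
    ) -> _selection.GeneSelection:
        sel = _selection.select_genes(
            self.decomposition, ell4_indices, threshold, context_label, combine
        )
        if context_label:
            self._selections[context_label] = sel
        return sel

    def select_context(
        self, ell1: int, ell2_candidates: Sequence[int] = (2, 3), ell3: int = 1,
        n_vectors: int = 1, threshold: float = 0.01, context_label: str = "",
        combine: str = "chi2", dominance: float = 0.5, side: str = "abs",
    ) -> _selection.GeneSelection:
        """Core-guided selection for one tissue context: rank the gene-mode
        vectors by |G(l1, ., l3, .)| and select genes from the top ones.

        With ``side`` set to ``"positive"`` or ``"negative"`` the context is
        signed: the tissue group is read off one sign of the l1 vector, and
        the significant genes are additionally required to be over-expressed
        (in standardized units) in the member tissues relative to the rest.
        Signed contexts disentangle two planted groups of equal signal
        strength, which the factorization returns as a sum/difference vector
        pair rather than one vector per group.
        """
        ranked = self.rank_gene_vectors(ell1, ell2_candidates, ell3, top=n_vectors)
        ell4_indices = [l4 for l4, _ in ranked]
        suffix = {"abs": "", "positive": "+", "negative": "-"}[side]
        label = context_label or f"l1={ell1}{suffix}"
        sel = _selection.select_genes(
            self.decomposition, ell4_indices, threshold, label, combine
        )
        if side != "abs":
            split = self.tissue_group(ell1, dominance, side=side)
            members = set(split.members)
            in_idx = [j for j, t in enumerate(self.std_tensor.tissue_names)
                      if t in members]
            out_idx = [j for j, t in enumerate(self.std_tensor.tissue_names)
                       if t not in members]
            x = self.std_tensor.values
            contrast = x[:, in_idx].mean(axis=(1, 2, 3)) - x[:, out_idx].mean(
                axis=(1, 2, 3)
            )
            sel.direction_mask = contrast > 0
        if label:
            self._selections[label] = sel
        return sel

    # -- validation --------------------------------------------------------
    def two_group_test(
        self, selection: _selection.GeneSelection, split: _selection.GroupSplit
    ) -> _validation.GroupTestResult:
        return _validation.two_group_test(self.std_tensor, selection, split)

    def overlap_table(
        self, selections: Sequence[_selection.GeneSelection] | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        sels = list(selections) if selections else list(self._selections.values())
        return _validation.overlap_table(sels)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary: shape, ranks, variance partition of
        the leading sample-mode vectors, and any stored selections."""
        t = self.std_tensor
        r1, r2, r3, r4 = self.mode_ranks
        sv = self.decomposition.singular_values
        lines = [
            "Tensor-decomposition unsupervised feature extraction",
            "=" * 56,
            f"tensor: {t.n_genes} genes x {len(t.tissue_names)} tissues x "
            f"{len(t.treatment_names)} treatments x {len(t.replicate_labels)} replicates",
            f"mode ranks (tissue, treatment, replicate, gene): {(r1, r2, r3, r4)}",
            f"log-transform: {self.model.log_transform} "
            f"(pseudocount {self.model.pseudocount})",
            "",
            "leading singular values per mode:",
        ]
        for mode in ("tissue", "treatment", "replicate", "gene"):
            top = ", ".join(f"{v:.3g}" for v in sv[mode][:5])
            lines.append(f"  {mode:<10} {top}")
        if self._selections:
            lines += ["", "stored gene selections:"]
            for label, sel in self._selections.items():
                lines.append(
                    f"  {label:<12} vectors {sel.ell4_indices} -> "
                    f"{sel.n_selected} genes at adjusted P < {sel.threshold}"
                )
        return "\n".join(lines)

    def plot_treatment_plane(self, ell2_pair: tuple[int, int] = (2, 3), ax=None):
        """Scatter of treatments on the contrast plane (optional figure)."""
        import matplotlib.pyplot as plt

        split, report = self.treatment_split(ell2_pair)
        if ax is None:
            _, ax = plt.subplots()
        for grp, marker in (("members", "o"), ("complement", "s")):
            sub = report[report["group"] == grp]
            ax.scatter(sub.iloc[:, 1], sub.iloc[:, 2], marker=marker, label=grp)
        for _, row in report.iterrows():
            ax.annotate(row["treatment"], (row.iloc[1], row.iloc[2]), fontsize=7)
        ax.set_xlabel(f"u{ell2_pair[0]} (treatment mode)")
        ax.set_ylabel(f"u{ell2_pair[1]} (treatment mode)")
        ax.legend()
        return ax
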