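"""Two-group validation of selected genes and overlap between selections.

Selected genes are confirmed by pooling every standardized expression value
``x[i, j, k, m]`` with gene i in the selection and the axis label (tissue j
or treatment k) on one side of a two-way split, against the pool from the
other side, then comparing the pools with a Welch two-sided t-test and a
two-sided Wilcoxon rank-sum test.  Every (i, j, k, m) value counts as one
observation — no per-gene averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .selection import GeneSelection, GroupSplit
from .tensor import ExpressionTensor

__all__ = ["GroupTestResult", "two_group_test", "overlap_table"]


@dataclass
class GroupTestResult:
    """Pooled two-sample comparison for one selection and one axis split."""

    context_label: str
    axis: str
    split: GroupSplit
    t_p: float
    wilcoxon_p: float
    t_stat: float
    n_in: int
    n_out: int


def two_group_test(
    tensor: ExpressionTensor, selection: GeneSelection, split: GroupSplit
) -> GroupTestResult:
    """Welch t and Wilcoxon rank-sum on pooled values across a two-way split.

    The Welch (unequal-variance) form is used because pool sizes and
    variances differ by construction; the rank-sum test uses the normal
    approximation with tie correction, appropriate for the large continuous
    pools produced by standardization.
    """
    genes = selection.selected
    if not genes:
        raise ValueError("selection is empty")
    gene_idx = [i for i, g in enumerate(tensor.gene_ids) if g in genes]
    if not gene_idx:
        raise ValueError("selected genes not present in tensor")

    if split.axis == "tissue":
        labels, axis = tensor.tissue_names, 1
    else:
        labels, axis = tensor.treatment_names, 2
    members = set(split.members)
    in_idx = [i for i, lab in enumerate(labels) if lab in members]
    out_idx = [i for i, lab in enumerate(labels) if lab not in members]
    if not in_idx or not out_idx:
        raise ValueError(f"empty pool on the {split.axis} axis")

    sub = tensor.values[gene_idx]
    pool_in = np.take(sub, in_idx, axis=axis).ravel()
    pool_out = np.take(sub, out_idx, axis=axis).ravel()

    t_stat, t_p = stats.ttest_ind(pool_in, pool_out, equal_var=False)
    w = stats.mannwhitneyu(pool_in, pool_out, alternative="two-sided",
                           method="asymptotic")
    return GroupTestResult(
        context_label=selection.context_label,
        axis=split.axis,
        split=split,
        t_p=float(t_p),
        wilcoxon_p=float(w.pvalue),
        t_stat=float(t_stat),
        n_in=pool_in.size,
        n_out=pool_out.size,
    )


def overlap_table(
    selections: Sequence[GeneSelection],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Venn-region counts and pairwise Jaccard indices for >= 2 selections.

    Returns ``(regions, jaccard)``: `regions` has one row per non-empty
    membership pattern (columns: one boolean per selection label, plus
    ``count``); every gene in the union is counted in exactly one region.
    `jaccard` is the symmetric pairwise Jaccard-index matrix.
    """
    if len(selections) < 2:
        raise ValueError("need at least two selections")
    labels = [s.context_label or f"set{i}" for i, s in enumerate(selections)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i}" for i, lab in enumerate(labels)]
    sets = [s.selected for s in selections]
    union = set().union(*sets)

    patterns: dict[tuple[bool, ...], int] = {}
    for g in union:
        key = tuple(g in s for s in sets)
        patterns[key] = patterns.get(key, 0) + 1
    regions = pd.DataFrame(
        [dict(zip(labels, key), count=n) for key, n in sorted(patterns.items())]
    )

    jac = pd.DataFrame(np.eye(len(sets)), index=labels, columns=labels)
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        u = len(a | b)
        val = len(a & b) / u if u else 1.0
        jac.iloc[i, j] = jac.iloc[j, i] = val
    return regions, jac
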