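"""Interpretation of factor matrices and chi-squared gene selection.

The unsupervised feature-extraction step works entirely on the HOSVD
factors:

1. Tissue-mode vectors whose large-magnitude loadings concentrate on a few
   tissues define tissue groups (the first vector is typically near-uniform
   and carries no contrast).
2. Treatment-mode vectors 2 and 3 span a plane in which drug treatments
   separate from control/vehicle conditions; a deterministic 2-means split
   of the projected treatments recovers the two sides.
3. For a chosen tissue-mode index l1 (and the contrast-carrying treatment
   vectors, replicate vector 1), the gene-mode vectors l4 with the largest
   core magnitudes |G(l1, l2, 1, l4)| carry the matching gene weights.
4. Gene-mode loadings are treated as zero-mean Gaussian; each gene's summed
   squared standardized loading over the selected vectors is referred to a
   chi-squared distribution with one degree of freedom per vector, and the
   resulting P-values are BH-adjusted and thresholded (default adjusted
   P < 0.01, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hosvd import HOSVDResult, core_slice

__all__ = [
    "GroupSplit",
    "GeneSelection",
    "identify_tissue_groups",
    "classify_treatment_axes",
    "select_ell4",
    "compute_gene_pvalues",
    "bh_adjust",
    "select_genes",
]


@dataclass
class GroupSplit:
    """Two-way partition of one axis (tissues J vs complement, or
    treatments K vs complement), with provenance of the rule that made it."""

    axis: str  # "tissue" or "treatment"
    members: list[str]
    complement: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in ("tissue", "treatment"):
            raise ValueError("axis must be 'tissue' or 'treatment'")
        if not self.members:
            raise ValueError("members must be non-empty")
        if set(self.members) & set(self.complement):
            raise ValueError("members and complement overlap")

    @property
    def labels(self) -> list[str]:
        return list(self.members) + list(self.complement)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "group": ["members"] * len(self.members)
                + ["complement"] * len(self.complement),
            }
        )


@dataclass
class GeneSelection:
    """Genes selected for one tissue-group context, with full provenance.

    ``direction_mask``, when present, restricts the significant set to the
    genes whose expression contrast points into the context's member
    tissues; it is populated only for signed contexts (see
    :meth:`tdfe.model.TensorFEResults.select_context`).
    """

    context_label: str
    ell4_indices: list[int]
    gene_ids: list[str]
    p_values: np.ndarray
    adjusted_p: np.ndarray
    threshold: float
    sigma: dict[int, float]
    loadings: np.ndarray  # genes x len(ell4_indices)
    direction_mask: np.ndarray | None = None

    @property
    def selected_mask(self) -> np.ndarray:
        mask = self.adjusted_p < self.threshold
        if self.direction_mask is not None:
            mask = mask & self.direction_mask
        return mask

    @property
    def selected(self) -> set[str]:
        return {g for g, keep in zip(self.gene_ids, self.selected_mask) if keep}

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene": self.gene_ids, "p": self.p_values,
                           "adjusted_p": self.adjusted_p})
        for col, ell4 in enumerate(self.ell4_indices):
            df[f"u{ell4}"] = self.loadings[:, col]
        df["selected"] = self.selected_mask
        return df

    def export_gene_list(self, path: str | Path) -> None:
        """Plain one-symbol-per-line list, suitable for enrichment upload."""
        ordered = sorted(self.selected)
        Path(path).write_text("\n".join(ordered) + ("\n" if ordered else ""))

    def export_table(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def identify_tissue_groups(
    result: HOSVDResult, ell1: int, dominance: float = 0.5, side: str = "abs"
) -> GroupSplit:
    """Read a tissue group off one tissue-mode singular vector.

    Tissues whose loading magnitude reaches ``dominance`` times the maximum
    magnitude form the group.  A near-constant vector (the typical first
    vector) yields the full tissue set, signalling "no tissue specificity";
    callers should skip such indices.

    ``side`` restricts the group to one sign of the loading:
    ``"positive"``/``"negative"`` keep only tissues whose loading reaches
    the dominance cut with that sign.  Two planted tissue groups of equal
    signal strength appear in the factorization as a sum/difference pair of
    vectors; on the difference vector the two groups carry opposite signs,
    and the signed reading separates them where the magnitude reading
    returns their union.
    """
    if not 0 < dominance <= 1:
        raise ValueError("dominance must be in (0, 1]")
    if side not in ("abs", "positive", "negative"):
        raise ValueError("side must be 'abs', 'positive' or 'negative'")
    u = result.tissue_vector(ell1)
    cut = dominance * np.abs(u).max()
    mask = np.abs(u) >= cut
    if side == "positive":
        mask &= u > 0
    elif side == "negative":
        mask &= u < 0
    members = [t for t, keep in zip(result.tissue_names, mask) if keep]
    complement = [t for t, keep in zip(result.tissue_names, mask) if not keep]
    return GroupSplit(
        axis="tissue",
        members=members,
        complement=complement,
        provenance={"ell1": ell1, "dominance": dominance, "side": side,
                    "loadings": dict(zip(result.tissue_names, u.tolist()))},
    )


def _best_two_partition(points: np.ndarray) -> np.ndarray:
    """Deterministic 2-means on a small point set.

    For n <= 22 points the within-cluster sum of squares is minimized
    exactly by enumerating all bipartitions (vectorized); larger sets fall
    back to Lloyd iterations from the farthest pair.  Returns a boolean
    cluster-membership array.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    if d2.max() == 0:
        raise ValueError("fewer than 2 distinct projected points")
    if n <= 20:
        codes = np.arange(1, 2 ** (n - 1), dtype=np.int64)
        masks = ((codes[:, None] >> np.arange(n)) & 1).astype(bool)
        sizes = masks.sum(axis=1)
        sums = masks.astype(float) @ pts
        total = pts.sum(axis=0)
        sq = (pts**2).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            between = (sums**2).sum(1) / sizes + ((total - sums) ** 2).sum(1) / (
                n - sizes
            )
        best = int(np.argmax(between))  # min within-SS == max between-SS
        return masks[best]
    # Lloyd fallback, farthest-pair initialization
    a, b = np.unravel_index(np.argmax(d2), d2.shape)
    centers = pts[[a, b]].copy()
    assign = np.zeros(n, dtype=int)
    for it in range(100):
        dists = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_assign = np.argmin(dists, axis=1)
        if it > 0 and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in (0, 1):
            if (assign == c).any():
                centers[c] = pts[assign == c].mean(axis=0)
    return assign == 1


def classify_treatment_axes(
    result: HOSVDResult, ell2_pair: tuple[int, int] = (2, 3)
) -> tuple[GroupSplit, pd.DataFrame]:
    """Split treatments into two groups on the (u_2k, u_3k) plane.

    Projects every treatment onto the plane of the two contrast-carrying
    treatment-mode vectors and applies a deterministic 2-means split (the
    within-cluster sum of squares is minimized exactly for the small
    treatment sets this axis carries, so the result cannot be trapped in a
    local optimum of a heuristic initialization).  The smaller cluster is
    reported as ``members`` (the control-like side in the study design,
    where controls are the minority); ties go to the cluster containing the
    first treatment label.

    Returns the split plus a coordinates table (treatment, u2, u3, group)
    for plotting and manual override.
    """
    if result.U_treatment.shape[1] < max(ell2_pair):
        raise ValueError("treatment mode rank too small for the requested plane")
    pts = np.column_stack(
        [result.treatment_vector(ell2_pair[0]), result.treatment_vector(ell2_pair[1])]
    )
    in_b = _best_two_partition(pts)
    names = np.array(result.treatment_names)
    side_a = [str(t) for t in names[~in_b]]
    side_b = [str(t) for t in names[in_b]]
    if len(side_b) < len(side_a) or (
        len(side_b) == len(side_a) and result.treatment_names[0] in side_b
    ):
        members, complement = side_b, side_a
    else:
        members, complement = side_a, side_b
    split = GroupSplit(
        axis="treatment",
        members=members,
        complement=complement,
        provenance={"rule": "2means", "ell2_pair": list(ell2_pair)},
    )
    report = pd.DataFrame(
        {
            "treatment": result.treatment_names,
            f"u{ell2_pair[0]}": pts[:, 0],
            f"u{ell2_pair[1]}": pts[:, 1],
            "group": ["members" if t in set(members) else "complement"
                      for t in result.treatment_names],
        }
    )
    return split, report


def select_ell4(
    result: HOSVDResult,
    ell1: int,
    ell2_candidates: Sequence[int] = (2, 3),
    ell3: int = 1,
    top: int = 1,
    exclude_first: bool = True,
) -> list[tuple[int, float]]:
    """Rank gene-mode vectors by core magnitude for a fixed tissue context.

    ``score(l4) = max over l2 in candidates of |G(l1, l2, l3, l4)|``; the
    top-scoring l4 indices are returned with their scores.  The first
    gene-mode vector mirrors the contrast-free first vectors of the sample
    modes and is excluded by default.
    """
    if not ell2_candidates:
        raise ValueError("ell2_candidates must be non-empty")
    if top < 1:
        raise ValueError("top must be >= 1")
    scores = np.max(
        np.abs(
            np.stack([core_slice(result, ell1, l2, ell3) for l2 in ell2_candidates])
        ),
        axis=0,
    )
    order = np.argsort(-scores, kind="stable")
    ranked = [(int(idx) + 1, float(scores[idx])) for idx in order]
    if exclude_first:
        ranked = [(l4, s) for l4, s in ranked if l4 != 1]
    return ranked[:top]


def compute_gene_pvalues(
    result: HOSVDResult, ell4_indices: Sequence[int]
) -> tuple[np.ndarray, dict[int, float], np.ndarray]:
    """Chi-squared upper-tail P-value per gene from selected loading vectors.

    Each selected gene-mode vector is assumed zero-mean Gaussian over genes
    with standard deviation ``sigma = sqrt(mean(u^2))`` (population form,
    zero-mean).  The per-gene statistic is the sum of squared standardized
    loadings, referred to chi-squared with one degree of freedom per vector.

    Returns ``(p_values, sigma per index, loadings matrix)``.
    """
    if not ell4_indices:
        raise ValueError("ell4_indices must be non-empty")
    loadings = np.column_stack([result.gene_vector(l4) for l4 in ell4_indices])
    sigma = np.sqrt((loadings**2).mean(axis=0))
    if np.any(sigma == 0):
        bad = [l4 for l4, s in zip(ell4_indices, sigma) if s == 0]
        raise ValueError(f"zero standard deviation for gene vector(s) {bad}")
    statistic = ((loadings / sigma) ** 2).sum(axis=1)
    p = stats.chi2.sf(statistic, df=len(ell4_indices))
    return p, dict(zip(ell4_indices, sigma.tolist())), loadings


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_genes(
    result: HOSVDResult,
    ell4_indices: Sequence[int],
    threshold: float = 0.01,
    context_label: str = "",
    combine: str = "chi2",
) -> GeneSelection:
    """Select genes whose adjusted P-value falls below the threshold.

    ``combine="chi2"`` (default) sums squared standardized loadings across
    the selected vectors into one chi-squared statistic with df = number of
    vectors; ``combine="union"`` instead selects per-vector at df = 1 and
    takes the union (the per-gene P reported is then the minimum across
    vectors, its BH adjustment computed per vector).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if combine not in ("chi2", "union"):
        raise ValueError("combine must be 'chi2' or 'union'")

    if combine == "chi2" or len(ell4_indices) == 1:
        p, sigma, loadings = compute_gene_pvalues(result, ell4_indices)
        adj = bh_adjust(p)
    else:
        per = [compute_gene_pvalues(result, [l4]) for l4 in ell4_indices]
        p = np.min(np.column_stack([x[0] for x in per]), axis=1)
        adj = np.min(np.column_stack([bh_adjust(x[0]) for x in per]), axis=1)
        sigma = {l4: x[1][l4] for l4, x in zip(ell4_indices, per)}
        loadings = np.column_stack([x[2][:, 0] for x in per])

    return GeneSelection(
        context_label=context_label,
        ell4_indices=list(ell4_indices),
        gene_ids=list(result.gene_ids),
        p_values=p,
        adjusted_p=adj,
        threshold=threshold,
        sigma=sigma,
        loadings=loadings,
    )
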