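import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tdfe.hosvd import HOSVDResult, hosvd
from tdfe.selection import (
    bh_adjust,
    classify_treatment_axes,
    compute_gene_pvalues,
    identify_tissue_groups,
    select_ell4,
    select_genes,
)
from tdfe.tensor import ExpressionTensor


def make_result(U_gene=None, U_tissue=None, U_treatment=None, core=None):
    """Minimal HOSVDResult for unit tests of the selection rules."""
    U_gene = np.atleast_2d(np.ones((4, 1))) if U_gene is None else U_gene
    U_tissue = np.eye(3) if U_tissue is None else U_tissue
    U_treatment = np.eye(3) if U_treatment is None else U_treatment
    if core is None:
        core = np.zeros((U_tissue.shape[1], U_treatment.shape[1], 1,
                         U_gene.shape[1]))
    return HOSVDResult(
        U_tissue=U_tissue,
        U_treatment=U_treatment,
        U_replicate=np.eye(core.shape[2]),
        U_gene=U_gene,
        core=core,
        singular_values={m: np.ones(2) for m in
                         ("tissue", "treatment", "replicate", "gene")},
        gene_ids=[f"g{i}" for i in range(U_gene.shape[0])],
        tissue_names=[f"T{j}" for j in range(U_tissue.shape[0])],
        treatment_names=[f"D{k}" for k in range(U_treatment.shape[0])],
    )


class TestTissueGroups:
    def test_dominant_singleton(self):
        u = np.array([[0.99, 0.05, 0.02]]).T
        res = make_result(U_tissue=u)
        split = identify_tissue_groups(res, 1, dominance=0.5)
        assert split.members == ["T0"]
        assert set(split.complement) == {"T1", "T2"}

    def test_constant_vector_returns_all_tissues(self):
        u = np.full((5, 1), 1 / np.sqrt(5))
        res = make_result(U_tissue=u)
        split = identify_tissue_groups(res, 1)
        assert len(split.members) == 5  # signals "no tissue specificity"

    def test_signed_sides_partition_a_contrast_vector(self):
        u = np.array([[0.7, 0.69, -0.68, -0.71, 0.01, -0.02]]).T
        res = make_result(U_tissue=u)
        pos = identify_tissue_groups(res, 1, side="positive")
        neg = identify_tissue_groups(res, 1, side="negative")
        both = identify_tissue_groups(res, 1, side="abs")
        assert pos.members == ["T0", "T1"]
        assert neg.members == ["T2", "T3"]
        assert set(both.members) == set(pos.members) | set(neg.members)

    def test_dominance_validation(self):
        res = make_result(U_tissue=np.eye(3))
        with pytest.raises(ValueError, match="dominance"):
            identify_tissue_groups(res, 1, dominance=0.0)


class TestTreatmentAxes:
    def test_well_separated_clouds_split_exactly(self, rng):
        pts = np.concatenate([
            np.array([1.0, 0.0]) + 0.03 * rng.normal(size=(6, 2)),
            np.array([-1.0, 0.0]) + 0.03 * rng.normal(size=(12, 2)),
        ])
        res = make_result(U_treatment=np.column_stack(
            [np.ones(18) / np.sqrt(18), pts[:, 0], pts[:, 1]]))
        split, report = classify_treatment_axes(res)
        assert set(split.members) == {f"D{k}" for k in range(6)}
        assert len(report) == 18
        assert set(report["group"]) == {"members", "complement"}

    def test_recovers_planted_control_partition(self, study_fit):
        spec, _, truth, results = study_fit
        split, _ = results.treatment_split()
        assert set(split.members) == set(truth.control_treatments)

    def test_degenerate_points_error(self):
        res = make_result(U_treatment=np.zeros((4, 3)))
        with pytest.raises(ValueError, match="distinct"):
            classify_treatment_axes(res)


class TestSelectEll4:
    def test_rank_one_picks_first_vector_when_not_excluded(self, rng):
        a, b, c, d = (v / np.linalg.norm(v) for v in
                      (rng.normal(size=5), rng.normal(size=4),
                       rng.normal(size=3), rng.normal(size=2)))
        values = 4.0 * np.einsum("i,j,k,m->ijkm", a, b, c, d)
        result = hosvd(values, require_standardized=False)
        ranked = select_ell4(result, 1, [1], 1, top=1, exclude_first=False)
        assert ranked[0][0] == 1
        with_excl = select_ell4(result, 1, [1], 1, top=1, exclude_first=True)
        assert with_excl[0][0] != 1

    def test_scores_are_max_over_candidates(self):
        core = np.zeros((2, 3, 1, 4))
        core[0, 1, 0] = [9.0, 1.0, 5.0, 0.5]  # l2=2
        core[0, 2, 0] = [0.0, 2.0, 6.0, 0.1]  # l2=3
        res = make_result(U_gene=np.ones((4, 4)), U_tissue=np.eye(2), core=core)
        ranked = select_ell4(res, 1, [2, 3], 1, top=3)
        assert ranked == [(3, 6.0), (2, 2.0), (4, 0.5)]

    def test_empty_candidates_error(self, study_fit):
        _, _, _, results = study_fit
        with pytest.raises(ValueError, match="candidates"):
            select_ell4(results.decomposition, 2, [], 1)


class TestChiSquaredPvalues:
    def test_zero_loading_gives_p_one(self):
        u = np.array([[0.0, 1.0, -1.0, 2.0]]).T
        res = make_result(U_gene=u)
        p, _, _ = compute_gene_pvalues(res, [1])
        assert p[0] == 1.0

    def test_two_sigma_loading_matches_closed_form(self):
        # vector built so mean(u^2) = 1 (sigma = 1) with gene 0 at u = 2
        rest = np.sqrt(4.0 / 7.0) * np.array([1, -1, 1, -1, 1, -1, 1])
        u = np.concatenate([[2.0], rest]).reshape(-1, 1)
        res = make_result(U_gene=u)
        p, sig, _ = compute_gene_pvalues(res, [1])
        # independent closed form: chi2_1 upper tail at z^2 = erfc(|z|/sqrt(2))
        expected = math.erfc(2.0 / math.sqrt(2.0))
        assert p[0] == pytest.approx(expected, rel=1e-12)
        assert p[0] == pytest.approx(0.0455, abs=5e-5)

    def test_null_gaussian_loadings_give_uniform_pvalues(self):
        rng = np.random.default_rng(2024)
        u = rng.normal(size=(2000, 1))
        res = make_result(U_gene=u)
        p, _, _ = compute_gene_pvalues(res, [1])
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_df2_statistic_is_sum_of_df1_statistics(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=(50, 2))
        res = make_result(U_gene=u)
        p2, _, _ = compute_gene_pvalues(res, [1, 2])
        p1a, _, _ = compute_gene_pvalues(res, [1])
        p1b, _, _ = compute_gene_pvalues(res, [2])
        stat = lambda p, df: stats.chi2.isf(p, df)
        np.testing.assert_allclose(
            stat(p2, 2), stat(p1a, 1) + stat(p1b, 1), rtol=1e-9
        )

    def test_zero_variance_vector_errors(self):
        res = make_result(U_gene=np.zeros((4, 1)))
        with pytest.raises(ValueError, match="zero standard deviation"):
            compute_gene_pvalues(res, [1])


class TestBHAdjust:
    def test_worked_example_exact(self):
        adjusted = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_independent_step_up_oracle(self, rng):
        p = rng.random(40)

        def step_up(p):
            n = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                running = min(running, n * p[order[rank - 1]] / rank)
                adj[order[rank - 1]] = running
            return adj

        np.testing.assert_allclose(bh_adjust(p), step_up(p), rtol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_adjusted_never_below_raw_and_rank_monotone(self, p_list):
        p = np.array(p_list)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust(np.array([0.1, np.nan]))


class TestSelectGenes:
    def test_invalid_threshold_rejected(self, study_fit):
        _, _, _, results = study_fit
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="threshold"):
                select_genes(results.decomposition, [2], threshold=bad)

    def test_tiny_threshold_selects_nothing_under_null(self):
        rng = np.random.default_rng(5)
        res = make_result(U_gene=rng.normal(size=(500, 1)))
        sel = select_genes(res, [1], threshold=1e-12)
        assert sel.selected == set()

    def test_selection_invariant_to_gene_permutation(self, rng):
        spec_values = rng.gamma(2.0, 30.0, size=(60, 4, 3, 2))
        spec_values[:10] *= 8.0  # strong block to give a non-empty selection
        ids = [f"g{i}" for i in range(60)]
        from tdfe.tensor import standardize

        def run(values, ids):
            t = standardize(
                ExpressionTensor(values, ids, [f"T{j}" for j in range(4)],
                                 [f"D{k}" for k in range(3)], [1, 2]),
                log_transform=False,
            )
            return select_genes(hosvd(t), [2], context_label="perm")

        perm = rng.permutation(60)
        s1 = run(spec_values, ids)
        s2 = run(spec_values[perm], [ids[i] for i in perm])
        assert s1.selected == s2.selected

    def test_union_combine_equals_union_of_single_vector_selections(self,
                                                                    study_fit):
        _, _, _, results = study_fit
        d = results.decomposition
        union_sel = select_genes(d, [3, 4], combine="union")
        singles = (select_genes(d, [3]).selected | select_genes(d, [4]).selected)
        assert union_sel.selected == singles

    def test_adjusted_p_dominates_raw(self, study_fit):
        _, _, _, results = study_fit
        sel = select_genes(results.decomposition, [2])
        assert (sel.adjusted_p >= sel.p_values - 1e-15).all()
        assert set(np.array(sel.gene_ids)[sel.selected_mask]) == sel.selected


def test_exports_write_plain_text(tmp_path, study_fit):
    _, _, _, results = study_fit
    sel = select_genes(results.decomposition, [2], context_label="neuron")
    lst = tmp_path / "genes.txt"
    tbl = tmp_path / "genes.tsv"
    sel.export_gene_list(lst)
    sel.export_table(tbl)
    genes = [line for line in lst.read_text().splitlines() if line]
    assert set(genes) == sel.selected
    header = tbl.read_text().splitlines()[0].split("\t")
    assert header[:3] == ["gene", "p", "adjusted_p"]
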