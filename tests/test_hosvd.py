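import numpy as np
import pytest

from tdfe.hosvd import core_slice, hosvd, reconstruct
from tdfe.tensor import ExpressionTensor

from conftest import random_tensor


def brute_force_core(values, result):
    """Independent quadruple-loop contraction of the core tensor."""
    r1, r2, r3, r4 = result.mode_ranks
    core = np.zeros((r1, r2, r3, r4))
    n, nj, nk, nm = values.shape
    for l1 in range(r1):
        for l2 in range(r2):
            for l3 in range(r3):
                for l4 in range(r4):
                    acc = 0.0
                    for i in range(n):
                        for j in range(nj):
                            for k in range(nk):
                                for m in range(nm):
                                    acc += (
                                        values[i, j, k, m]
                                        * result.U_tissue[j, l1]
                                        * result.U_treatment[k, l2]
                                        * result.U_replicate[m, l3]
                                        * result.U_gene[i, l4]
                                    )
                    core[l1, l2, l3, l4] = acc
    return core


def unit(v):
    return v / np.linalg.norm(v)


def test_rank_one_tensor_has_single_core_entry(rng):
    a, b, c, d = (unit(rng.normal(size=s)) for s in (5, 4, 3, 2))
    values = 7.0 * np.einsum("i,j,k,m->ijkm", a, b, c, d)
    result = hosvd(values, require_standardized=False)
    norm = np.linalg.norm(values)
    assert abs(abs(result.core[0, 0, 0, 0]) - norm) < 1e-10
    rest = result.core.copy()
    rest[0, 0, 0, 0] = 0.0
    assert np.abs(rest).max() < 1e-10


def test_full_rank_reconstruction_is_exact(rng):
    t = random_tensor(rng, shape=(7, 5, 4, 2))
    result = hosvd(t)
    assert np.abs(reconstruct(result) - t.values).max() < 1e-8


def test_core_matches_brute_force_contraction(rng):
    t = random_tensor(rng, shape=(6, 4, 3, 2))
    result = hosvd(t)
    expected = brute_force_core(t.values, result)
    np.testing.assert_allclose(result.core, expected, atol=1e-8)


def test_factor_orthonormality_and_norm_conservation(rng):
    t = random_tensor(rng, shape=(9, 5, 4, 2))
    result = hosvd(t)
    for u in (result.U_tissue, result.U_treatment, result.U_replicate,
              result.U_gene):
        np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8)
    assert np.linalg.norm(result.core) == pytest.approx(
        np.linalg.norm(t.values), rel=1e-6
    )


def test_gene_factor_is_economy_sized(study_fit):
    _, _, _, results = study_fit
    d = results.decomposition
    n = len(d.gene_ids)
    assert d.U_gene.shape == (n, 24 * 18 * 2)
    assert d.core.shape == (24, 18, 2, 24 * 18 * 2)


def test_truncation_error_equals_dropped_singular_values(rng):
    """Zeroing the trailing gene-mode components loses exactly the sum of
    the squared dropped singular values of the gene-mode unfolding."""
    t = random_tensor(rng, shape=(8, 5, 4, 2))
    result = hosvd(t)
    s = result.singular_values["gene"]
    keep = 3
    truncated = result.core.copy()
    truncated[..., keep:] = 0.0
    result.core, full_core = truncated, result.core
    err2 = ((reconstruct(result) - t.values) ** 2).sum()
    result.core = full_core
    assert err2 == pytest.approx((s[keep:] ** 2).sum(), rel=1e-6)


def test_zero_core_reconstructs_zero(rng):
    t = random_tensor(rng)
    result = hosvd(t)
    result.core = np.zeros_like(result.core)
    assert np.abs(reconstruct(result)).max() == 0.0


def test_tissue_permutation_permutes_rows_and_preserves_core_magnitudes(rng):
    t = random_tensor(rng, shape=(6, 4, 3, 2))
    perm = rng.permutation(4)
    t2 = ExpressionTensor(
        t.values[:, perm], t.gene_ids, [t.tissue_names[j] for j in perm],
        t.treatment_names, t.replicate_labels, standardized=True,
    )
    r1, r2 = hosvd(t), hosvd(t2)
    np.testing.assert_allclose(
        np.abs(r1.U_tissue[perm]), np.abs(r2.U_tissue), atol=1e-8
    )
    np.testing.assert_allclose(np.abs(r1.core), np.abs(r2.core), atol=1e-8)


def test_unstandardized_tensor_refused(rng):
    raw = ExpressionTensor(
        rng.gamma(2.0, 30.0, size=(5, 3, 2, 2)),
        [f"g{i}" for i in range(5)], ["A", "B", "C"], ["d1", "d2"], [1, 2],
    )
    with pytest.raises(ValueError, match="standardized"):
        hosvd(raw)


class TestCoreSlice:
    def test_rank_one_slice_has_single_nonzero(self, rng):
        a, b, c, d = (unit(rng.normal(size=s)) for s in (5, 4, 3, 2))
        values = 3.0 * np.einsum("i,j,k,m->ijkm", a, b, c, d)
        result = hosvd(values, require_standardized=False)
        fiber = core_slice(result, 1, 1, 1)
        assert abs(fiber[0]) > 1.0
        assert np.abs(fiber[1:]).max() < 1e-10

    def test_slices_partition_core_norm(self, rng):
        result = hosvd(random_tensor(rng))
        total = sum(
            (core_slice(result, l1, l2, l3) ** 2).sum()
            for l1 in range(1, result.mode_ranks[0] + 1)
            for l2 in range(1, result.mode_ranks[1] + 1)
            for l3 in range(1, result.mode_ranks[2] + 1)
        )
        assert total == pytest.approx((result.core**2).sum(), rel=1e-10)

    def test_out_of_range_indices(self, rng):
        result = hosvd(random_tensor(rng))
        with pytest.raises(IndexError):
            core_slice(result, 0, 1, 1)
        with pytest.raises(IndexError):
            core_slice(result, 1, 99, 1)


def test_save_load_round_trip(tmp_path, rng):
    result = hosvd(random_tensor(rng))
    path = tmp_path / "hosvd.npz"
    result.save(path)
    from tdfe.hosvd import HOSVDResult

    back = HOSVDResult.load(path)
    np.testing.assert_array_equal(back.core, result.core)
    np.testing.assert_array_equal(back.U_gene, result.U_gene)
    assert back.tissue_names == result.tissue_names
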