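import numpy as np
import pytest

from tcalign.mnn import (
    CorrectionField,
    apply_correction,
    compute_correction,
    find_mutual_nn,
)


def brute_force_pairs(C, T, k_cl, k_t):
    """Exhaustive double-loop mutual-nearest-neighbor enumeration."""
    d = np.sqrt(((C[:, None, :] - T[None, :, :]) ** 2).sum(-1))
    pairs = set()
    for t in range(T.shape[0]):
        near_cl = set(np.argsort(d[:, t], kind="stable")[:k_cl])
        for c in near_cl:
            near_t = set(np.argsort(d[c], kind="stable")[:k_t])
            if t in near_t:
                pairs.add((c, t))
    return pairs


def brute_force_correction(pairing, C, T, cols, sigma_multiplier):
    d_vec = [C[c] - T[t] for c, t in zip(pairing.cell_line_idx, pairing.tumor_idx)]
    U = T[:, cols]
    Up = U[pairing.tumor_idx]
    d2 = np.array([[((u - v) ** 2).sum() for v in Up] for u in U])
    sigma_sq = sigma_multiplier * np.median(d2)
    out = np.zeros_like(T)
    for t in range(T.shape[0]):
        w = np.exp(-d2[t] / sigma_sq)
        w = w / w.sum()
        out[t] = sum(wi * dv for wi, dv in zip(w, d_vec))
    return out, sigma_sq


def names(n, prefix):
    return [f"{prefix}{i}" for i in range(n)]


class TestFindMutualNN:
    def test_identity_matching_on_copy(self, rng):
        C = rng.normal(size=(10, 6)) + 5
        T = C.copy()
        genes = names(6, "g")
        pairing = find_mutual_nn(C, T, names(10, "c"), names(10, "t"),
                                 genes, genes, k_cl=1, k_t=1)
        assert pairing.as_tuples() == {(f"c{i}", f"t{i}") for i in range(10)}
        np.testing.assert_allclose(pairing.distances, 0.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        C = rng.normal(size=(8, 2))
        T = rng.normal(size=(20, 2))
        genes = names(2, "g")
        pairing = find_mutual_nn(C, T, names(8, "c"), names(20, "t"),
                                 genes, genes, k_cl=2, k_t=5)
        got = set(zip(pairing.cell_line_idx.tolist(), pairing.tumor_idx.tolist()))
        assert got == brute_force_pairs(C, T, 2, 5)

    def test_mutuality_symmetry(self, rng):
        # the pair set is direction-free: recompute with roles of the axes
        # swapped inside the brute-force enumeration
        C = rng.normal(size=(12, 3))
        T = rng.normal(size=(30, 3))
        genes = names(3, "g")
        pairing = find_mutual_nn(C, T, names(12, "c"), names(30, "t"),
                                 genes, genes, k_cl=3, k_t=7)
        d = np.sqrt(((C[:, None, :] - T[None, :, :]) ** 2).sum(-1))
        cl_first = set()
        for c in range(12):
            for t in np.argsort(d[c], kind="stable")[:7]:
                if c in np.argsort(d[:, t], kind="stable")[:3]:
                    cl_first.add((c, int(t)))
        assert set(zip(pairing.cell_line_idx.tolist(),
                       pairing.tumor_idx.tolist())) == cl_first

    def test_monotone_in_k_t(self, rng):
        C = rng.normal(size=(10, 4))
        T = rng.normal(size=(40, 4))
        genes = names(4, "g")
        counts = [
            find_mutual_nn(C, T, names(10, "c"), names(40, "t"),
                           genes, genes, k_cl=3, k_t=k).n_pairs
            for k in (2, 5, 10, 20)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_gene_subset_restricts_space(self, rng):
        C = rng.normal(size=(6, 4))
        T = rng.normal(size=(15, 4))
        genes = names(4, "g")
        sub = ["g1", "g3"]
        pairing = find_mutual_nn(C, T, names(6, "c"), names(15, "t"),
                                 genes, sub, k_cl=2, k_t=4)
        expected = brute_force_pairs(C[:, [1, 3]], T[:, [1, 3]], 2, 4)
        assert set(zip(pairing.cell_line_idx.tolist(),
                       pairing.tumor_idx.tolist())) == expected

    def test_empty_gene_subset(self, rng):
        C, T = rng.normal(size=(4, 2)), rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="empty gene subset"):
            find_mutual_nn(C, T, names(4, "c"), names(6, "t"),
                           names(2, "g"), [], 1, 1)

    def test_k_bounds(self, rng):
        C, T = rng.normal(size=(4, 2)), rng.normal(size=(6, 2))
        g = names(2, "g")
        with pytest.raises(ValueError):
            find_mutual_nn(C, T, names(4, "c"), names(6, "t"), g, g, 4, 2)
        with pytest.raises(ValueError):
            find_mutual_nn(C, T, names(4, "c"), names(6, "t"), g, g, 2, 6)


class TestComputeCorrection:
    def _pairing(self, C, T, k_cl, k_t, genes, sub=None):
        return find_mutual_nn(C, T, names(C.shape[0], "c"), names(T.shape[0], "t"),
                              genes, sub or genes, k_cl, k_t)

    def test_constant_pair_vectors(self, rng):
        from tcalign.mnn import MNNPairing

        T = rng.normal(size=(7, 3)) + 10
        d = np.array([1.0, -2.0, 0.5])
        C = T[:5] + d  # every pair vector equals d exactly
        genes = names(3, "g")
        pairing = MNNPairing(
            cell_line_idx=np.arange(5), tumor_idx=np.arange(5),
            distances=np.full(5, np.linalg.norm(d)),
            cell_line_ids=names(5, "c"), tumor_ids=names(7, "t"),
            k_cell_line=1, k_tumor=1, gene_subset=genes,
        )
        field = compute_correction(pairing, C, T, genes, sigma_multiplier=3.0)
        np.testing.assert_allclose(field.vectors, np.tile(d, (7, 1)), atol=1e-10)

    def test_zero_differences_zero_corrections(self, rng):
        C = rng.normal(size=(6, 4)) + 5
        T = C.copy()
        genes = names(4, "g")
        pairing = self._pairing(C, T, 1, 1, genes)
        field = compute_correction(pairing, C, T, genes, 3.0)
        np.testing.assert_allclose(field.vectors, 0.0, atol=1e-10)

    def test_matches_weighted_average_oracle(self, rng):
        C = rng.normal(size=(8, 2))
        T = rng.normal(size=(20, 2))
        genes = names(2, "g")
        pairing = self._pairing(C, T, 2, 5, genes)
        field = compute_correction(pairing, C, T, genes, 3.0)
        expected, sigma_sq = brute_force_correction(pairing, C, T, np.array([0, 1]), 3.0)
        assert field.sigma_sq == pytest.approx(sigma_sq, rel=1e-12)
        np.testing.assert_allclose(field.vectors, expected, atol=1e-10)

    def test_translation_equivariance(self, rng):
        C = rng.normal(size=(8, 3))
        T = rng.normal(size=(25, 3))
        shift = np.array([2.0, -1.0, 0.5])
        genes = names(3, "g")
        p1 = self._pairing(C, T, 2, 6, genes)
        f1 = compute_correction(p1, C, T, genes, 3.0)
        # same pair set: tumor-tumor kernel distances are shift-invariant
        f2 = compute_correction(p1, C, T + shift, genes, 3.0)
        np.testing.assert_allclose(f2.vectors, f1.vectors - shift, atol=1e-8)

    def test_empty_pairing_rejected(self, rng):
        C, T = rng.normal(size=(4, 2)), rng.normal(size=(6, 2))
        genes = names(2, "g")
        pairing = self._pairing(C, T, 1, 1, genes)
        pairing.cell_line_idx = pairing.cell_line_idx[:0]
        pairing.tumor_idx = pairing.tumor_idx[:0]
        with pytest.raises(ValueError, match="empty"):
            compute_correction(pairing, C, T, genes, 3.0)


class TestApplyCorrection:
    def test_zero_field(self, rng):
        T = rng.normal(size=(5, 3))
        field = CorrectionField(names(5, "t"), np.zeros((5, 3)), 1.0)
        np.testing.assert_array_equal(apply_correction(T, field), T)

    def test_duplicate_dataset_fixture_aligns_exactly(self, rng):
        C = rng.normal(size=(10, 5)) + 6
        T = C.copy()
        genes = names(5, "g")
        pairing = find_mutual_nn(C, T, names(10, "c"), names(10, "t"),
                                 genes, genes, 1, 1)
        field = compute_correction(pairing, C, T, genes, 3.0)
        corrected = apply_correction(T, field)
        np.testing.assert_allclose(corrected, C, atol=1e-8)

    def test_shape_mismatch(self, rng):
        T = rng.normal(size=(5, 3))
        field = CorrectionField(names(4, "t"), np.zeros((4, 3)), 1.0)
        with pytest.raises(ValueError, match="shape mismatch"):
            apply_correction(T, field)


class TestOnSyntheticFixture:
    def test_exclusive_types_rarely_paired(self, default_fixture, pipeline_run):
        _, _, truth = default_fixture
        res = pipeline_run
        tt = np.array(truth.tumor_types)
        ct = np.array(truth.cell_line_types)
        exclusive = truth.exclusive_types[0] | truth.exclusive_types[1]
        touching = np.mean([
            ct[c] in exclusive or tt[t] in exclusive
            for c, t in zip(res.pairing.cell_line_idx, res.pairing.tumor_idx)
        ])
        assert touching <= 0.05

    def test_matched_centroids_move_closer(self, default_fixture, pipeline_run):
        _, _, truth = default_fixture
        res = pipeline_run
        tt = np.array(truth.tumor_types)
        ct = np.array(truth.cell_line_types)
        before = res.tumors_aligned - res.correction.vectors
        shared = sorted(set(tt) & set(ct))
        d_before = d_after = 0.0
        for ty in shared:
            cl_centroid = res.cell_lines_aligned[ct == ty].mean(0)
            d_before += np.linalg.norm(before[tt == ty].mean(0) - cl_centroid)
            d_after += np.linalg.norm(res.tumors_aligned[tt == ty].mean(0) - cl_centroid)
        assert d_after < d_before
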