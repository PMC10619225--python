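"""Normalization, gene selection, embedding, correction and projection."""

import numpy as np
import pytest

from hascad import harmonize as hz
from hascad.harmonize import (
    EmbeddingSet,
    ReferenceModel,
    ScalingParams,
    batch_mixing_entropy,
    build_reference,
    correct_embedding,
    embed,
    log_cp10k,
    project_query,
    reconstruct,
    standardize,
    tpm,
    vst_select,
)


class TestLogCp10k:
    def test_zero_count_maps_to_zero(self):
        m = np.array([[0.0, 0.0], [10.0, 5.0]])
        out = log_cp10k(m)
        assert out[0, 0] == 0.0 and out[0, 1] == 0.0

    def test_single_gene_cell(self):
        out = log_cp10k(np.array([[100.0]]))
        assert out[0, 0] == pytest.approx(np.log2(1e4 + 1), abs=1e-4)
        assert out[0, 0] == pytest.approx(13.2879, abs=1e-3)

    def test_depth_invariance(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [0.0, 6.0]])
        doubled = m.copy()
        doubled[:, 1] *= 7.5
        assert np.allclose(log_cp10k(m)[:, 1], log_cp10k(doubled)[:, 1])

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            log_cp10k(np.array([[1.0, 0.0], [1.0, 0.0]]))


class TestTpm:
    def test_already_normalized_unchanged(self):
        m = np.array([[5e5], [5e5]])
        assert np.allclose(tpm(m), m)

    def test_direct_arithmetic(self):
        out = tpm(np.array([[1.0], [3.0]]))
        assert np.allclose(out[:, 0], [2.5e5, 7.5e5])

    def test_columns_sum_to_one_million(self, rng):
        m = rng.uniform(0.1, 5.0, size=(20, 7))
        assert np.allclose(tpm(m).sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            tpm(np.zeros((3, 1)))


class TestVstSelect:
    def test_constant_genes_never_selected(self, rng):
        m = rng.normal(2.0, 1.0, size=(10, 50))
        m[3] = 5.0  # constant gene
        params = vst_select(np.abs(m), [f"g{i}" for i in range(10)], 5)
        assert "g3" not in params.selected_genes

    def test_block_effect_gene_outranks_housekeeping(self, rng):
        n = 60
        flat = rng.normal(3.0, 0.05, size=n)
        block = np.concatenate([rng.normal(1.0, 0.05, n // 2), rng.normal(5.0, 0.05, n // 2)])
        filler = np.abs(rng.normal(2.0, 0.3, size=(8, n)))
        m = np.vstack([flat, block, filler])
        ids = ["flat", "block"] + [f"f{i}" for i in range(8)]
        params = vst_select(np.abs(m), ids, 1)
        assert params.selected_genes == ["block"]

    def test_requesting_all_genes_returns_all(self, rng):
        m = np.abs(rng.normal(1.0, 0.5, size=(6, 30)))
        params = vst_select(m, [f"g{i}" for i in range(6)], 6)
        assert len(params.selected_genes) == 6

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vst_select(np.full((4, 10), 2.0), list("abcd"), 2)

    def test_scale_strictly_positive(self, small_reference):
        assert (small_reference.scaling.scale > 0).all()


class TestEmbed:
    def test_rank2_exact_recovery(self, rng):
        A = rng.normal(size=(40, 2)) @ rng.normal(size=(2, 30))
        emb = embed(A, 2)
        assert np.allclose(emb.U @ emb.Z, A, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        A = rng.normal(size=(20, 25))
        e1, e2 = embed(A, 5), embed(A, 5)
        assert np.array_equal(e1.U, e2.U) and np.array_equal(e1.Z, e2.Z)
        for j in range(5):
            assert e1.U[np.argmax(np.abs(e1.U[:, j])), j] > 0

    def test_component_variance_non_increasing(self, rng):
        A = rng.normal(size=(30, 50))
        emb = embed(A, 8)
        v = (emb.Z**2).sum(axis=1)
        assert (np.diff(v) <= 1e-9).all()

    def test_d_above_rank_reduced_with_warning(self, rng):
        A = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 12))
        with pytest.warns(UserWarning, match="rank"):
            emb = embed(A, 5)
        assert emb.d == 2

    def test_orthonormal_loadings(self, rng):
        emb = embed(rng.normal(size=(30, 40)), 6)
        assert np.allclose(emb.U.T @ emb.U, np.eye(6), atol=1e-6)


def _translated_mixture(rng, gap=6.0, n=150, d=5):
    """Two batches that are pure translations of the same Gaussian mixture."""
    centers = rng.normal(scale=3.0, size=(3, d))
    comp = rng.integers(0, 3, size=2 * n)
    Z = centers[comp] + rng.normal(scale=0.4, size=(2 * n, d))
    shift = np.zeros(d)
    shift[0] = gap
    Z[n:] += shift
    batches = np.array(["a"] * n + ["b"] * n)
    return Z.T, batches


class TestCorrectEmbedding:
    def test_single_batch_identity(self, rng):
        Z = rng.normal(size=(4, 30))
        emb = EmbeddingSet(U=np.linalg.qr(rng.normal(size=(10, 4)))[0], Z=Z, Z_corrected=Z.copy(), d=4)
        out, state = correct_embedding(emb, np.array(["x"] * 30))
        assert np.array_equal(out.Z_corrected, out.Z)
        assert state.K == 0

    def test_k_below_two_rejected(self, rng):
        Z = rng.normal(size=(3, 20))
        emb = EmbeddingSet(U=np.linalg.qr(rng.normal(size=(5, 3)))[0], Z=Z, Z_corrected=Z.copy(), d=3)
        with pytest.raises(ValueError, match="K"):
            correct_embedding(emb, np.array(["a", "b"] * 10), K=1)

    def test_translation_removed(self):
        """Batch centroids of a translated mixture collapse by >= 90%."""
        rng = np.random.default_rng(7)
        Z, batches = _translated_mixture(rng)
        U = np.linalg.qr(rng.normal(size=(12, 5)))[0]
        emb = EmbeddingSet(U=U, Z=Z, Z_corrected=Z.copy(), d=5)
        out, _ = correct_embedding(emb, batches, K=6, seed=0)
        gap_before = np.linalg.norm(
            Z[:, batches == "a"].mean(axis=1) - Z[:, batches == "b"].mean(axis=1)
        )
        Zc = out.Z_corrected
        gap_after = np.linalg.norm(
            Zc[:, batches == "a"].mean(axis=1) - Zc[:, batches == "b"].mean(axis=1)
        )
        assert gap_after <= 0.1 * gap_before

    def test_diversity_score_increases_on_fixture(self, small_cells, small_reference):
        before = batch_mixing_entropy(small_reference.embedding.Z, small_cells.batch_labels)
        after = batch_mixing_entropy(small_reference.embedding.Z_corrected, small_cells.batch_labels)
        assert after > before

    def test_soft_memberships_are_distributions(self, small_reference):
        R = small_reference.clusters.assignments
        assert (R >= 0).all()
        assert np.allclose(R.sum(axis=0), 1.0, atol=1e-9)

    def test_objective_non_increasing_within_tolerance(self, small_reference):
        obj = np.array(small_reference.clusters.objective)
        assert len(obj) >= 2
        # allow a small relative uptick from the block updates
        assert (np.diff(obj) <= 0.05 * np.abs(obj[:-1])).all()


class TestReconstruct:
    def test_shape_contract(self, small_reference):
        out = reconstruct(small_reference.embedding, small_reference.scaling)
        assert out.shape[0] == len(small_reference.scaling.selected_genes)
        assert (out >= 0).all()

    def test_identity_correction_recovers_low_rank_input(self, rng):
        W = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 40))
        scaling = ScalingParams(
            [f"g{i}" for i in range(30)],
            mean=np.full(30, 5.0),
            scale=np.full(30, 2.0),
        )
        emb = embed(W, 3)
        rec = reconstruct(emb, scaling)
        assert np.allclose(rec, np.maximum(W * 2.0 + 5.0, 0.0), atol=1e-8)

    def test_cross_batch_type_distance_shrinks(self, small_cells, small_reference):
        """Per-type mean profiles of different batches get closer after
        correction than in the raw normalized data."""
        raw = small_reference.normalized_expression
        cor = small_reference.corrected_expression
        b0 = small_cells.batch_labels == "batch0"
        gaps_raw, gaps_cor = [], []
        for t in set(small_cells.type_labels):
            sel = small_cells.type_labels == t
            gaps_raw.append(np.linalg.norm(raw[:, sel & b0].mean(1) - raw[:, sel & ~b0].mean(1)))
            gaps_cor.append(np.linalg.norm(cor[:, sel & b0].mean(1) - cor[:, sel & ~b0].mean(1)))
        assert np.mean(gaps_cor) < np.mean(gaps_raw)


class TestProjectQuery:
    def test_reference_cell_projects_onto_its_embedding(self, small_cells, small_reference):
        norm = hz.log_cp10k(small_cells.counts)
        sel = [small_cells.gene_ids.index(g) for g in small_reference.scaling.selected_genes]
        q = norm[sel][:, :3]
        proj = project_query(q, small_reference.scaling.selected_genes, small_reference)
        assert np.allclose(proj.Zq, small_reference.embedding.Z[:, :3], atol=1e-6)

    def test_reference_mean_query_embeds_at_origin(self, small_reference):
        q = small_reference.scaling.mean[:, None]
        proj = project_query(q, small_reference.scaling.selected_genes, small_reference)
        assert np.allclose(proj.Zq, 0.0, atol=1e-9)

    def test_gene_order_invariance(self, rng, small_reference):
        genes = list(small_reference.scaling.selected_genes)
        q = np.abs(rng.normal(1.0, 0.5, size=(len(genes), 4)))
        p1 = project_query(q, genes, small_reference)
        perm = rng.permutation(len(genes))
        p2 = project_query(q[perm], [genes[i] for i in perm], small_reference)
        assert np.allclose(p1.Zq_corrected, p2.Zq_corrected, atol=1e-10)
        # genes unknown to the reference are ignored
        q3 = np.vstack([q, np.full((2, 4), 9.0)])
        p3 = project_query(q3, genes + ["zz1", "zz2"], small_reference)
        assert np.allclose(p1.Zq, p3.Zq, atol=1e-12)

    def test_low_overlap_rejected(self, small_reference):
        with pytest.raises(ValueError, match="%"):
            project_query(np.ones((2, 1)), ["nope1", "nope2"], small_reference)


def test_reference_roundtrip(tmp_path, small_reference):
    path = tmp_path / "ref.h5"
    small_reference.save(path)
    loaded = ReferenceModel.load(path)
    assert np.allclose(loaded.embedding.Z_corrected, small_reference.embedding.Z_corrected)
    assert np.allclose(loaded.corrected_expression, small_reference.corrected_expression)
    assert loaded.scaling.selected_genes == small_reference.scaling.selected_genes
    assert list(loaded.type_labels) == list(small_reference.type_labels)
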