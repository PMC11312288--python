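"""Signature comparison: panels, D and C matrices, MDS, clustering."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from microsig import (
    DistanceMatrix,
    SignatureSet,
    SignatureSimConfig,
    align_gene_panels,
    build_signature,
    classical_mds,
    correlation_matrix,
    cut_clusters,
    distance_matrix,
    hierarchical_cluster,
    simulate_signature_collection,
    to_newick,
)
from .conftest import random_signature_set
from ._oracles import abs_cosine_loops, euclidean_loops


def sigset(values, pops=None, genes=None) -> SignatureSet:
    arr = np.asarray(values, dtype=float)
    pops = pops or [f"P{i}" for i in range(arr.shape[0])]
    genes = genes or [f"g{i}" for i in range(arr.shape[1])]
    return SignatureSet(values=pd.DataFrame(arr, index=pops, columns=genes))


class TestBuildSignature:
    def test_projection_preserves_values_and_order(self):
        deg = pd.DataFrame({"log2fc": [9.06, 2.0, -1.0, 0.3]}, index=["a", "b", "c", "d"])
        vec = build_signature(deg, ["a", "b", "c"])
        assert list(vec) == [9.06, 2.0, -1.0]
        permuted = build_signature(deg, ["c", "a", "b"])
        assert list(permuted) == [-1.0, 9.06, 2.0]

    def test_missing_panel_gene_is_an_error(self):
        deg = pd.DataFrame({"log2fc": [1.0]}, index=["a"])
        with pytest.raises(KeyError, match="missing"):
            build_signature(deg, ["a", "zz"])


class TestAlignPanels:
    def test_case_insensitive_intersection(self):
        a2 = sigset([[1.0, 2.0, 3.0], [7.0, 8.0, 9.0]], pops=["A1", "A2"], genes=["Spp1", "Itgax", "Gpnmb"])
        b2 = sigset([[4.0, 5.0, 6.0], [1.0, 1.0, 1.0]], pops=["B1", "B2"], genes=["SPP1", "ITGAX", "Apoe"])
        merged = align_gene_panels([a2, b2])
        assert merged.genes == ["Itgax", "Spp1"]
        assert merged.populations == ["A1", "A2", "B1", "B2"]
        assert merged.values.loc["B1"].tolist() == [5.0, 4.0]

    def test_idempotent_for_identical_panels(self):
        a = sigset(np.arange(6.0).reshape(2, 3), pops=["A", "B"])
        b = sigset(np.arange(6.0).reshape(2, 3) + 1, pops=["C", "D"])
        merged = align_gene_panels([a, b])
        assert merged.genes == a.genes
        assert merged.values.shape == (4, 3)

    def test_casefold_duplicate_within_set_is_error(self):
        bad = sigset([[1.0, 2.0], [3.0, 4.0]], genes=["Spp1", "SPP1"])
        with pytest.raises(ValueError, match="case-folding"):
            align_gene_panels([bad, bad])

    def test_empty_intersection_is_error(self):
        a = sigset([[1.0], [2.0]], genes=["x"])
        b = sigset([[1.0], [2.0]], pops=["C", "D"], genes=["y"])
        with pytest.raises(ValueError, match="intersection"):
            align_gene_panels([a, b])


class TestDistanceMatrix:
    def test_hand_computed_entry(self):
        dm = distance_matrix(sigset([[1.0, 2.0, 2.0], [0.0, 0.0, 0.0]]))
        assert dm.d[0, 1] == pytest.approx(3.0, abs=1e-12)

    def test_zero_diagonal(self, rng):
        dm = distance_matrix(random_signature_set(rng))
        assert np.all(np.diag(dm.d) == 0.0)

    def test_matches_brute_force_loops(self, rng):
        for _ in range(20):
            sig = random_signature_set(rng, n=6, n_genes=50)
            dm = distance_matrix(sig)
            assert np.allclose(dm.d, euclidean_loops(sig.values.to_numpy()), atol=1e-12)

    def test_metric_axioms_on_random_sets(self, rng):
        for _ in range(50):
            sig = random_signature_set(rng, n=5, n_genes=20)
            d = distance_matrix(sig).d
            assert np.allclose(d, d.T, atol=1e-12)
            assert (d >= 0).all()
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestCorrelationMatrix:
    def test_hand_computed_entries(self):
        cm = correlation_matrix(sigset([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]]))
        assert cm.c[0, 1] == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-9)
        colinear = correlation_matrix(sigset([[2.0, 4.0], [1.0, 2.0]]))
        assert colinear.c[0, 1] == pytest.approx(1.0, abs=1e-12)
        anti = correlation_matrix(sigset([[1.0, 0.0], [-1.0, 0.0]]))
        assert anti.c[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_signed_option_exposes_anticorrelation(self):
        cm = correlation_matrix(sigset([[1.0, 0.0], [-1.0, 0.0]]), signed=True)
        assert cm.c[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_vector_rejected_by_name(self):
        with pytest.raises(ValueError, match="P1"):
            correlation_matrix(sigset([[1.0, 0.0], [0.0, 0.0]]))

    def test_matches_brute_force_loops(self, rng):
        for _ in range(20):
            sig = random_signature_set(rng, n=6, n_genes=40)
            cm = correlation_matrix(sig)
            assert np.allclose(cm.c, abs_cosine_loops(sig.values.to_numpy()), atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0), st.integers(min_value=0, max_value=10**6))
    def test_scale_invariance_bounds_and_symmetry(self, alpha, seed):
        r = np.random.default_rng(seed)
        sig = random_signature_set(r, n=4, n_genes=15)
        cm = correlation_matrix(sig)
        scaled = sig.values.copy()
        scaled.iloc[0] *= alpha
        cm2 = correlation_matrix(SignatureSet(values=scaled))
        assert np.allclose(cm.c, cm2.c, atol=1e-9)
        assert np.allclose(cm.c, cm.c.T, atol=1e-12)
        assert np.all((cm.c >= 0) & (cm.c <= 1))
        assert np.allclose(np.diag(cm.c), 1.0)

    def test_distance_cosine_consistency_for_unit_vectors(self, rng):
        """d^2 = 2(1 - cos theta) for unit-normalised vectors with cos >= 0."""
        x = rng.normal(size=(5, 30))
        x[0] = np.abs(x[0])  # keep some positive-cos pairs likely
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        sig = sigset(x)
        d = distance_matrix(sig).d
        cos = (x @ x.T).clip(-1, 1)
        mask = cos >= 0
        assert np.allclose(d[mask] ** 2, 2.0 * (1.0 - cos[mask]), atol=1e-9)


class TestClassicalMDS:
    def triangle(self) -> DistanceMatrix:
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        return DistanceMatrix(labels=["A", "B", "C"], d=d)

    def test_right_triangle_is_exactly_embeddable(self):
        emb = classical_mds(self.triangle(), k=2)
        coords = emb.coordinates
        dhat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(dhat, self.triangle().d, atol=1e-9)
        assert emb.stress <= 1e-9
        assert emb.eigenvalues[0] >= emb.eigenvalues[1]

    def test_planar_points_embed_with_zero_stress(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        emb = classical_mds(DistanceMatrix([f"P{i}" for i in range(8)], d), k=2)
        assert emb.stress <= 1e-9

    def test_one_dimension_cannot_embed_the_triangle(self):
        emb = classical_mds(self.triangle(), k=1)
        assert emb.stress > 1e-3

    def test_round_trip_idempotence(self, rng):
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"P{i}" for i in range(7)], d)
        emb1 = classical_mds(dm, k=2)
        c1 = emb1.coordinates
        d1 = np.sqrt(((c1[:, None] - c1[None, :]) ** 2).sum(-1))
        emb2 = classical_mds(DistanceMatrix(dm.labels, d1), k=2)
        c2 = emb2.coordinates
        d2 = np.sqrt(((c2[:, None] - c2[None, :]) ** 2).sum(-1))
        assert np.allclose(d1, d2, atol=1e-9)

    def test_sign_convention_is_reproducible(self):
        emb = classical_mds(self.triangle(), k=2)
        for axis in range(2):
            i = np.argmax(np.abs(emb.coordinates[:, axis]))
            assert emb.coordinates[i, axis] > 0

    def test_all_zero_distances_give_stress_zero(self):
        emb = classical_mds(DistanceMatrix(["A", "B"], np.zeros((2, 2))), k=1)
        assert emb.stress == 0.0
        assert np.allclose(emb.coordinates, 0.0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(self.triangle(), k=3)


class TestClustering:
    def test_two_populations_single_merge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 2.5], [2.5, 0.0]]))
        spec = hierarchical_cluster(dm)
        assert spec.merges.shape == (1, 4)
        assert spec.heights[0] == pytest.approx(2.5)

    def test_matches_scipy_average_linkage(self, rng):
        """Merge heights match scipy's average linkage on random points."""
        for _ in range(30):
            pts = rng.normal(size=(5, 3))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            spec = hierarchical_cluster(DistanceMatrix([f"P{i}" for i in range(5)], d))
            z = linkage(d[np.triu_indices(5, 1)], method="average")
            assert np.allclose(np.sort(spec.heights), np.sort(z[:, 2]), atol=1e-12)

    def test_heights_non_decreasing(self, rng):
        sig = random_signature_set(rng, n=8, n_genes=20)
        spec = hierarchical_cluster(distance_matrix(sig))
        assert np.all(np.diff(spec.heights) >= -1e-12)

    def test_planted_blocks_recovered_at_two_cluster_cut(self):
        for seed in range(1, 21):
            cfg = SignatureSimConfig(seed=seed)
            sig = simulate_signature_collection(cfg)
            spec = hierarchical_cluster(distance_matrix(sig))
            cut = cut_clusters(spec, 2)
            truth = [cfg.block_of[p] for p in sig.populations]
            pred = [cut[p] for p in sig.populations]
            assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_newick_is_parseable_with_correct_leaves(self, rng):
        import dendropy

        sig = random_signature_set(rng, n=6, n_genes=10)
        spec = hierarchical_cluster(distance_matrix(sig))
        tree = dendropy.Tree.get(data=to_newick(spec), schema="newick")
        leaves = sorted(t.label for t in tree.taxon_namespace)
        assert leaves == sorted(sig.populations)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix(["A"], np.zeros((1, 1))))
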