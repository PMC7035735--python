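"""K-means clustering and the NMI score against independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from dra.evaluate import evaluate_embedding, kmeans_cluster, nmi, run_baselines
from dra.io import LabelVector, ProcessedMatrix


def _three_blobs(rng, n_per=50, sigma=0.1, sep=5.0):
    centers = np.array([[0.0, 0.0], [sep, 0.0], [0.0, sep]])
    pts = np.vstack([c + sigma * rng.standard_normal((n_per, 2)) for c in centers])
    labels = LabelVector([i for i in range(3) for _ in range(n_per)])
    return pts, labels


class TestKMeans:
    def test_single_cluster(self):
        res = kmeans_cluster(np.random.default_rng(0).normal(size=(10, 2)), 1)
        assert set(res.assignments.labels) == {0}

    def test_k_equals_m_gives_singletons(self):
        pts = np.arange(8, dtype=float).reshape(4, 2) * 10
        res = kmeans_cluster(pts, 4, seed=0)
        assert len(set(res.assignments.labels)) == 4
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_blobs(self):
        pts, labels = _three_blobs(np.random.default_rng(1))
        res = kmeans_cluster(pts, 3, seed=0)
        assert nmi(res.assignments, labels) == pytest.approx(1.0)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), 4)


class TestNMI:
    def test_perfect_agreement(self):
        labs = LabelVector([0, 0, 1, 1, 2])
        assert nmi(labs, labs) == pytest.approx(1.0)

    def test_independent_design_is_zero(self):
        assert nmi(LabelVector([0, 0, 1, 1]), LabelVector([0, 1, 0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_contingency(self):
        # joint: p(0,0)=1/2, p(1,0)=1/4, p(1,1)=1/4; marginals (1/2,1/2), (3/4,1/4)
        mi = 0.5 * np.log(4 / 3) + 0.25 * np.log(2 / 3) + 0.25 * np.log(2)
        hx = np.log(2)
        hy = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        val = nmi(LabelVector([0, 0, 1, 1]), LabelVector([0, 0, 1, 0]))
        assert val == pytest.approx(mi / np.sqrt(hx * hy), rel=1e-12)
        assert val == pytest.approx(0.3456, abs=1e-4)

    def test_matches_sklearn_geometric_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 40)
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 3, n)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            ref = normalized_mutual_info_score(x, y, average_method="geometric")
            assert nmi(LabelVector(list(x)), LabelVector(list(y))) == pytest.approx(ref, abs=1e-10)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(5)
        x = LabelVector(list(rng.integers(0, 3, 30)))
        y = LabelVector(list(rng.integers(0, 4, 30)))
        assert nmi(x, y) == pytest.approx(nmi(y, x), rel=1e-12)
        renamed = LabelVector([f"type_{v}" for v in x.labels])
        assert nmi(renamed, y) == pytest.approx(nmi(x, y), rel=1e-12)

    def test_base_invariance(self):
        # recompute in bits: the ratio must be identical
        x = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        y = np.array([0, 1, 1, 1, 2, 0, 0, 2])
        n = len(x)
        table = np.zeros((3, 3))
        for a, b in zip(x, y):
            table[a, b] += 1
        pxy = table / n
        px, py = pxy.sum(1), pxy.sum(0)
        mi2 = sum(
            pxy[i, j] * np.log2(pxy[i, j] / (px[i] * py[j]))
            for i in range(3) for j in range(3) if pxy[i, j] > 0
        )
        h2 = lambda p: -sum(v * np.log2(v) for v in p if v > 0)
        assert nmi(LabelVector(list(x)), LabelVector(list(y))) == pytest.approx(
            mi2 / np.sqrt(h2(px) * h2(py)), rel=1e-12
        )

    def test_single_class_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            assert nmi(LabelVector([0, 0, 0]), LabelVector([0, 1, 2])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nmi(LabelVector([0, 1]), LabelVector([0, 1, 2]))


class TestEvaluateEmbedding:
    def test_three_blob_composition(self):
        pts, labels = _three_blobs(np.random.default_rng(2))
        assert evaluate_embedding(pts, labels, seed=0) == pytest.approx(1.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_embedding(np.zeros((5, 2)), LabelVector([0] * 5))

    def test_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(3)
        pts, labels = _three_blobs(rng)
        perm = rng.permutation(len(labels))
        a = evaluate_embedding(pts, labels, seed=0)
        b = evaluate_embedding(pts[perm], labels.subset(perm), seed=0)
        assert a == pytest.approx(b)

    def test_invariant_to_rotation(self):
        rng = np.random.default_rng(4)
        pts, labels = _three_blobs(rng)
        angle = 0.7
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        assert evaluate_embedding(pts @ R.T, labels, seed=0) == pytest.approx(
            evaluate_embedding(pts, labels, seed=0)
        )


class TestBaselines:
    def _processed(self, pts, n_genes):
        vals = np.abs(pts)
        return ProcessedMatrix(
            vals, list(range(vals.shape[1])),
            [f"g{i}" for i in range(vals.shape[1])],
            [f"c{i}" for i in range(vals.shape[0])],
        )

    def test_tsne_above_3_dims_reported_na(self):
        rng = np.random.default_rng(0)
        pts, labels = _three_blobs(rng, n_per=20)
        data = self._processed(pts, 2)
        table = run_baselines(data, ["tsne"], K=10, truth=labels, seed=0)
        assert len(table) == 1
        assert np.isnan(table.iloc[0]["nmi"])
        assert "N/A" in table.iloc[0]["note"]

    def test_pca_recovers_blobs_at_k2(self):
        rng = np.random.default_rng(1)
        pts, labels = _three_blobs(rng, n_per=30)
        table = run_baselines(self._processed(pts, 2), ["pca"], K=2, truth=labels, seed=0)
        assert table.iloc[0]["nmi"] == pytest.approx(1.0)

    def test_one_row_per_method(self):
        rng = np.random.default_rng(2)
        pts, labels = _three_blobs(rng, n_per=15)
        table = run_baselines(self._processed(pts, 2), ["pca", "tsne"], K=2,
                              truth=labels, seed=0)
        assert list(table["method"]) == ["pca", "tsne"]

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(3)
        pts, labels = _three_blobs(rng, n_per=10)
        with pytest.raises(ValueError):
            run_baselines(self._processed(pts, 2), ["zifa"], K=2, truth=labels, seed=0)
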