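import numpy as np
import pytest
from scipy import stats

import microviz as mv
from microviz.data_model import ValidationError
from microviz.community_structure import phylum_of


class TestPca:
    def test_single_axis_of_variation(self):
        m = np.array([[0.0, 0], [1, 2], [2, 4], [3, 6]])
        res = mv.pca(m)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(6, 3))
        res = mv.pca(m)
        centered = m - m.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # scores match projection onto eigenvectors up to sign
        for j in range(res.n_components):
            proj = centered @ evecs[:, j]
            assert np.allclose(np.abs(res.scores[:, j]), np.abs(proj), atol=1e-9)
        assert np.allclose(res.variance_explained, 100 * evals / evals.sum())

    def test_reconstruction(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(8, 5))
        res = mv.pca(m)
        recon = res.scores @ res.loadings.T
        assert np.allclose(recon, m - m.mean(axis=0), atol=1e-9)

    def test_scores_centered_and_variance_sums_100(self):
        rng = np.random.default_rng(3)
        res = mv.pca(rng.normal(size=(10, 4)))
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-9)
        assert res.variance_explained.sum() == pytest.approx(100.0)
        assert (np.diff(res.variance_explained) <= 1e-9).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(7, 4))
        a, b = mv.pca(m), mv.pca(m.copy())
        assert np.allclose(a.scores, b.scores)
        for j in range(a.n_components):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, j])), j] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            mv.pca(np.ones((4, 3)))


class TestGroupSeparation:
    def test_tight_far_clusters_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal([0, 0], 0.1, size=(6, 2))
        b = rng.normal([10, 10], 0.1, size=(6, 2))
        t, p = mv.group_separation_test(np.vstack([a, b]), ["a"] * 6 + ["b"] * 6)
        assert p < 0.01

    def test_shuffled_labels_null_uniformish(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        ps = []
        for _ in range(60):
            labels = list("aaabbbcccddd")
            rng.shuffle(labels)
            _, p = mv.group_separation_test(pts, labels)
            ps.append(p)
        assert 0.1 < np.mean(np.array(ps) < 0.5) < 0.9  # not pathologically skewed

    def test_identical_points_guarded(self):
        pts = np.zeros((6, 2))
        with pytest.warns(UserWarning):
            t, p = mv.group_separation_test(pts, ["a", "a", "a", "b", "b", "b"])
        assert p == 1.0

    def test_no_within_pairs_rejected(self):
        with pytest.raises(ValidationError):
            mv.group_separation_test(np.zeros((2, 2)), ["a", "b"])


class TestConfidenceEllipse:
    def test_isotropic_cloud_near_circular(self):
        rng = np.random.default_rng(7)
        e = mv.confidence_ellipse(rng.normal(size=(4000, 2)), level=0.87)
        assert e.semi_axes[0] / e.semi_axes[1] == pytest.approx(1.0, abs=0.1)

    def test_zero_level_degenerates_to_point(self):
        rng = np.random.default_rng(8)
        e = mv.confidence_ellipse(rng.normal(size=(10, 2)), level=0.0)
        assert e.semi_axes == (0.0, 0.0)

    def test_known_diagonal_covariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, [3.0, 1.0], size=(60_000, 2))
        e = mv.confidence_ellipse(pts, level=0.87)
        q = stats.chi2.ppf(0.87, 2)
        assert e.semi_axes[0] == pytest.approx(3 * np.sqrt(q), rel=0.05)
        assert e.semi_axes[1] == pytest.approx(1 * np.sqrt(q), rel=0.05)

    def test_singular_covariance_flagged(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.warns(UserWarning):
            e = mv.confidence_ellipse(pts)
        assert e.degenerate


class TestOverlap:
    def _table(self, cols):
        cols = np.asarray(cols, dtype=np.int64)
        return mv.OtuTable(
            [f"o{i}" for i in range(cols.shape[0])],
            [f"s{j}" for j in range(cols.shape[1])],
            cols,
        )

    def test_identical_sets_full_overlap(self):
        t = self._table([[3, 3], [2, 2]])
        o = mv.phylotype_overlap(t, ["s0", "s1"])
        assert (o.phylotype_overlap_pct, o.sequence_overlap_pct) == (100.0, 100.0)

    def test_disjoint_sets_zero(self):
        t = self._table([[3, 0], [0, 2]])
        o = mv.phylotype_overlap(t, ["s0", "s1"])
        assert (o.phylotype_overlap_pct, o.sequence_overlap_pct) == (0.0, 0.0)

    def test_jaccard_arithmetic(self):
        # sets {a,b,c} and {b,c,d}: 2 shared of 4 in the union
        t = self._table([[1, 0], [1, 1], [1, 1], [0, 1]])
        o = mv.phylotype_overlap(t, ["s0", "s1"])
        assert o.phylotype_overlap_pct == pytest.approx(50.0)

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        cols = rng.integers(0, 5, size=(20, 2))
        cols[0] += 1
        t = self._table(cols)
        a = mv.phylotype_overlap(t, ["s0", "s1"])
        b = mv.phylotype_overlap(t, ["s1", "s0"])
        perm = rng.permutation(20)
        t2 = self._table(cols[perm])
        c = mv.phylotype_overlap(t2, ["s0", "s1"])
        assert a.phylotype_overlap_pct == b.phylotype_overlap_pct == c.phylotype_overlap_pct

    def test_mean_fraction_denominator(self):
        t = self._table([[1, 0], [1, 1], [1, 1], [0, 1]])
        o = mv.phylotype_overlap(t, ["s0", "s1"], denominator="mean_fraction")
        assert o.phylotype_overlap_pct == pytest.approx(100 * (2 / 3 + 2 / 3) / 2)


class TestPhylumComposition:
    def test_single_phylum_is_100(self):
        t = mv.OtuTable(
            ["a"], ["s"], np.array([[5]]),
            taxonomy={"a": mv.parse_taxonomy_string("Bacteria1.0Firmicutes0.95")},
        )
        out = mv.phylum_composition(t, {"s": "g"})
        assert out.loc["g", "Firmicutes"] == 100.0

    def test_minor_phylum_pooled_into_other(self):
        t = mv.OtuTable(
            ["a", "b"], ["s"], np.array([[99], [1]]),
            taxonomy={
                "a": mv.parse_taxonomy_string("Bacteria1.0Firmicutes0.95"),
                "b": mv.parse_taxonomy_string("Bacteria1.0Fusobacteria0.95"),
            },
        )
        out = mv.phylum_composition(t, {"s": "g"})
        assert "Fusobacteria" not in out.columns
        assert out.loc["g", "Other"] == 1.0

    def test_low_confidence_goes_unclassified(self):
        t = mv.OtuTable(
            ["a"], ["s"], np.array([[5]]),
            taxonomy={"a": mv.parse_taxonomy_string("Bacteria1.0Firmicutes0.5")},
        )
        out = mv.phylum_composition(t, {"s": "g"})
        assert out.loc["g", "unclassified"] == 100.0

    def test_simulated_habitat_dominance(self, default_sim):
        """Simulated stool is Bacteroidetes-dominant, mucosa Firmicutes-
        dominant (the two habitats' template structure)."""
        table, meta, _ = default_sim
        group_by = {r.sample_id: r.habitat for r in meta.itertuples()}
        out = mv.phylum_composition(table, group_by)
        assert out.loc["stool", "Bacteroidetes"] > out.loc["stool", "Firmicutes"]
        assert out.loc["mucosa", "Firmicutes"] > out.loc["mucosa", "Bacteroidetes"]

    def test_phylum_lookup_threshold(self, toy_table):
        assert phylum_of(toy_table)["a"] == "Firmicutes"
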