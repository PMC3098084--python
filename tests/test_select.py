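"""Gene selection scorers, PCA projection and standardization."""

import numpy as np
import pytest
from scipy import stats

import maclust as mc
from maclust.select import ModeratedVarianceConfig

from test_preprocess import make_matrix


NU0_OFF = ModeratedVarianceConfig(nu0=0)


class TestScorers:
    def test_std_examples(self):
        m = make_matrix([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        s = mc.score_std(m)
        assert s[0] == 0.0
        assert s[1] == pytest.approx(1.0)
        shifted = make_matrix(m.values + 5.0)
        assert np.allclose(mc.score_std(shifted), s)

    def test_m_examples(self):
        m = make_matrix([[1.0, -1.0], [2.0, 2.0]])
        s = mc.score_m(m)
        assert s.tolist() == [0.0, 2.0]
        assert np.allclose(mc.score_m(make_matrix(-m.values)), s)

    def test_moderated_variance_formula(self):
        # n=3, s2=1, nu0=2, sigma0^2=4 -> (2*4 + 2*1)/(2+3-2) = 10/3
        vals = np.array([[-1.0, 0.0, 1.0]])
        out = mc.moderated_variance(vals, ModeratedVarianceConfig(nu0=2),
                                    sigma0=4.0)
        assert out[0] == pytest.approx(10.0 / 3.0)

    def test_moderated_variance_nu0_zero_is_sample_variance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 8))
        assert np.allclose(mc.moderated_variance(vals, NU0_OFF),
                           vals.var(axis=1, ddof=1))

    def test_constant_gene_regularized_to_positive(self):
        vals = np.vstack([np.zeros(5), np.random.default_rng(1).normal(size=(10, 5))])
        out = mc.moderated_variance(vals, ModeratedVarianceConfig(nu0=5, window=5))
        assert out[0] > 0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ModeratedVarianceConfig(nu0=-1)
        with pytest.raises(ValueError):
            ModeratedVarianceConfig(window=4)

    def test_t1_matches_classical_t_when_unmoderated(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(0.3, 1.0, size=(100, 12)))
        t1 = mc.score_t1(m, NU0_OFF)
        oracle = np.abs(stats.ttest_1samp(m.values, 0.0, axis=1).statistic)
        assert np.allclose(t1, oracle, atol=1e-10)

    def test_t1_example_and_scale_invariance(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        t = mc.score_t1(m, NU0_OFF)
        assert t[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        doubled = mc.score_t1(make_matrix([[2.0, 4.0, 6.0]]), NU0_OFF)
        assert doubled[0] == pytest.approx(t[0])
        centered = mc.score_t1(make_matrix([[-1.0, 0.0, 1.0]]), NU0_OFF)
        assert centered[0] == 0.0

    def test_t2_matches_welch_when_unmoderated(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(80, 14)))
        labels = np.array(["A"] * 6 + ["B"] * 8)
        t2 = mc.score_t2(m, labels, NU0_OFF)
        oracle = np.abs(stats.ttest_ind(
            m.values[:, :6], m.values[:, 6:], axis=1, equal_var=False).statistic)
        assert np.allclose(t2, oracle, atol=1e-10)

    def test_t2_example_and_label_symmetry(self):
        m = make_matrix([[0.0, 1.0, 2.0, 3.0]])
        labels = np.array(["A", "A", "B", "B"])
        t2 = mc.score_t2(m, labels, NU0_OFF)
        assert t2[0] == pytest.approx(2.0 / np.sqrt(0.5 / 2 + 0.5 / 2))
        swapped = mc.score_t2(m, np.where(labels == "A", "B", "A"), NU0_OFF)
        assert swapped[0] == pytest.approx(t2[0])

    def test_mdiff(self):
        m = make_matrix([[0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0]])
        labels = np.array(["A", "A", "B", "B"])
        d = mc.score_mdiff(m, labels)
        assert d.tolist() == [2.0, 0.0]

    def test_supervised_scorers_require_two_classes(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ValueError, match="2 classes"):
            mc.score_mdiff(m, np.array(["A"] * 4))
        with pytest.raises(ValueError, match=">= 2 samples"):
            mc.score_t2(m, np.array(["A", "B", "B", "B"]), NU0_OFF)

    def test_unsupervised_scorers_sample_permutation_equivariant(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(30, 10)))
        perm = rng.permutation(10)
        mp = make_matrix(m.values[:, perm])
        for fn in (mc.score_std, mc.score_m,
                   lambda x: mc.score_t1(x, NU0_OFF)):
            assert np.allclose(fn(m), fn(mp))


class TestSelectTop:
    def test_top_n_set_and_orientation(self):
        m = make_matrix(np.diag([3.0, 1.0, 2.0]),
                        gene_ids=["g1", "g2", "g3"])
        fm = mc.select_top(m, mc.score_std(m), 2)
        assert fm.feature_ids.tolist() == ["g1", "g3"]
        assert fm.values.shape == (3, 2)

    def test_tie_break_by_gene_id_and_nestedness(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 4, size=40).astype(float)  # many ties
        m = make_matrix(rng.normal(size=(40, 5)),
                        gene_ids=[f"g{i:02d}" for i in range(40)])
        prev: set = set()
        for n in (1, 5, 17, 40):
            sel = set(mc.select_top(m, scores, n).feature_ids)
            assert prev <= sel
            prev = sel
        # all-tied scores: lexicographically smallest IDs win
        fm = mc.select_top(m, np.zeros(40), 3)
        assert fm.feature_ids.tolist() == ["g00", "g01", "g02"]

    def test_n_larger_than_gene_count_errors(self):
        m = make_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError):
            mc.select_top(m, np.zeros(3), 4)

    def test_full_selection_is_a_permutation(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(10, 4)))
        fm = mc.select_top(m, mc.score_std(m), 10)
        assert sorted(fm.feature_ids) == sorted(m.gene_ids)


class TestSelectPC:
    def test_full_projection_preserves_sample_distances(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(20, 6)))
        fm = mc.select_pc(m, 6)
        centered = m.values - m.values.mean(axis=1, keepdims=True)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(fm.values), pdist(centered.T), atol=1e-8)

    def test_leading_component_captures_planted_axis(self):
        rng = np.random.default_rng(8)
        # gene values driven by one strong sample factor + isotropic noise
        factor = rng.normal(size=12) * 5.0
        loadings = rng.normal(size=30)
        m = make_matrix(np.outer(loadings, factor)
                        + rng.normal(0, 0.5, size=(30, 12)))
        fm = mc.select_pc(m, 3)
        var = fm.values.var(axis=0)
        assert var[0] / var.sum() > 0.8
        assert var[0] >= var[1] >= var[2]

    def test_duplicated_sample_gives_identical_rows(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(15, 5))
        vals[:, 4] = vals[:, 0]
        fm = mc.select_pc(make_matrix(vals), 3)
        assert np.allclose(fm.values[0], fm.values[4], atol=1e-10)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            mc.select_pc(make_matrix(np.ones((4, 3))), 4)


class TestStandardize:
    def test_z_transform_and_identity(self):
        fm = mc.FeatureMatrix(np.array([[1.0], [2.0], [3.0]]),
                              ["S1", "S2", "S3"], ["g"])
        out = mc.standardize(fm, on=True)
        assert np.allclose(out.values.ravel(), [-1.0, 0.0, 1.0])
        off = mc.standardize(fm, on=False)
        assert np.array_equal(off.values, fm.values)

    def test_constant_feature_zeroed_with_warning(self):
        fm = mc.FeatureMatrix(np.array([[1.0, 5.0], [1.0, 7.0]]),
                              ["S1", "S2"], ["g1", "g2"])
        with pytest.warns(UserWarning, match="constant"):
            out = mc.standardize(fm)
        assert np.allclose(out.values[:, 0], 0.0)
        assert np.allclose(out.values[:, 1], [-np.sqrt(0.5), np.sqrt(0.5)])


def test_select_features_dispatch(small_matrix):
    m, truth = small_matrix
    for spec, expected in [
        (mc.SelectionSpec("STD", 50), 50),
        (mc.SelectionSpec("PC", 5), 5),
        (mc.SelectionSpec("NONE"), m.n_genes),
        (mc.SelectionSpec("T2", 20), 20),
    ]:
        fm = mc.select_features(m, spec, labels=truth)
        assert fm.n_features == expected
        assert fm.n_samples == m.n_samples
    with pytest.raises(ValueError, match="labels"):
        mc.select_features(m, mc.SelectionSpec("T2", 10))
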