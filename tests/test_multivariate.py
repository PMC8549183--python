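"""Statistics engine: scaling, ordination, clustering, tests, discriminants."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis as LDA

from erbody import multivariate as mv


def procrustes_error(a, b):
    """Residual after optimal rigid alignment (rotation + translation)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    r, _ = orthogonal_procrustes(a, b)
    return float(np.abs(a @ r - b).max())


class TestZscore:
    def test_basic_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = mv.zscore(df)
        np.testing.assert_allclose(out["x"], [-1, 0, 1])

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0], "y": [1.0, 2.0, 3.0]})
        out = mv.zscore(df)
        assert (out["x"] == 0).all()
        assert out.attrs["constant_columns"] == ["x"]

    def test_stratified_moments(self, rng):
        df = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10,
            "x": np.r_[rng.normal(5, 2, 10), rng.normal(-3, 0.5, 10)],
        })
        out = mv.zscore(df, columns=["x"], strata="g")
        for g in ("a", "b"):
            sub = out.loc[out["g"] == g, "x"]
            assert sub.mean() == pytest.approx(0, abs=1e-12)
            assert sub.std(ddof=1) == pytest.approx(1, abs=1e-12)


class TestPccDistance:
    def test_identical_rows_zero(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], (3, 1))
        x = x + np.arange(3)[:, None] * 0  # identical profiles
        d = mv.pcc_distance(x)
        np.testing.assert_allclose(d, 0, atol=1e-12)

    def test_anticorrelated_rows_two(self):
        x = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        d = mv.pcc_distance(x)
        assert d[0, 1] == pytest.approx(2.0)

    def test_matches_direct_correlation(self, rng):
        x = rng.normal(size=(5, 10))
        d = mv.pcc_distance(x)
        for i in range(5):
            for j in range(5):
                r = np.corrcoef(x[i], x[j])[0, 1]
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_degenerate_profile_distance_one(self):
        x = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = mv.pcc_distance(x)
        assert d[0, 1] == 1.0 and d[0, 2] == 1.0 and d[0, 0] == 0.0


class TestClassicalMDS:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(4, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = mv.classical_mds(d, 2)
        assert procrustes_error(res.coordinates, pts) < 1e-9

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = np.abs(pts - pts.T)
        with pytest.warns(UserWarning):
            res = mv.classical_mds(d, 2)
        assert res.axis_fractions[0] == pytest.approx(1.0)

    def test_eigenvalues_match_dense_oracle(self, rng):
        x = rng.normal(size=(8, 5))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        res = mv.classical_mds(d, 3)
        a = -0.5 * d ** 2
        j = np.eye(8) - np.ones((8, 8)) / 8
        evals = np.sort(np.linalg.eigvalsh(j @ a @ j))[::-1]
        np.testing.assert_allclose(res.eigenvalues[:3], evals[:3], atol=1e-9)

    def test_matches_skbio_pcoa(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        x = rng.normal(size=(10, 4))
        d = mv.pcc_distance(x)
        res = mv.classical_mds(d, 3)
        pc = pcoa(skbio.DistanceMatrix(d), number_of_dimensions=3)
        np.testing.assert_allclose(res.eigenvalues[:3], pc.eigvals.values[:3],
                                   atol=1e-8)


class TestKmeansAIC:
    def test_recovers_three_separated_clusters(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.vstack([r.normal(size=(100, 5)) + c
                           for c in (0.0, 10.0, 20.0)])
            res = mv.kmeans_aic(x, (2, 8), restarts=3, rng_seed=seed)
            hits += res.k_selected == 3
        assert hits >= 9

    def test_single_blob_selects_minimum(self):
        x = np.random.default_rng(3).normal(size=(200, 4))
        res = mv.kmeans_aic(x, (2, 8), restarts=3, rng_seed=0)
        assert res.k_selected == 2

    def test_labels_invariant_to_feature_permutation(self, rng):
        x = rng.normal(size=(60, 6)) + np.repeat([0, 8], 30)[:, None]
        res1 = mv.kmeans_aic(x, (2, 4), 3, rng_seed=5)
        res2 = mv.kmeans_aic(x[:, ::-1], (2, 4), 3, rng_seed=5)
        # same partition up to label renaming
        assert len(set(zip(res1.labels, res2.labels))) == len(set(res1.labels))

    def test_wcss_matches_labels(self, rng):
        x = rng.normal(size=(50, 3))
        res = mv.kmeans_aic(x, (3, 3), 3, rng_seed=1)
        wcss = sum(((x[res.labels == k] - x[res.labels == k].mean(0)) ** 2).sum()
                   for k in np.unique(res.labels))
        assert res.wcss == pytest.approx(wcss, rel=1e-9)


class TestConstrainedOrdination:
    def test_fraction_matches_anova_decomposition(self, rng):
        """With no conditions, the constrained share equals the between-group
        share of the principal-coordinate inertia."""
        g = np.repeat(["a", "b"], 15)
        pat = np.array([1, -1, 1, 0, 0, -1.0])
        x = rng.normal(size=(30, 6)) + (g[:, None] == "b") * pat * 2
        res = mv.constrained_ordination(x, g)
        # oracle: ANOVA decomposition of the PCo coordinates
        d = mv.pcc_distance(x)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y = mv.classical_mds(d, 29).coordinates
        yc = y - y.mean(axis=0)
        between = sum(
            (g == lev).sum() * (y[g == lev].mean(0) - y.mean(0)) ** 2
            for lev in ("a", "b")
        ).sum()
        total = (yc ** 2).sum()
        assert res.constrained_fraction == pytest.approx(between / total, rel=1e-6)

    def test_null_fraction_near_expectation(self, rng):
        n, g_levels = 60, 3
        fracs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=(n, 10))
            g = np.tile(["a", "b", "c"], n // 3)
            fracs.append(mv.constrained_ordination(x, g).constrained_fraction)
        assert np.mean(fracs) == pytest.approx((g_levels - 1) / (n - 1), abs=0.02)

    def test_effect_monotonicity(self):
        rng = np.random.default_rng(4)
        g = np.repeat(["a", "b", "c"], 20)
        pat = np.array([1, -1, 0.5, -0.5, 1, 0, 0, -1])
        base = rng.normal(size=(60, 8))
        fracs = []
        for eff in (0.3, 1.0, 3.0):
            x = base + (g[:, None] == "b") * pat * eff \
                + (g[:, None] == "c") * pat[::-1] * eff
            fracs.append(mv.constrained_ordination(x, g).constrained_fraction)
        assert fracs[0] < fracs[1] < fracs[2]

    def test_confounded_design_rejected(self, rng):
        x = rng.normal(size=(20, 5))
        g = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="confounded"):
            mv.constrained_ordination(x, g, conditions=[g])


class TestPermanova:
    def test_maximal_separation_minimal_p(self):
        base = np.array([[0.0] * 4, [10.0] * 4])
        x = np.repeat(base, 10, axis=0) + np.random.default_rng(0).normal(
            scale=1e-6, size=(20, 4))
        g = np.repeat(["a", "b"], 10)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        res = mv.permanova(d, g, permutations=199, rng_seed=0)
        # only a permutation that exactly reproduces the two-cluster split can
        # tie the observed F, so p sits at (or within a tie or two of) the floor
        assert res.p_value <= 3 / 200

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.normal(size=(18, 5))
        g = list(np.repeat(["a", "b", "c"], 6))
        d = mv.pcc_distance(x)
        ours = mv.permanova(d, g, permutations=99, rng_seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(d), grouping=g, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_invariant_to_joint_relabelling(self, rng):
        x = rng.normal(size=(12, 4))
        g = np.repeat(["a", "b"], 6)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        perm = rng.permutation(12)
        r1 = mv.permanova(d, g, permutations=199, rng_seed=7)
        r2 = mv.permanova(d[np.ix_(perm, perm)], g[perm], permutations=199,
                          rng_seed=7)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)

    def test_strata_restrict_permutations(self, rng):
        """Within-stratum shuffling preserves the stratum composition."""
        x = rng.normal(size=(16, 4)) + np.repeat([0, 3], 8)[:, None]
        g = np.tile(np.repeat(["a", "b"], 4), 2)
        strata = np.repeat(["s1", "s2"], 8)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        res = mv.permanova(d, g, conditions=[strata], permutations=99, rng_seed=0)
        assert 0 < res.p_value <= 1

    def test_single_level_rejected(self, rng):
        d = np.zeros((6, 6))
        with pytest.raises(ValueError):
            mv.permanova(d, ["a"] * 6, permutations=99)


class TestDiscriminants:
    def test_fda_perfect_on_separable_classes(self, rng):
        x = np.vstack([rng.normal(size=(20, 4)),
                       rng.normal(size=(20, 4)) + 8])
        y = np.repeat(["a", "b"], 20)
        model = mv.fda_fit(x, y)
        cm = mv.confusion_matrix(y, model.predict(x))
        assert cm.loc["a", "a"] == 1.0 and cm.loc["b", "b"] == 1.0

    def test_fda_equals_lda(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = np.repeat(["a", "b", "c"], 15)
            x = r.normal(size=(45, 6)) + (y[:, None] == "b") * 1.5 \
                + (y[:, None] == "c") * np.array([1, -1, 0, 1, 0, -1.0])
            ours = mv.fda_fit(x, y).predict(x)
            theirs = LDA().fit(x, y).predict(x)
            assert (ours == theirs).all(), f"seed {seed}"

    def test_shuffled_labels_near_chance(self, rng):
        x = rng.normal(size=(90, 5))
        y = rng.permutation(np.repeat(["a", "b", "c"], 30))
        cm = mv.confusion_matrix(y, mv.fda_fit(x, y).predict(x))
        diag = np.diag(cm.to_numpy()).mean()
        assert diag < 0.75  # far from the separable case's 1.0

    def test_mda_subclass1_equals_lda(self, rng):
        y = np.repeat(["a", "b"], 25)
        x = rng.normal(size=(50, 4)) + (y[:, None] == "b") * 2
        ours = mv.mda_fit(x, y, subclasses=1, rng_seed=0).predict(x)
        theirs = LDA().fit(x, y).predict(x)
        assert (ours == theirs).all()

    def test_mda_beats_fda_on_bimodal_class(self):
        rng = np.random.default_rng(8)
        # class a bimodal at -6 and +6; class b unimodal at 0
        xa = np.vstack([rng.normal(size=(30, 3)) - 6,
                        rng.normal(size=(30, 3)) + 6])
        xb = rng.normal(size=(60, 3))
        x = np.vstack([xa, xb])
        y = np.repeat(["a", "b"], 60)
        acc = lambda pred: (pred == y).mean()
        fda_acc = acc(mv.fda_fit(x, y).predict(x))
        mda_acc = acc(mv.mda_fit(x, y, subclasses=2, rng_seed=0).predict(x))
        assert mda_acc > fda_acc

    def test_mda_loglik_nondecreasing(self, rng):
        y = np.repeat(["a", "b"], 30)
        x = rng.normal(size=(60, 4)) + (y[:, None] == "b") * 1.0
        model = mv.mda_fit(x, y, subclasses=2, rng_seed=1)
        diffs = np.diff(model.log_likelihood_trace)
        assert (diffs >= -1e-6).all()

    def test_confusion_rows_sum_to_one(self, rng):
        y = np.repeat(["a", "b", "c"], 10)
        pred = rng.choice(["a", "b", "c"], 30)
        cm = mv.confusion_matrix(y, pred)
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)


class TestGroupwiseTests:
    def test_identical_groups_not_flagged(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 30), "f1": np.tile(x[:30], 2)})
        out = mv.groupwise_tests(df, "g", ["f1"])
        assert not out["significant"].any()

    def test_shifted_feature_flagged(self, rng):
        df = pd.DataFrame({
            "g": np.repeat(["a", "b"], 50),
            "hit": np.r_[rng.normal(0, 1, 50), rng.normal(5, 1, 50)],
            "null1": rng.normal(size=100),
            "null2": rng.normal(size=100),
        })
        out = mv.groupwise_tests(df, "g", ["hit", "null1", "null2"]).set_index("feature")
        assert out.loc["hit", "significant"]
        assert out.loc["hit", "q"] <= 0.05

    def test_bh_matches_step_up_enumeration(self):
        # hand-enumerated BH on p = {0.001, 0.01, 0.02, 0.5}
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.01, 0.02, 0.5])
        q = multipletests(p, method="fdr_bh")[1]
        expected = [0.004, 0.02 * 4 / 3, 0.02, 0.5]
        # step-up: q_i = min_{j>=i} p_j * n / j
        expected = [min(0.004, 0.02, 0.0266667, 0.5),
                    min(0.02, 0.0266667, 0.5),
                    min(0.0266667, 0.5), 0.5]
        np.testing.assert_allclose(q, expected, atol=1e-6)


class TestClusterReport:
    def test_composition_and_flags(self, rng):
        n = 40
        labels = np.repeat([1, 2], 20)
        df = pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(n)],
            "genotype": np.repeat(["wt", "mut"], 20),
            "s.area": rng.random(n) + 1,
        })
        res = mv.ClusteringResult(labels, np.zeros((2, 1)), 0.0, {2: 0.0}, 2)
        counts = np.r_[np.zeros(20), np.ones(20)]
        rep = mv.cluster_report(res, df, object_counts=counts, rng_seed=0)
        rep = rep.set_index("cluster")
        assert not rep.loc[1, "has_erbody"]
        assert rep.loc[2, "has_erbody"]
        props = rep.filter(like="prop.").fillna(0)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_exemplars_reproducible(self, rng):
        df = pd.DataFrame({"feature_id": [f"f{i}" for i in range(30)],
                           "genotype": ["wt"] * 30, "x": rng.random(30)})
        res = mv.ClusteringResult(np.ones(30, int), np.zeros((1, 1)), 0.0, {1: 0.0}, 1)
        r1 = mv.cluster_report(res, df, rng_seed=3)
        r2 = mv.cluster_report(res, df, rng_seed=3)
        assert r1["exemplars"].equals(r2["exemplars"])
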