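"""PCA, PLS/OPLS-DA, VIP, S-plot selection, Wilcoxon, HCA."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.cross_decomposition import PLSRegression

from metabodiv import (Preprocessing, cluster_support, discriminative_features,
                       hca, impute_half_min, log_transform, opls_da, pca,
                       pls_da, select_candidates, vip, wilcoxon_select)

CENTER_ONLY = Preprocessing(center=True, scaling="none")


def _two_group_data(rng, n_per_group=10, n_features=50, n_informative=5,
                    shift=2.0):
    """Gaussian features; the first n_informative are shifted in group B."""
    X = rng.normal(0, 1, size=(2 * n_per_group, n_features))
    X[n_per_group:, :n_informative] += shift
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    return X, labels


class TestPCA:
    def test_single_varying_feature_gets_unit_loading(self):
        X = np.zeros((6, 4))
        X[:, 2] = [1, 2, 3, 4, 5, 6]
        res = pca(X, n_components=1, prep=CENTER_ONLY)
        assert abs(res.loadings[2, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_samples_identical_scores(self, rng):
        X = rng.normal(size=(5, 8))
        X2 = np.vstack([X, X[2]])
        res = pca(X2, n_components=2, prep=CENTER_ONLY)
        assert np.allclose(res.scores[2], res.scores[-1], atol=1e-10)

    def test_explained_variance_non_increasing(self, rng):
        X = rng.normal(size=(12, 20))
        res = pca(X, n_components=5)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.normal(size=(4, 10))
        with pytest.warns(UserWarning, match="rank"):
            res = pca(X, n_components=9)
        assert res.scores.shape[1] <= 4

    def test_planted_groups_separate(self, rng):
        X, labels = _two_group_data(rng, n_per_group=10, shift=3.0)
        res = pca(X, n_components=2)
        t = res.scores[:, :2]
        a, b = t[:10], t[10:]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = 0.5 * (np.mean(np.linalg.norm(a - a.mean(0), axis=1)) +
                        np.mean(np.linalg.norm(b - b.mean(0), axis=1)))
        assert between / within > 2


class TestPLSOPLS:
    def test_single_informative_feature_concentrates_weight(self, rng):
        X = rng.normal(0, 0.001, size=(20, 10))
        y01 = np.repeat([0, 1], 10)
        X[:, 3] += y01 * 5.0
        model = opls_da(X, ["A" if v == 0 else "B" for v in y01], n_orth=0,
                        prep=CENTER_ONLY)
        w = model.weights[:, 0]
        assert abs(w[3]) > 0.99

    def test_opls_zero_orth_equals_plsda(self, rng):
        X, labels = _two_group_data(rng)
        m1 = opls_da(X, labels, n_orth=0)
        m2 = pls_da(X, labels, n_components=1)
        assert np.allclose(m1.scores, m2.scores, atol=1e-8)
        assert np.allclose(m1.weights, m2.weights, atol=1e-8)

    def test_matches_sklearn_pls_first_component(self, rng):
        """Independent oracle: scikit-learn NIPALS PLS on the same scaled data."""
        X, labels = _two_group_data(rng)
        model = pls_da(X, labels, n_components=1, prep=CENTER_ONLY)
        y = np.where(np.asarray(labels) == "B", 1.0, -1.0)
        sk = PLSRegression(n_components=1, scale=False).fit(X - X.mean(0), y)
        t_sk = sk.x_scores_[:, 0]
        t_my = model.scores[:, 0]
        sign = np.sign(t_sk @ t_my)
        assert np.allclose(t_my, sign * t_sk, atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_predictive(self, rng):
        X, labels = _two_group_data(rng, n_features=30)
        model = opls_da(X, labels, n_orth=2)
        t1 = model.scores[:, 0]
        for k in range(model.orth_scores.shape[1]):
            r = np.corrcoef(t1, model.orth_scores[:, k])[0, 1]
            assert abs(r) < 1e-6

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 5))
        with pytest.raises(ValueError):
            opls_da(X, ["A"] * 6)

    def test_vip_recovery_auroc(self, rng):
        # planted informative features should rank above noise by VIP
        X, labels = _two_group_data(rng, n_per_group=20, n_features=200,
                                    n_informative=10, shift=2.0)
        model = opls_da(X, labels, n_orth=1)
        v = vip(model)
        planted = np.zeros(200, dtype=bool)
        planted[:10] = True
        # AUROC via the Mann-Whitney U statistic
        from scipy.stats import mannwhitneyu
        u = mannwhitneyu(v[planted], v[~planted], alternative="greater")
        auroc = u.statistic / (planted.sum() * (~planted).sum())
        assert auroc >= 0.95


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        from metabodiv.multivariate import LatentModel
        p = 6
        w = np.full((p, 1), 1 / np.sqrt(p))
        model = LatentModel(prep=CENTER_ONLY, classes=("A", "B"),
                            y=np.array([-1.0, 1.0]),
                            scores=np.zeros((2, 1)), loadings=w.copy(),
                            weights=w, y_loadings=np.array([1.0]),
                            ssy=np.array([1.0]))
        assert np.allclose(vip(model), 1.0)

    def test_one_hot_weight_vip(self):
        from metabodiv.multivariate import LatentModel
        w = np.array([[1.0], [0.0], [0.0], [0.0]])
        model = LatentModel(prep=CENTER_ONLY, classes=("A", "B"),
                            y=np.array([-1.0, 1.0]),
                            scores=np.zeros((2, 1)), loadings=w.copy(),
                            weights=w, y_loadings=np.array([1.0]),
                            ssy=np.array([1.0]))
        assert np.allclose(vip(model), [2.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sum_vip_squared_equals_p(self, seed):
        rng = np.random.default_rng(seed)
        X, labels = _two_group_data(rng, n_features=37)
        for model in (pls_da(X, labels, n_components=3),
                      opls_da(X, labels, n_orth=1)):
            v = vip(model)
            assert v @ v == pytest.approx(model.n_features, rel=1e-6)


class TestSelectCandidates:
    def test_max_feature_selected(self, rng):
        X, labels = _two_group_data(rng, n_informative=1, shift=4.0)
        model = opls_da(X, labels, n_orth=0)
        sel = select_candidates(model)
        j_covmax = int(np.argmax(np.abs(model.cov_t1)))
        assert j_covmax in sel

    def test_90_40_feature_rejected(self):
        from metabodiv.multivariate import LatentModel
        model = LatentModel(prep=CENTER_ONLY, classes=("A", "B"),
                            y=np.array([-1.0, 1.0]),
                            scores=np.zeros((2, 1)),
                            loadings=np.zeros((2, 1)),
                            weights=np.zeros((2, 1)),
                            y_loadings=np.array([1.0]), ssy=np.array([1.0]),
                            cov_t1=np.array([1.0, 0.9]),
                            corr_t1=np.array([1.0, 0.4]))
        assert select_candidates(model).tolist() == [0]

    def test_all_zero_covariance_empty(self):
        from metabodiv.multivariate import LatentModel
        model = LatentModel(prep=CENTER_ONLY, classes=("A", "B"),
                            y=np.array([-1.0, 1.0]),
                            scores=np.zeros((2, 1)),
                            loadings=np.zeros((2, 1)),
                            weights=np.zeros((2, 1)),
                            y_loadings=np.array([1.0]), ssy=np.array([1.0]),
                            cov_t1=np.zeros(3), corr_t1=np.zeros(3))
        assert select_candidates(model).size == 0


class TestWilcoxon:
    def test_exact_p_n3_vs_n3(self):
        X = np.array([[1], [2], [3], [10], [11], [12]], dtype=float)
        tab = wilcoxon_select(X, ["A", "A", "A", "B", "B", "B"])
        assert tab.loc[0, "p"] == pytest.approx(0.100, abs=1e-9)
        assert not tab.loc[0, "selected"]

    def test_exact_p_n4_vs_n4_complete_separation(self):
        X = np.array([[1], [2], [3], [4], [10], [11], [12], [13]], dtype=float)
        tab = wilcoxon_select(X, list("AAAABBBB"))
        assert tab.loc[0, "p"] == pytest.approx(2 / 70, abs=1e-4)
        assert bool(tab.loc[0, "selected"])

    def test_identical_groups_p_one(self):
        X = np.array([[5.0]] * 8)
        tab = wilcoxon_select(X, list("AAAABBBB"))
        assert tab.loc[0, "p"] == pytest.approx(1.0)
        assert not tab.loc[0, "selected"]

    def test_q_values_bh_monotone(self, rng):
        X, labels = _two_group_data(rng, n_features=40)
        tab = wilcoxon_select(X, labels)
        assert (tab["q"] >= tab["p"] - 1e-12).all()


class TestHCA:
    def test_identical_samples_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        z = hca(X, method="single", prep=None)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_single_linkage_1d_hand_case(self):
        X = np.array([[0.0], [1.0], [10.0]])
        z = hca(X, method="single", prep=None)
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(9.0)

    def test_heights_non_decreasing(self, rng):
        X = rng.normal(size=(12, 6))
        z = hca(X, method="average", prep=None)
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_unknown_linkage_rejected(self, rng):
        with pytest.raises(ValueError, match="linkage"):
            hca(rng.normal(size=(4, 3)), method="banana")


class TestPipeline:
    def test_planted_recovery_precision_recall(self, small_study):
        truth = small_study["truth"]
        fm = small_study["matrix"]
        labels = fm.sample_meta["age_class"].to_numpy()
        res = discriminative_features(fm, labels)
        from metabodiv.formula_assignment import PROTON_MASS
        planted_m = truth.masses[np.concatenate(
            list(truth.accessory_idx.values()))] + PROTON_MASS
        planted = {j for j, mz in enumerate(fm.feature_mzs)
                   if np.min(np.abs(planted_m - mz)) / mz * 1e6 < 1.0}
        sel = set(res["selected"])
        tp = len(sel & planted)
        assert tp / max(len(sel), 1) >= 0.8
        assert tp / len(planted) >= 0.8

    def test_per_group_split_orientation(self, small_study):
        truth = small_study["truth"]
        fm = small_study["matrix"]
        labels = fm.sample_meta["age_class"].to_numpy()
        res = discriminative_features(fm, labels)
        from metabodiv.formula_assignment import PROTON_MASS
        old_m = truth.masses[truth.accessory_idx["old"]] + PROTON_MASS
        old_sel = res["per_group"]["old"]
        hits = sum(1 for j in old_sel
                   if np.min(np.abs(old_m - fm.feature_mzs[j]))
                   / fm.feature_mzs[j] * 1e6 < 1.0)
        assert hits / max(len(old_sel), 1) >= 0.9

    def test_cluster_support_detects_real_and_rejects_random(self, rng):
        X, labels = _two_group_data(rng, n_per_group=14, n_features=60,
                                    n_informative=12, shift=2.0)
        real = cluster_support(X, labels, n_permutations=50, seed=5)
        assert real["supported"]
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        random_out = cluster_support(X, shuffled, n_permutations=50, seed=5)
        assert not random_out["supported"]


class TestTransforms:
    def test_log_transform_monotone_and_zero_preserving(self, small_study):
        fm = small_study["matrix"]
        lt = log_transform(fm)
        assert lt.values[fm.values == 0].sum() == 0
        assert (lt.values[fm.values > 0] > 0).all()

    def test_impute_half_min_fills_zeros_only(self, small_study):
        fm = small_study["matrix"]
        im = impute_half_min(fm)
        nz = fm.values > 0
        assert np.array_equal(im.values[nz], fm.values[nz])
        filled = im.values[~nz]
        assert (filled > 0).all() or filled.size == 0
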