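"""Z-normalization, PCA and varimax properties."""

import numpy as np
import pandas as pd
import pytest

from pianism.spaces import VarimaxPCA, ZScaler, _varimax_criterion, plot_space, varimax, zscore


class TestZScore:
    def test_closed_form(self):
        z = zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["x"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"x": rng.normal(size=100)})
        once = zscore(tab)
        twice = zscore(once)
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(rng.normal(5, 3, size=(60, 4)), columns=list("abcd"))
        z = zscore(tab)
        assert np.abs(z.mean()).max() < 1e-9
        assert np.abs(z.std(ddof=0) - 1).max() < 1e-9

    def test_constant_column_dropped(self):
        tab = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning, match="zero-SD"):
            z = zscore(tab)
        assert list(z.columns) == ["x"]

    def test_missing_values_propagate(self):
        tab = pd.DataFrame({"x": [1.0, np.nan, 3.0, 5.0]})
        z = zscore(tab)
        assert np.isnan(z["x"][1]) and not np.isnan(z["x"][0])


class TestPCA:
    def test_rank_one_table(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=6)
        X = np.outer(rng.normal(size=40), v) + 1e-6 * rng.normal(size=(40, 6))
        space = VarimaxPCA(n_components=1, rotation="none").fit(X)
        assert space.variance_fraction_[0] >= 0.999

    def test_isotropic_noise_fractions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 10))
        space = VarimaxPCA(n_components=10, rotation="none").fit(X)
        assert np.all(np.abs(space.variance_fraction_ - 0.1) < 0.05)

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 7)) @ np.diag([3, 2, 1.5, 1, 1, 0.5, 0.2])
        space = VarimaxPCA(n_components=4, rotation="none").fit(X)
        cov = (space.scores_.T @ space.scores_) / X.shape[0]
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction_error_equals_discarded_mass(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 9))
        Z = (X - X.mean(0)) / X.std(0)
        space = VarimaxPCA(n_components=3, rotation="varimax").fit(Z)
        resid = (Z - Z.mean(0)) - space.scores_ @ space.loadings_.T
        s = np.linalg.svd(Z - Z.mean(0), compute_uv=False)
        assert (resid**2).sum() == pytest.approx(float((s**2)[3:].sum()), abs=1e-8)

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(6).normal(size=(5, 3))
        with pytest.raises(ValueError):
            VarimaxPCA(n_components=4).fit(X)

    def test_variance_fractions_nonincreasing_unrotated(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 8))
        space = VarimaxPCA(n_components=5, rotation="none").fit(X)
        assert np.all(np.diff(space.variance_fraction_) <= 1e-12)

    def test_rotation_is_orthogonal(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 8))
        space = VarimaxPCA(n_components=3, rotation="varimax").fit(X)
        R = space.rotation_matrix_
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.allclose(space.loadings_, space.unrotated_loadings_ @ R, atol=1e-10)


class TestVarimax:
    def test_two_component_matches_grid_search(self):
        """Pairwise rotation reaches the best criterion on a fine angle grid."""
        rng = np.random.default_rng(9)
        L = rng.normal(size=(12, 2))
        rotated, _ = varimax(L)
        comm = np.sqrt((L**2).sum(axis=1))
        W = L / comm[:, None]
        best = max(
            _varimax_criterion(W @ np.array([[np.cos(a), -np.sin(a)],
                                             [np.sin(a), np.cos(a)]]))
            for a in np.arange(0.0, np.pi / 2, 1e-4)
        )
        assert _varimax_criterion(rotated / comm[:, None]) == pytest.approx(best, abs=1e-6)

    def test_already_optimal_is_fixed_point(self):
        rng = np.random.default_rng(10)
        L = rng.normal(size=(15, 3))
        first, _ = varimax(L)
        second, R = varimax(first)
        # identity up to column sign/permutation
        perm = np.abs(R)
        assert np.allclose(perm @ perm.T, np.eye(3), atol=1e-5)
        assert np.allclose(np.sort(np.abs(R).max(axis=0)), [1, 1, 1], atol=1e-5)

    def test_criterion_never_decreases(self):
        """Each accepted pairwise rotation is an ascent step."""
        rng = np.random.default_rng(11)
        L = rng.normal(size=(20, 4))
        comm = np.sqrt((L**2).sum(axis=1))
        rotated, _ = varimax(L)
        assert _varimax_criterion(rotated / comm[:, None]) >= _varimax_criterion(
            L / comm[:, None]
        ) - 1e-12

    def test_single_component_unchanged(self):
        L = np.arange(5.0).reshape(-1, 1)
        rotated, R = varimax(L)
        assert np.allclose(rotated, L) and R.shape == (1, 1)


class TestPlots:
    def test_three_component_space_emits_three_planes(self, small_table, tmp_path):
        feats = [c for c in small_table.columns[4:]
                 if small_table[c].notna().all() and small_table[c].std() > 0][:40]
        Z = ZScaler().fit_transform(small_table[feats])
        space = VarimaxPCA(n_components=3).fit(Z.to_numpy())
        paths = plot_space(space, small_table[["pianist", "piece", "timbre", "repetition"]],
                           out_prefix=str(tmp_path / "space"))
        assert len(paths) == 3

    def test_two_component_space_emits_one_plane(self, small_table, tmp_path):
        feats = [c for c in small_table.columns[4:]
                 if small_table[c].notna().all() and small_table[c].std() > 0][:20]
        Z = ZScaler().fit_transform(small_table[feats])
        space = VarimaxPCA(n_components=2, rotation="none").fit(Z.to_numpy())
        paths = plot_space(space, small_table[["pianist", "piece", "timbre", "repetition"]],
                           out_prefix=str(tmp_path / "space"))
        assert len(paths) == 1

    def test_unknown_dims_rejected(self, small_table):
        feats = [c for c in small_table.columns[4:]
                 if small_table[c].notna().all() and small_table[c].std() > 0][:10]
        Z = ZScaler().fit_transform(small_table[feats])
        space = VarimaxPCA(n_components=2, rotation="none").fit(Z.to_numpy())
        with pytest.raises(ValueError, match="dims"):
            plot_space(space, small_table[["pianist", "piece", "timbre", "repetition"]],
                       dims=[(0, 5)])


def test_separated_profiles_give_disjoint_se_ellipses(small_table):
    """Strongly separated pianists yield non-overlapping +/-1 SE regions."""
    feats = ["all.mhv_cmean_pmean", "all.articulation_same_hand_pmean",
             "all.amax_cmean_pmean", "all.attack_duration_cmean_pmean"]
    Z = ZScaler().fit_transform(small_table[feats])
    space = VarimaxPCA(n_components=2, rotation="none").fit(Z.to_numpy())
    frame = small_table[["pianist"]].copy()
    frame["d1"] = space.scores_[:, 0]
    frame["d2"] = space.scores_[:, 1]
    stats = frame.groupby("pianist")[["d1", "d2"]].agg(["mean", "sem", "count"])
    pianists = list(stats.index)
    for i, a in enumerate(pianists):
        for b in pianists[i + 1 :]:
            da = np.hypot(stats.loc[a, ("d1", "mean")] - stats.loc[b, ("d1", "mean")],
                          stats.loc[a, ("d2", "mean")] - stats.loc[b, ("d2", "mean")])
            ra = np.hypot(stats.loc[a, ("d1", "sem")], stats.loc[a, ("d2", "sem")])
            rb = np.hypot(stats.loc[b, ("d1", "sem")], stats.loc[b, ("d2", "sem")])
            assert da > ra + rb
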