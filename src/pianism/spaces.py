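"""Reduced performance spaces: Z-normalization, PCA, varimax rotation, plots.

The selected (individuality-significant) features are standardized to
Z-scores per feature over the included performances, then decomposed by PCA;
the leading components span a low-dimensional "performance space" in which
each performance is a point and each pianist a cloud.  An optional varimax
rotation redistributes the loadings of the retained components for
interpretability; the overall three-component space is rotated by default
while per-timbre two-component spaces are not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ZScaler", "VarimaxPCA", "zscore", "pca", "varimax", "plot_space"]


class ZScaler(TransformerMixin, BaseEstimator):
    """Column-wise standardization to mean 0, SD 1 (population SD).

    Missing values are excluded from the moments and propagated through the
    transform; zero-SD (constant) columns are dropped with a warning.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.means_ = X.mean(skipna=True)
        self.sds_ = X.std(ddof=0, skipna=True)
        keep = self.sds_ > 0
        self.dropped_ = list(X.columns[~keep])
        if self.dropped_:
            import warnings

            warnings.warn(f"dropping zero-SD features: {self.dropped_}", stacklevel=2)
        self.columns_ = list(X.columns[keep])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        return (X[self.columns_] - self.means_[self.columns_]) / self.sds_[self.columns_]


def zscore(table: pd.DataFrame, features=None) -> pd.DataFrame:
    """Z-scores per feature over the included performances."""
    sub = table[list(features)] if features is not None else table
    return ZScaler().fit_transform(sub)


# ---------------------------------------------------------------------------
# varimax
# ---------------------------------------------------------------------------


def _varimax_criterion(L: np.ndarray) -> float:
    """Variance of squared loadings, summed over components."""
    sq = L**2
    return float((sq**2).sum(axis=0).sum() - (sq.sum(axis=0) ** 2).sum() / L.shape[0])


def varimax(loadings, tol: float = 1e-10, max_iter: int = 500, kaiser: bool = True):
    """Varimax rotation by iterative pairwise (Jacobi) plane rotations.

    Kaiser row normalization is applied by default: rows are scaled to unit
    communality before optimizing and scaled back afterwards.  Returns
    ``(rotated, rotation)`` with ``rotated = loadings @ rotation`` and
    ``rotation`` orthogonal.  The criterion never decreases across sweeps;
    non-convergence within ``max_iter`` sweeps returns the best found with a
    warning.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    comm = np.sqrt((L**2).sum(axis=1))
    if kaiser:
        safe = np.where(comm > 0, comm, 1.0)
        W = L / safe[:, None]
    else:
        W = L.copy()
    R = np.eye(k)
    crit = _varimax_criterion(W)
    converged = False
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = W[:, i], W[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = (u**2 - v**2).sum()
                D = (2.0 * u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                W[:, [i, j]] = W[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        new = _varimax_criterion(W)
        if new - crit < tol:
            crit = new
            converged = True
            break
        crit = new
    if not converged:
        import warnings

        warnings.warn(f"varimax did not converge in {max_iter} sweeps", stacklevel=2)
    if kaiser:
        rotated = (W * np.where(comm > 0, comm, 1.0)[:, None])
    else:
        rotated = W
    return rotated, R


# ---------------------------------------------------------------------------
# PCA estimator
# ---------------------------------------------------------------------------


class VarimaxPCA(TransformerMixin, BaseEstimator):
    """PCA on Z-scored features with optional varimax rotation.

    Parameters
    ----------
    n_components : int
    rotation : {'varimax', 'none'}

    Attributes
    ----------
    loadings_ : (n_features, n_components) array
        Unit-norm component loadings (rotated when requested), with a
        deterministic sign convention: the largest-magnitude loading of each
        component is positive.
    scores_ : (n_samples, n_components) array of the fitted data's scores.
    variance_fraction_ : per-component share of the total input variance
        (non-increasing before rotation; recomputed from the rotated scores
        after rotation).
    rotation_matrix_ : orthogonal matrix mapping unrotated to rotated loadings.
    """

    def __init__(self, n_components: int = 3, rotation: str = "varimax"):
        self.n_components = n_components
        self.rotation = rotation

    def fit(self, X, y=None):
        Z = np.asarray(X, dtype=float)
        n, p = Z.shape
        k = self.n_components
        if not (1 <= k <= min(n, p)):
            raise ValueError(f"n_components={k} outside 1..{min(n, p)}")
        if self.rotation not in ("varimax", "none"):
            raise ValueError(f"unknown rotation {self.rotation!r}")
        self.mean_ = Z.mean(axis=0)
        Zc = Z - self.mean_
        U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
        eigvals = s**2 / n  # population covariance eigenvalues of Z-scored data
        rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
        if k > rank:
            raise ValueError(f"n_components={k} exceeds data rank {rank}")
        total = float(eigvals.sum())
        loadings = Vt[:k].T
        # deterministic sign: largest-magnitude loading positive
        for j in range(k):
            idx = np.argmax(np.abs(loadings[:, j]))
            if loadings[idx, j] < 0:
                loadings[:, j] = -loadings[:, j]
        self.unrotated_loadings_ = loadings
        self.unrotated_variance_fraction_ = eigvals[:k] / total
        if self.rotation == "varimax" and k >= 2:
            rotated, R = varimax(loadings)
            for j in range(k):
                idx = np.argmax(np.abs(rotated[:, j]))
                if rotated[idx, j] < 0:
                    rotated[:, j] = -rotated[:, j]
                    R[:, j] = -R[:, j]
            self.rotation_matrix_ = R
            self.loadings_ = rotated
        else:
            self.rotation_matrix_ = np.eye(k)
            self.loadings_ = loadings
        self.components_ = self.loadings_.T
        self.scores_ = Zc @ self.loadings_
        self.variance_fraction_ = self.scores_.var(axis=0) / total
        self.explained_variance_ratio_ = self.variance_fraction_
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        Z = np.asarray(X, dtype=float)
        return (Z - self.mean_) @ self.loadings_

    def inverse_transform(self, scores):
        check_is_fitted(self, "loadings_")
        return np.asarray(scores) @ self.loadings_.T + self.mean_


def pca(normalized: pd.DataFrame, n_components: int, rotation: str = "none") -> VarimaxPCA:
    """Fit a reduced space on an already Z-scored table."""
    return VarimaxPCA(n_components=n_components, rotation=rotation).fit(
        np.asarray(normalized, dtype=float)
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def _se_ellipse(ax, xy, color):
    """+/- 1 SE ellipse around a pianist's mean position."""
    from matplotlib.patches import Ellipse

    n = len(xy)
    if n < 2:
        return
    se = xy.std(axis=0, ddof=1) / np.sqrt(n)
    mean = xy.mean(axis=0)
    ax.add_patch(
        Ellipse(mean, width=2 * se[0], height=2 * se[1], facecolor="none",
                edgecolor=color, linewidth=1.2)
    )


def plot_space(space: VarimaxPCA, metadata: pd.DataFrame, dims=None, out_prefix=None):
    """Planar projections of a fitted space with per-pianist means and SE.

    Same-condition repetitions (pianist x piece x timbre) are averaged before
    plotting; pianist means are drawn as crosses with +/- 1 SE ellipses
    (omitted when a pianist has a single plotted point).  Returns the list of
    written figure paths (or figures when ``out_prefix`` is None).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = space.scores_.shape[1]
    if dims is None:
        dims = [(a, b) for a in range(k) for b in range(a + 1, k)]
    for a, b in dims:
        if not (0 <= a < k and 0 <= b < k):
            raise ValueError(f"unknown dims ({a}, {b}) for a {k}-component space")
    frame = metadata.reset_index(drop=True).copy()
    for j in range(k):
        frame[f"dim{j + 1}"] = space.scores_[:, j]
    cond = frame.groupby(["pianist", "piece", "timbre"], observed=True)[
        [f"dim{j + 1}" for j in range(k)]
    ].mean().reset_index()

    colors = dict(zip(sorted(cond["pianist"].unique()),
                      plt.rcParams["axes.prop_cycle"].by_key()["color"]))
    outputs = []
    for a, b in dims:
        fig, ax = plt.subplots(figsize=(5, 4))
        for pianist, grp in cond.groupby("pianist", observed=True):
            xy = grp[[f"dim{a + 1}", f"dim{b + 1}"]].to_numpy()
            color = colors[pianist]
            ax.scatter(xy[:, 0], xy[:, 1], s=14, alpha=0.6, color=color, label=str(pianist))
            ax.scatter(*xy.mean(axis=0), marker="+", s=120, color=color)
            _se_ellipse(ax, xy, color)
        ax.set_xlabel(f"dimension {a + 1} ({space.variance_fraction_[a]:.1%})")
        ax.set_ylabel(f"dimension {b + 1} ({space.variance_fraction_[b]:.1%})")
        ax.legend(title="pianist", fontsize=8)
        fig.tight_layout()
        if out_prefix is not None:
            path = f"{out_prefix}_dim{a + 1}{b + 1}.svg"
            fig.savefig(path)
            plt.close(fig)
            outputs.append(path)
        else:
            outputs.append(fig)
    return outputs
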