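"""Descriptive performance portraits.

The individuality-significant features are partitioned into four technically
independent categories — dynamics/attack, articulation, soft pedal, sustain
pedal — then, within each category, highly correlated (redundant) features
are grouped by average-linkage hierarchical clustering on the distance
``1 - |Pearson r|``.  One representative is selected per cluster: the most
significant feature, with effect size, power and an interpretability rank as
tie-breaks.  A cluster contributes nothing when its best feature meets
neither minimum threshold of effect size nor statistical power
(eta2 < 0.2 and pi < 0.2).  The selected features, as per-pianist Z-score
means with standard errors, form a Kiviat (radar) portrait of each pianist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .schema import CATEGORIES, FeatureSchema, default_schema

__all__ = [
    "ClusterTree",
    "Portrait",
    "categorize",
    "cluster_category",
    "select_representatives",
    "build_portrait",
    "render_kiviat",
    "CUT_HEIGHT",
    "ETA2_MIN",
    "POWER_MIN",
]

logger = logging.getLogger(__name__)

CUT_HEIGHT = 0.3  # merge features with |r| >= 0.7
ETA2_MIN = 0.2
POWER_MIN = 0.2


@dataclass
class ClusterTree:
    category: str
    features: list
    linkage: np.ndarray | None
    cut: float
    clusters: list  # list of feature-name lists


@dataclass
class Portrait:
    """Selected representative features with per-pianist statistics."""

    scope: str
    features: list
    z_means: pd.DataFrame  # pianists x features, Z-score means
    z_se: pd.DataFrame  # pianists x features, standard errors of the mean
    raw_means: pd.DataFrame  # pianists x features, native units
    clusters: dict = field(default_factory=dict)  # category -> ClusterTree

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "features": list(self.features),
            "z_means": self.z_means.to_dict(),
            "z_se": self.z_se.to_dict(),
            "raw_means": self.raw_means.to_dict(),
        }


def categorize(features, schema: FeatureSchema | None = None) -> dict:
    """Map each performance feature to its schema category."""
    schema = schema or default_schema()
    return {f: schema.category_of(f) for f in features}


def cluster_category(
    table: pd.DataFrame,
    features,
    cut: float = CUT_HEIGHT,
    category: str = "",
) -> ClusterTree:
    """Average-linkage clustering of one category's features on 1 - |r|."""
    features = list(features)
    if not features:
        raise ValueError("need at least one feature to cluster")
    if len(features) == 1:
        return ClusterTree(category, features, None, cut, [features])
    X = table[features].to_numpy(dtype=float)
    r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    dist = np.clip(1.0 - np.abs(r), 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    clusters = [
        [f for f, l in zip(features, labels) if l == lab]
        for lab in sorted(set(labels))
    ]
    return ClusterTree(category, features, Z, cut, clusters)


def select_representatives(
    clusters,
    anova_results: dict,
    schema: FeatureSchema | None = None,
) -> list:
    """One representative per cluster, by significance then eta2 then power.

    A cluster yields no feature when even its best candidate falls below both
    minimum thresholds (eta2 < 0.2 and power < 0.2).  The final tie-break is
    the schema's interpretability rank, then the name (for determinism);
    the result is invariant to feature ordering and to duplicated
    non-selected features.
    """
    schema = schema or default_schema()
    chosen = []
    for cluster in clusters:
        candidates = []
        for feat in cluster:
            r = anova_results[feat]
            eta2 = r.eta2 if np.isfinite(r.eta2) else 0.0
            power = r.power if np.isfinite(r.power) else 0.0
            if eta2 < ETA2_MIN and power < POWER_MIN:
                continue
            p = r.p if np.isfinite(r.p) else 1.0
            candidates.append(
                (p, -eta2, -power, schema.interpretability_of(feat), feat)
            )
        if not candidates:
            logger.info("cluster %s: no feature meets eta2/power thresholds", cluster)
            continue
        chosen.append(min(candidates)[-1])
    return chosen


def build_portrait(
    table: pd.DataFrame,
    selection,
    scope: str = "overall",
    cut: float = CUT_HEIGHT,
    schema: FeatureSchema | None = None,
) -> Portrait:
    """Full portrait construction from a feature table and a selection result.

    ``selection`` is a :class:`pianism.stats.SelectionResult`; the performer
    effect's ANOVA statistics drive the representative choice.  Z-scores are
    computed per feature over the rows of ``table`` (restricted to the scope's
    timbre when applicable).
    """
    schema = schema or default_schema()
    sub = table if scope == "overall" else table[table["timbre"] == scope]
    significant = [f for f in selection.selected if f in table.columns]
    by_cat = {c: [] for c in CATEGORIES}
    for feat, cat in categorize(significant, schema).items():
        by_cat[cat].append(feat)

    perf_results = {f: selection.results[f]["pianist"] for f in significant}
    trees, chosen = {}, []
    for cat in CATEGORIES:
        feats = by_cat[cat]
        if not feats:
            continue
        tree = cluster_category(sub, feats, cut, cat)
        trees[cat] = tree
        chosen.extend(select_representatives(tree.clusters, perf_results, schema))
    if not chosen:
        logger.warning("empty portrait for scope %r", scope)
    chosen = sorted(chosen, key=lambda f: list(schema.column_names).index(f))

    mu = sub[chosen].mean()
    sd = sub[chosen].std(ddof=0)
    z = (sub[chosen] - mu) / sd.replace(0.0, np.nan)
    z["pianist"] = sub["pianist"].to_numpy()
    grouped = z.groupby("pianist", observed=True)
    z_means = grouped.mean()
    counts = grouped.size()
    z_se = grouped.std(ddof=1).div(np.sqrt(counts), axis=0)
    raw = sub[chosen + ["pianist"]].groupby("pianist", observed=True).mean()
    return Portrait(scope=scope, features=chosen, z_means=z_means, z_se=z_se,
                    raw_means=raw, clusters=trees)


def render_kiviat(portrait: Portrait, out_path=None, se_factor: float = 1.96):
    """Kiviat (radar) chart of per-pianist Z-score polylines.

    Shaded bands show +/- ``se_factor`` standard errors (1.96 for a 95 %
    confidence interval); raw per-pianist means in native units are annotated
    on each axis.  With fewer than three features a grouped bar chart is
    drawn instead (with a warning).  Returns the figure (also written to
    ``out_path`` when given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = portrait.features
    pianists = list(portrait.z_means.index)
    if len(feats) < 3:
        logger.warning("portrait has %d features; falling back to a bar chart", len(feats))
        fig, ax = plt.subplots(figsize=(6, 4))
        width = 0.8 / max(1, len(pianists))
        x = np.arange(len(feats))
        for i, p in enumerate(pianists):
            vals = portrait.z_means.loc[p, feats].to_numpy(dtype=float)
            errs = se_factor * portrait.z_se.loc[p, feats].to_numpy(dtype=float)
            ax.bar(x + i * width, vals, width=width, yerr=errs, label=str(p))
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(feats, rotation=30, ha="right", fontsize=7)
        ax.set_ylabel("Z-score")
    else:
        angles = np.linspace(0, 2 * np.pi, len(feats), endpoint=False)
        closed = np.concatenate([angles, angles[:1]])
        fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"projection": "polar"})
        for p in pianists:
            vals = portrait.z_means.loc[p, feats].to_numpy(dtype=float)
            errs = se_factor * portrait.z_se.loc[p, feats].to_numpy(dtype=float)
            loop = np.concatenate([vals, vals[:1]])
            eloop = np.concatenate([errs, errs[:1]])
            line = ax.plot(closed, loop, marker="o", markersize=3, label=str(p))[0]
            ax.fill_between(closed, loop - eloop, loop + eloop, alpha=0.15,
                            color=line.get_color())
        labels = [
            f"{f}\n" + " / ".join(
                f"{portrait.raw_means.loc[p, f]:.3g}" for p in pianists
            )
            for f in feats
        ]
        ax.set_xticks(angles)
        ax.set_xticklabels(labels, fontsize=6)
        ax.set_yticklabels([])
    ax.legend(title="pianist", loc="upper right", bbox_to_anchor=(1.25, 1.05), fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
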