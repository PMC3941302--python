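"""Repeated-measures ANOVA gate for performer-individuality features.

For each performance feature a balanced repeated-measures ANOVA is run with
the performer as random factor and timbre, piece and repetition (of the same
condition) as fixed factors.  A feature reveals individuality when the
performer effect is significant at the 5 % level *and* the repetition effect
is not (consistency between repetitions).  Significance levels are not
adjusted for multiple comparisons; type-I errors are instead controlled by
the assumption checks with a non-parametric fallback, and downstream by the
redundancy clustering of the portrait stage.

Error-term construction (classical expected-mean-squares rules for a mixed
model with one random factor and one observation per cell):

* fixed main effects and fixed-fixed interactions are tested against their
  interaction with the random performer factor;
* the performer effect and performer-involving interactions are tested
  against the pooled residual (the highest-order interaction).

The Huynh–Feldt epsilon, estimated from the repetition-level covariance, is
applied to the degrees of freedom of every repetition-involving effect.
Partial eta-squared is ``SS_effect / (SS_effect + SS_error)`` and the
observed power is computed from the noncentral F at alpha = 0.05 with
noncentrality ``F * df1``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.diagnostic import lilliefors

from .io import METADATA_COLUMNS

__all__ = [
    "AnovaResult",
    "SelectionResult",
    "rm_anova",
    "per_timbre_anova",
    "check_assumptions",
    "select_features",
    "interaction_candidates",
    "IndividualityGate",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
_FIXED = ("timbre", "piece", "repetition")
_RANDOM = "pianist"


@dataclass
class AnovaResult:
    """F-test for one effect of one feature."""

    feature: str
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    ss_effect: float
    ss_error: float
    eta2: float
    power: float
    hf_epsilon: float = 1.0
    assumptions: dict = field(default_factory=dict)
    kw_p: float | None = None


@dataclass
class SelectionResult:
    """Outcome of the significance + consistency gate for one scope."""

    scope: str
    selected: list
    results: dict  # feature -> {effect -> AnovaResult}
    excluded: list = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = []
        for feat, effects in self.results.items():
            for eff, r in effects.items():
                rows.append(
                    dict(feature=feat, effect=eff, F=r.F, df1=r.df1, df2=r.df2,
                         p=r.p, eta2=r.eta2, power=r.power, hf_epsilon=r.hf_epsilon,
                         kw_p=r.kw_p, selected=feat in self.selected)
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# balanced factorial decomposition
# ---------------------------------------------------------------------------


def _balanced_cube(table: pd.DataFrame, feature: str, factors):
    """Reshape one feature column into a len(factors)-dimensional cell array."""
    levels = [np.sort(table[f].unique()) for f in factors]
    shape = tuple(len(lv) for lv in levels)
    counts = table.groupby(list(factors), observed=True).size()
    if len(counts) != int(np.prod(shape)) or counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError(
            f"unbalanced design for feature {feature!r}: "
            "need exactly one observation per factor-level cell"
        )
    ordered = table.sort_values(list(factors), kind="mergesort")
    return ordered[feature].to_numpy(dtype=float).reshape(shape), levels


def _effect_decomposition(data: np.ndarray):
    """Sums of squares for every effect of a balanced full factorial.

    Returns ``{frozenset(axes): (SS, df)}``; the full-order interaction is the
    pooled residual for a design with one observation per cell.
    """
    k = data.ndim
    shape = data.shape
    grand = data.mean()
    effects: dict[frozenset, np.ndarray] = {}
    out: dict[frozenset, tuple] = {}
    for size in range(1, k + 1):
        for axes in itertools.combinations(range(k), size):
            s = frozenset(axes)
            other = tuple(a for a in range(k) if a not in s)
            marg = data.mean(axis=other, keepdims=True) - grand
            for sub, e in effects.items():
                if sub < s:
                    marg = marg - e
            effects[s] = marg
            ss = float((marg**2).sum()) * int(np.prod([shape[a] for a in other]))
            df = int(np.prod([shape[a] - 1 for a in axes]))
            out[s] = (ss, df)
    return out


def _hf_epsilon(table: pd.DataFrame, feature: str, within: str, factors) -> float:
    """Huynh-Feldt epsilon from the within-level covariance.

    Replicates are all combinations of the remaining factors (performer x
    piece x timbre cells for the repetition factor of the full design).
    """
    others = [f for f in factors if f != within]
    wide = table.pivot_table(
        index=others, columns=within, values=feature, observed=True
    ).to_numpy(dtype=float)
    n, k = wide.shape
    if k < 3 or n < 2:
        return 1.0
    S = np.cov(wide, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    E = C @ S @ C
    tr = np.trace(E)
    denom = (k - 1) * float((E * E).sum())
    if denom <= 0:
        return 1.0
    gg = tr**2 / denom
    hf = (n * (k - 1) * gg - 2) / ((k - 1) * (n - 1 - (k - 1) * gg))
    return float(np.clip(hf, 1.0 / (k - 1), 1.0))


def _f_test(feature, name, ss, df, ss_err, df_err, epsilon=1.0, alpha=ALPHA):
    if df_err <= 0 or ss_err <= 0 or df <= 0:
        return AnovaResult(feature, name, np.nan, df, df_err, np.nan, ss, ss_err,
                           np.nan, np.nan, epsilon)
    ms, ms_err = ss / df, ss_err / df_err
    F = ms / ms_err
    df1, df2 = df * epsilon, df_err * epsilon
    p = float(sps.f.sf(F, df1, df2))
    eta2 = ss / (ss + ss_err)
    lam = F * df1
    crit = sps.f.ppf(1 - alpha, df1, df2)
    power = float(1.0 - sps.ncf.cdf(crit, df1, df2, lam))
    return AnovaResult(feature, name, float(F), df1, df2, p, ss, ss_err,
                       float(eta2), power, epsilon)


def rm_anova(
    table: pd.DataFrame,
    feature: str,
    fixed=_FIXED,
    random: str = _RANDOM,
    repetition: str = "repetition",
    alpha: float = ALPHA,
) -> dict:
    """Mixed repeated-measures ANOVA for one feature; returns effect -> result.

    Reported effects: the random performer factor, every fixed main effect,
    and every interaction except the full-order one (the pooled residual).
    """
    factors = [random] + [f for f in fixed if table[f].nunique() > 1]
    data, _ = _balanced_cube(table, feature, factors)
    ss = _effect_decomposition(data)
    k = data.ndim
    full = frozenset(range(k))
    resid_ss, resid_df = ss[full]
    eps = (
        _hf_epsilon(table, feature, repetition, factors)
        if repetition in factors
        else 1.0
    )
    rep_axis = factors.index(repetition) if repetition in factors else None

    results = {}
    for axes, (ss_eff, df_eff) in ss.items():
        if axes == full:
            continue
        name = ":".join(factors[a] for a in sorted(axes))
        if 0 in axes:  # involves the random performer factor
            err_ss, err_df = resid_ss, resid_df
        else:
            err = frozenset(axes | {0})
            err_ss, err_df = ss[err] if err != full else (resid_ss, resid_df)
        epsilon = eps if (rep_axis is not None and rep_axis in axes) else 1.0
        results[name] = _f_test(feature, name, ss_eff, df_eff, err_ss, err_df,
                                epsilon, alpha)
    return results


def per_timbre_anova(table: pd.DataFrame, timbre: str, feature_columns=None,
                     alpha: float = ALPHA) -> dict:
    """Two-way repeated-measures ANOVAs on one timbre's performances.

    Performer stays the random factor; piece and repetition are fixed.
    Returns ``{feature: {effect: AnovaResult}}`` with the same assumption,
    fallback and sphericity-correction machinery as the overall analysis.
    """
    sub = table[table["timbre"] == timbre]
    if sub.empty:
        raise ValueError(f"no rows for timbre {timbre!r}")
    feats = feature_columns or _usable_features(sub)
    return {
        feat: rm_anova(sub, feat, fixed=("piece", "repetition"), alpha=alpha)
        for feat in feats
    }


def check_assumptions(table: pd.DataFrame, feature: str, group: str = _RANDOM,
                      alpha: float = ALPHA) -> dict:
    """Normality (Lilliefors-corrected KS per group) and Levene homoscedasticity.

    Returns flags plus the Kruskal-Wallis fallback p-value across groups.
    """
    groups = [g.to_numpy(dtype=float) for _, g in table.groupby(group, observed=True)[feature]]
    if any(len(g) < 3 for g in groups) or len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 3 observations each")
    # one normality flag per feature: Bonferroni over the per-group KS tests
    # keeps the family-wise false-flag rate at alpha
    level = alpha / len(groups)
    normality = True
    for g in groups:
        if np.ptp(g) == 0:
            normality = False
            continue
        _, p = lilliefors(g, dist="norm")
        if p < level:
            normality = False
    try:
        _, lev_p = sps.levene(*groups)
    except ValueError:
        lev_p = np.nan
    homo = bool(lev_p >= alpha) if np.isfinite(lev_p) else False
    try:
        _, kw_p = sps.kruskal(*groups)
    except ValueError:
        kw_p = np.nan
    return {
        "normality_ok": bool(normality),
        "homoscedasticity_ok": homo,
        "levene_p": float(lev_p) if np.isfinite(lev_p) else np.nan,
        "kw_p": float(kw_p) if np.isfinite(kw_p) else np.nan,
    }


def _gate_feature(sub: pd.DataFrame, feature: str, fixed, alpha: float):
    """Run the ANOVA + assumption machinery for one feature on one scope."""
    effects = rm_anova(sub, feature, fixed=fixed, alpha=alpha)
    perf = effects[_RANDOM]
    checks = check_assumptions(sub, feature, alpha=alpha)
    perf.assumptions = {
        "normality_ok": checks["normality_ok"],
        "homoscedasticity_ok": checks["homoscedasticity_ok"],
        "sphericity_ok": perf.hf_epsilon > 0.95,
    }
    significant = np.isfinite(perf.p) and perf.p < alpha
    if significant and not (checks["normality_ok"] and checks["homoscedasticity_ok"]):
        perf.kw_p = checks["kw_p"]
        significant = np.isfinite(checks["kw_p"]) and checks["kw_p"] < alpha
    rep = effects.get("repetition")
    consistent = rep is None or not (np.isfinite(rep.p) and rep.p < alpha)
    return effects, bool(significant and consistent)


def interaction_candidates(table: pd.DataFrame, feature_columns=None,
                           alpha: float = ALPHA):
    """Features with a significant pianist x timbre interaction overall.

    Separate per-timbre analyses are only valid for features protected by
    this interaction in the general ANOVA.
    """
    feature_columns = feature_columns or _usable_features(table)
    out = []
    for feat in feature_columns:
        effects = rm_anova(table, feat)
        inter = effects.get("pianist:timbre")
        if inter is not None and np.isfinite(inter.p) and inter.p < alpha:
            out.append(feat)
    return out


def _usable_features(table: pd.DataFrame):
    feats = []
    for col in table.columns:
        if col in METADATA_COLUMNS:
            continue
        vals = table[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            logger.info("feature %s skipped: missing values", col)
            continue
        if np.ptp(vals) == 0:
            logger.info("feature %s excluded: constant", col)
            continue
        feats.append(col)
    return feats


def select_features(
    table: pd.DataFrame,
    scope: str = "overall",
    alpha: float = ALPHA,
    feature_columns=None,
    candidates=None,
) -> SelectionResult:
    """Apply the significance + consistency selection rule.

    ``scope='overall'`` uses the full three-way design; a timbre label scope
    restricts the table to that timbre, drops the timbre factor, and limits
    the candidate set to features whose pianist x timbre interaction is
    significant overall (computed here unless ``candidates`` is given).
    No multiple-comparison correction is applied.
    """
    timbres = set(table["timbre"].unique())
    if scope != "overall" and scope not in timbres:
        raise ValueError(f"unknown scope {scope!r}; expected 'overall' or one of {sorted(timbres)}")

    usable = _usable_features(table)
    if feature_columns is not None:
        usable = [f for f in feature_columns if f in usable]
    if scope == "overall":
        sub, fixed = table, _FIXED
    else:
        if candidates is None:
            candidates = interaction_candidates(table, usable, alpha)
        usable = [f for f in usable if f in set(candidates)]
        sub, fixed = table[table["timbre"] == scope], ("piece", "repetition")

    selected, results, excluded = [], {}, []
    all_feats = set(usable)
    for feat in usable:
        try:
            effects, ok = _gate_feature(sub, feat, fixed, alpha)
        except ValueError as exc:
            logger.info("feature %s excluded: %s", feat, exc)
            excluded.append(feat)
            continue
        results[feat] = effects
        if ok:
            selected.append(feat)
    excluded.extend(
        c for c in (table.columns if feature_columns is None else feature_columns)
        if c not in all_feats and c not in METADATA_COLUMNS
    )
    return SelectionResult(scope=scope, selected=selected, results=results,
                           excluded=excluded)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class IndividualityGate(BaseEstimator):
    """Feature selector applying the performer-individuality gate.

    Parameters
    ----------
    scope : str
        ``'overall'`` or a timbre label.
    alpha : float
        Significance level for both the selection (performer effect
        ``p < alpha``) and the consistency requirement (repetition effect
        ``p >= alpha``).

    Attributes
    ----------
    selected_features_ : list of str
    support_ : boolean array over the fitted feature columns
    selection_ : SelectionResult with the full ANOVA tables
    """

    def __init__(self, scope: str = "overall", alpha: float = ALPHA):
        self.scope = scope
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None, design: pd.DataFrame | None = None,
            candidates=None):
        """Fit on a feature table.

        ``X`` may be the full table (metadata columns included) or a pure
        feature frame with ``design`` supplying the performer / piece /
        timbre / repetition factors row-wise.
        """
        if design is not None:
            table = pd.concat(
                [design.reset_index(drop=True), X.reset_index(drop=True)], axis=1
            )
        else:
            table = X
        missing = [c for c in METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"missing design columns: {missing}")
        self.feature_names_in_ = [c for c in table.columns if c not in METADATA_COLUMNS]
        self.n_features_in_ = len(self.feature_names_in_)
        self.selection_ = select_features(
            table, scope=self.scope, alpha=self.alpha, candidates=candidates
        )
        self.selected_features_ = list(self.selection_.selected)
        chosen = set(self.selected_features_)
        self.support_ = np.array([f in chosen for f in self.feature_names_in_])
        return self

    def get_support(self):
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
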