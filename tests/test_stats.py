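"""Mixed repeated-measures ANOVA, assumption checks and the selection gate."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pianism.stats import (
    IndividualityGate,
    check_assumptions,
    interaction_candidates,
    per_timbre_anova,
    rm_anova,
    select_features,
    _balanced_cube,
    _effect_decomposition,
)

from .conftest import design_frame, null_feature_table


@pytest.fixture()
def rng():
    # fresh, order-independent stream per test
    return np.random.default_rng(20240)


class TestAnovaMechanics:
    def test_sums_of_squares_match_statsmodels(self, rng):
        """Balanced decomposition agrees with an independent OLS ANOVA."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        tab = design_frame(pianists=4, timbres=("bright", "dark", "dry"), pieces=2)
        tab["f"] = rng.normal(size=len(tab)) + (tab["pianist"] == "P0") * 0.8
        model = smf.ols("f ~ C(pianist)*C(timbre)*C(piece)", data=tab).fit()
        ref = anova_lm(model, typ=2)
        cube, _ = _balanced_cube(tab, "f", ["pianist", "timbre", "piece", "repetition"])
        ss = _effect_decomposition(cube)
        names = ["pianist", "timbre", "piece", "repetition"]
        for axes, (s, _) in ss.items():
            if 3 in axes:
                continue
            label = ":".join(f"C({names[a]})" for a in sorted(axes))
            assert s == pytest.approx(ref.loc[label, "sum_sq"], abs=1e-8)

    def test_eta2_is_partial_effect_share(self, rng):
        """eta2 = SS_effect / (SS_effect + SS_error) from the same table."""
        tab = design_frame()
        tab["f"] = rng.normal(size=len(tab))
        for res in rm_anova(tab, "f").values():
            assert res.eta2 == pytest.approx(
                res.ss_effect / (res.ss_effect + res.ss_error), abs=1e-12
            )

    def test_compound_symmetry_gives_epsilon_one(self, rng):
        """Exchangeable repetition covariance leaves epsilon near 1."""
        tab = design_frame()
        subject_effect = rng.normal(size=80).repeat(3)  # shared across repetitions
        tab = tab.sort_values(["pianist", "timbre", "piece", "repetition"]).reset_index(drop=True)
        tab["f"] = subject_effect + rng.normal(scale=1.0, size=len(tab))
        res = rm_anova(tab, "f")
        assert res["repetition"].hf_epsilon == pytest.approx(1.0, abs=0.02)

    def test_unbalanced_design_rejected(self, rng):
        tab = design_frame()
        tab["f"] = rng.normal(size=len(tab))
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(tab.iloc[:-1], "f")

    def test_null_performer_pvalues_uniform(self, rng):
        """Identical pianists, i.i.d. noise: performer p is uniform on [0, 1]."""
        tab = null_feature_table(rng, n_features=200)
        pvals = [rm_anova(tab, f"F{j:03d}")["pianist"].p for j in range(200)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestAssumptions:
    def test_normal_groups_usually_pass(self, rng):
        """Under a common normal H0 both flags pass at the designed rate:
        Bonferroni family-wise normality (alpha) times Levene (alpha), about
        0.95 * 0.95; checked against its exact binomial 99.9 % interval."""
        from scipy.stats import binom

        ok = 0
        n_rep = 500
        for _ in range(n_rep):
            tab = pd.DataFrame({
                "pianist": np.repeat(list("ABCD"), 60),
                "f": rng.normal(size=240),
            })
            checks = check_assumptions(tab, "f")
            ok += checks["normality_ok"] and checks["homoscedasticity_ok"]
        expected = (1 - 0.05) * (1 - 0.05)
        lo = binom.ppf(0.0005, n_rep, expected)
        hi = binom.ppf(0.9995, n_rep, expected)
        assert lo <= ok <= hi
        assert ok / n_rep >= 0.85

    def test_levene_detects_variance_ratio_100(self, rng):
        tab = pd.DataFrame({
            "pianist": np.repeat(["A", "B"], 60),
            "f": np.concatenate([rng.normal(0, 1, 60), rng.normal(0, 10, 60)]),
        })
        assert not check_assumptions(tab, "f")["homoscedasticity_ok"]

    def test_too_small_groups_rejected(self):
        tab = pd.DataFrame({"pianist": ["A", "A", "B", "B"], "f": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="observations"):
            check_assumptions(tab, "f")


class TestSelectionGate:
    def test_planted_signals_selected(self, rng):
        """Large planted pianist effects are caught; false positives stay low."""
        tab = null_feature_table(rng, n_features=60)
        shift = tab["pianist"].map({"P0": -1.5, "P1": -0.5, "P2": 0.5, "P3": 1.5})
        planted = [f"F{j:03d}" for j in range(10)]
        for f in planted:
            tab[f] = tab[f] + shift
        res = select_features(tab)
        # every planted feature is flagged by the performer gate; at most one
        # may be vetoed by a chance repetition effect (the consistency rule)
        for f in planted:
            assert res.results[f]["pianist"].p < 0.05
        assert len(set(planted) & set(res.selected)) >= 9
        false_pos = [f for f in res.selected if f not in planted]
        assert len(false_pos) / 50 <= 0.10

    def test_repetition_effect_blocks_selection(self, rng):
        """A feature differing only across repetitions is not selected."""
        tab = null_feature_table(rng, n_features=1)
        tab["F000"] = tab["F000"] * 0.05 + tab["repetition"] * 2.0
        res = select_features(tab)
        assert res.selected == []

    def test_constant_feature_excluded(self, rng, caplog):
        tab = null_feature_table(rng, n_features=2)
        tab["F001"] = 3.14
        with caplog.at_level("INFO", logger="pianism.stats"):
            res = select_features(tab)
        assert "F001" in res.excluded and "F001" not in res.results

    def test_unknown_scope_rejected(self, rng):
        tab = null_feature_table(rng, n_features=1)
        with pytest.raises(ValueError, match="scope"):
            select_features(tab, scope="sparkly")

    def test_power_monotone_in_effect_size(self, rng):
        """Larger planted pianist separations select the feature more often."""
        rates = []
        for effect in (0.0, 0.4, 1.2):
            hits = 0
            for _ in range(20):
                tab = null_feature_table(rng, n_features=1, timbres=("bright", "dark"),
                                         pieces=2)
                shift = tab["pianist"].map(
                    {"P0": -1.5, "P1": -0.5, "P2": 0.5, "P3": 1.5}
                )
                tab["F000"] = tab["F000"] + effect * shift
                hits += len(select_features(tab).selected)
            rates.append(hits / 20)
        assert rates[0] < rates[2] and rates[1] <= rates[2]


class TestInteractionScopes:
    def _interaction_table(self, rng, effect=2.5):
        """One feature whose pianist effect exists only in 'dark' performances."""
        tab = null_feature_table(rng, n_features=3, timbres=("bright", "dark"), pieces=2)
        shift = tab["pianist"].map({"P0": -1.5, "P1": -0.5, "P2": 0.5, "P3": 1.5})
        dark = (tab["timbre"] == "dark").astype(float)
        tab["F000"] = tab["F000"] + effect * shift * dark
        return tab

    def test_planted_interaction_gates_scopes(self, rng):
        """The interaction-protected feature is selected for dark, not bright."""
        tab = self._interaction_table(rng)
        cands = interaction_candidates(tab)
        assert "F000" in cands
        dark = select_features(tab, scope="dark", candidates=cands)
        bright = select_features(tab, scope="bright", candidates=cands)
        assert "F000" in dark.selected
        assert "F000" not in bright.selected

    def test_per_timbre_anova_runs_two_way(self, rng):
        tab = self._interaction_table(rng)
        out = per_timbre_anova(tab, "dark", feature_columns=["F000"])
        effects = out["F000"]
        assert set(effects) >= {"pianist", "piece", "repetition"}
        assert effects["pianist"].p < 0.05


class TestEstimator:
    def test_gate_transform_selects_columns(self, rng):
        tab = null_feature_table(rng, n_features=20, timbres=("bright", "dark"), pieces=2)
        shift = tab["pianist"].map({"P0": -2.0, "P1": -1.0, "P2": 1.0, "P3": 2.0})
        tab["F000"] = tab["F000"] + shift
        gate = IndividualityGate()
        out = gate.fit_transform(tab)
        assert "F000" in out.columns
        assert gate.support_.sum() == out.shape[1]
        assert gate.get_params() == {"scope": "overall", "alpha": 0.05}

    def test_estimator_clones(self):
        from sklearn.base import clone

        gate = IndividualityGate(scope="dark", alpha=0.01)
        assert clone(gate).get_params() == gate.get_params()
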