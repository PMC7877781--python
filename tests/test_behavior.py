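"""Behavior taxonomy, timeline tabulation, and the multinomial model."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bobwarn.behavior import (
    ALL_COVARIATES,
    BEHAVIOR_LABELS,
    GROUPED_ACTIONS,
    ActionEvent,
    Trial,
    aic,
    behavior_percentages,
    fit_multinomial,
    group_behavior,
    most_common_action,
    select_model,
    tabulate_actions,
)
from bobwarn.datasets import load_behavior_counts
from bobwarn.synthetic import TrialModel, gen_trials


def make_trial(codes, tid="t1", **kw):
    defaults = dict(
        spider_type="field_adult",
        wasp_color="BOB",
        wasp_genus="Scelio",
        wasp_length=4.0,
        spider_length=6.0,
        silk_dragline="no",
        reaction_slot="0-5",
    )
    defaults.update(kw)
    events = tuple(ActionEvent(behavior=c, slot10="0-10") for c in codes)
    return Trial(trial_id=tid, events=events, **defaults)


class TestGrouping:
    @pytest.mark.parametrize(
        "code,expected",
        [(1, "detect"), (2, "detect"), (3, "attack"), (4, "attack"),
         (5, "avoid"), (6, "avoid"), (7, None)],
    )
    def test_partition(self, code, expected):
        assert group_behavior(code) == expected

    def test_invalid_code(self):
        with pytest.raises(ValueError):
            group_behavior(0)

    def test_published_totals_recount(self):
        df = load_behavior_counts()
        assert df["total"].sum() == 954
        grouped = df.assign(g=[group_behavior(c) for c in df["code"]])
        sums = grouped.groupby("g")["total"].sum()
        assert sums["detect"] == 352 + 210
        assert sums["attack"] == 200 + 8
        assert sums["avoid"] == 131 + 51


class TestMostCommonAction:
    def test_strict_mode(self):
        assert most_common_action(make_trial([1, 2, 3])) == "detect"

    def test_all_none_events_rejected(self):
        with pytest.raises(ValueError, match="no groupable"):
            most_common_action(make_trial([7, 7]))

    def test_tie_break_matches_brute_force_enumeration(self):
        """Every tied multiset resolves by attack > avoid > detect."""
        precedence = ["attack", "avoid", "detect"]
        for counts in itertools.product(range(3), repeat=3):
            if sum(counts) == 0:
                continue
            codes = [1] * counts[0] + [3] * counts[1] + [5] * counts[2]
            # oracle: max count, precedence as tie-break
            by_cat = dict(zip(("detect", "attack", "avoid"), counts))
            m = max(by_cat.values())
            expected = next(c for c in precedence if by_cat[c] == m)
            assert most_common_action(make_trial(codes)) == expected


class TestTabulation:
    def test_empty_set(self):
        out = tabulate_actions([])
        assert out["count"].sum() == 0
        assert len(out) == 3 * 2 * 3 * 4  # full cartesian cell grid

    def test_single_event_lands_in_its_cell(self):
        t = make_trial([], tid="x")
        t = Trial(
            trial_id="x",
            spider_type="captive_adult",
            wasp_color="black",
            wasp_genus="Scelio",
            wasp_length=4.0,
            spider_length=6.0,
            silk_dragline="no",
            reaction_slot="0-5",
            events=(ActionEvent(behavior=1, slot10="10-20"),),
        )
        out = tabulate_actions([t])
        cell = out.query(
            "spider_type=='captive_adult' and wasp_color=='black' "
            "and action=='detect' and slot10=='10-20'"
        )
        assert cell["count"].iloc[0] == 1 and out["count"].sum() == 1

    def test_counts_match_independent_recount(self, rng):
        trials = gen_trials(TrialModel(), 60, rng)
        out = tabulate_actions(trials)
        n_groupable = sum(
            1 for t in trials for e in t.events if group_behavior(e.behavior)
        )
        assert out["count"].sum() == n_groupable
        # spot-check one random cell against a brute-force recount
        row = out.sample(1, random_state=1).iloc[0]
        manual = sum(
            1
            for t in trials
            if t.spider_type == row.spider_type and t.wasp_color == row.wasp_color
            for e in t.events
            if group_behavior(e.behavior) == row.action and e.slot10 == row.slot10
        )
        assert row["count"] == manual


class TestPercentages:
    def test_bob_denominator_is_per_genus(self):
        trials = [
            make_trial([3], tid=f"b{i}", wasp_genus="Baryconus") for i in range(3)
        ] + [make_trial([1], tid="b3", wasp_genus="Baryconus")]
        out = behavior_percentages(trials)
        row = out[out["group"] == "Baryconus"].iloc[0]
        assert row["attack_pct"] == pytest.approx(75.0)
        assert row["detect_pct"] == pytest.approx(25.0)

    def test_black_trials_pool_across_genera(self):
        trials = [
            make_trial([1], tid=f"g{i}", wasp_color="black",
                       wasp_genus=g)
            for i, g in enumerate(
                ["Baryconus", "Chromoteleia", "Macroteleia", "Scelio", "Scelio"]
            )
        ] + [make_trial([3], tid=f"h{i}", wasp_color="black") for i in range(5)]
        out = behavior_percentages(trials)
        row = out[out["group"] == "black (pooled)"].iloc[0]
        assert row["n_trials"] == 10
        assert row["detect_pct"] == pytest.approx(50.0)

    def test_zero_denominator_gives_nan_not_error(self):
        out = behavior_percentages([])
        assert out["detect_pct"].isna().all()

    def test_percentages_sum_to_100_per_group(self, rng):
        trials = gen_trials(TrialModel(), 80, rng)
        out = behavior_percentages(trials)
        present = out.dropna()
        sums = present[["detect_pct", "attack_pct", "avoid_pct"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0)


class TestMultinomialFit:
    def _counted_trials(self, n_detect, n_attack, n_avoid):
        trials = []
        for i, (code, n) in enumerate(zip([1, 3, 5], [n_detect, n_attack, n_avoid])):
            trials += [make_trial([code], tid=f"c{i}-{j}") for j in range(n)]
        return trials

    def test_intercept_only_mle_is_observed_proportions(self):
        trials = self._counted_trials(60, 30, 10)
        fit = fit_multinomial(trials, ())
        probs = fit.fitted_probabilities.iloc[0]
        assert probs["detect"] == pytest.approx(0.6, abs=1e-8)
        assert probs["attack"] == pytest.approx(0.3, abs=1e-8)
        assert probs["avoid"] == pytest.approx(0.1, abs=1e-8)
        expected_ll = 60 * np.log(0.6) + 30 * np.log(0.3) + 10 * np.log(0.1)
        assert fit.log_likelihood == pytest.approx(expected_ll, abs=1e-6)
        assert fit.n_params == 2
        assert aic(fit) == pytest.approx(2 * 2 - 2 * expected_ll)
        assert aic(fit) == pytest.approx(183.589, abs=1e-2)

    def test_probabilities_sum_to_one(self, rng):
        trials = gen_trials(TrialModel(), 120, rng)
        fit = fit_multinomial(trials, ("wasp_color", "spider_type"))
        sums = fit.fitted_probabilities.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_two_category_fit_equals_binary_logistic_oracle(self, rng):
        # avoid never observed: multinomial collapses to binary logistic
        trials = []
        for i in range(200):
            color = "BOB" if rng.random() < 0.5 else "black"
            p = 0.7 if color == "BOB" else 0.35
            code = 1 if rng.random() < p else 3
            trials.append(make_trial([code], tid=f"t{i}", wasp_color=color))
        fit = fit_multinomial(trials, ("wasp_color",), reference="attack")
        y = np.array([1 if most_common_action(t) == "detect" else 0 for t in trials])
        x = sm.add_constant(
            np.array([1.0 if t.wasp_color == "black" else 0.0 for t in trials])
        )
        oracle = sm.Logit(y, x).fit(disp=False)
        np.testing.assert_allclose(
            fit.coefficients["detect"].to_numpy(), oracle.params, atol=1e-6
        )

    def test_parameter_recovery_at_large_n(self, rng):
        model = TrialModel()
        trials = gen_trials(model, 2000, rng)
        fit = fit_multinomial(trials, ("wasp_color", "spider_type"))
        assert fit.converged
        # cell probabilities implied by the fit should approach the generator's
        probs = fit.fitted_probabilities.copy()
        probs["spider_type"] = [t.spider_type for t in trials]
        probs["wasp_color"] = [t.wasp_color for t in trials]
        cell = probs.groupby(["spider_type", "wasp_color"]).mean()
        for (stype, color), truth in model.action_probs.items():
            est = cell.loc[(stype, color)]
            for action, p in zip(GROUPED_ACTIONS, truth):
                assert est[action] == pytest.approx(p, abs=0.08)

    def test_rank_deficient_design_names_columns(self):
        trials = [make_trial([1], tid=f"a{i}") for i in range(10)] + [
            make_trial([3], tid=f"b{i}", wasp_color="black") for i in range(10)
        ]
        # wasp_genus is constant -> fine; duplicate covariate makes collinearity
        with pytest.raises(ValueError, match="collinear"):
            fit_multinomial(trials, ("wasp_color", "wasp_color"))


class TestModelSelection:
    def test_single_candidate_returned_unchanged(self, rng):
        trials = gen_trials(TrialModel(), 60, rng)
        best, tab = select_model(trials, [("wasp_color",)])
        assert best.covariates == ("wasp_color",)
        assert len(tab) == 1

    def test_duplicated_candidates_resolve_by_listed_order(self, rng):
        trials = gen_trials(TrialModel(), 60, rng)
        best, tab = select_model(trials, [("wasp_color",), ("wasp_color",)])
        assert tab.index[tab["aic"].idxmin()] == 0

    def test_selection_invariant_to_candidate_ordering(self, rng):
        trials = gen_trials(TrialModel(), 200, rng)
        cands = [tuple(ALL_COVARIATES), ("wasp_color", "spider_type"), ()]
        best_fwd, _ = select_model(trials, cands)
        best_rev, _ = select_model(trials, list(reversed(cands)))
        assert best_fwd.covariates == best_rev.covariates

    def test_aic_ordering_definition(self, rng):
        trials = gen_trials(TrialModel(), 150, rng)
        _, tab = select_model(
            trials, [(), ("wasp_color",), ("wasp_color", "spider_type")]
        )
        # nested models: log-likelihood never decreases with more parameters
        lls = tab.sort_values("n_params")["log_likelihood"].to_numpy()
        assert np.all(np.diff(lls) >= -1e-6)
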