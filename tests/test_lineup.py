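"""Tests of the joint four-group 2-HT lineup model: structure, degrees of
freedom, and the nested restriction tests."""

import numpy as np
import pytest

from mptlineup.lineup import (
    GroupSpec,
    HypothesisTestPlan,
    base_restrictions,
    build_joint_model,
    default_plans,
    study_groups,
    run_model_analysis,
)
from mptlineup.mpt import (
    FitOptions,
    FrequencyTable,
    category_probabilities,
    fit,
)


class TestModelConstruction:
    def test_four_groups_structure(self):
        model = build_joint_model(study_groups())
        assert len(model.trees) == 8
        assert len(model.free_parameters) == 16
        assert len(model.constants) == 2
        assert sorted(model.constants.values()) == [0.16667, 0.33333]

    def test_single_group_structure(self):
        model = build_joint_model([GroupSpec("g1", 3, "low")])
        assert len(model.trees) == 2
        assert len(model.free_parameters) == 4

    def test_six_person_guessing_filler_path(self):
        # (1-dP)(1-b) g (1 - 0.16667): with dP=b=0, g=1 the filler
        # probability is exactly 0.83333
        model = build_joint_model([GroupSpec("g1", 6, "low")])
        probs = category_probabilities(
            model, {"dP_g1": 0.0, "b_g1": 0.0, "g_g1": 1.0, "dA_g1": 0.0}
        )
        assert probs["g1.present"][1] == pytest.approx(0.83333, abs=1e-12)

    def test_exact_sampling_option(self):
        g = GroupSpec("g1", 6, "low", exact=True)
        assert g.constant == pytest.approx(1 / 6, abs=1e-15)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(Exception):
            build_joint_model([GroupSpec("x", 3, "low"), GroupSpec("x", 6, "low")])

    def test_showups_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("x", 1, "low")


class TestBaseRestrictions:
    def test_four_group_free_count_and_df(self, exp1_data):
        groups, freqs = exp1_data
        model = build_joint_model(groups)
        res = fit(model, freqs, base_restrictions(groups), FitOptions(n_starts=2))
        assert res.n_free_parameters == 10
        assert res.df == 6

    def test_single_group_restrictions_empty(self):
        assert base_restrictions([GroupSpec("g1", 3, "low")]).equalities == []

    def test_one_additional_equality_gains_a_df(self, exp1_analysis):
        assert all(
            t.restricted.df == exp1_analysis.base.df + 1
            for t in exp1_analysis.tests
        )


class TestHypothesisPlans:
    def test_default_plan_parameter_pairs(self):
        groups = study_groups()
        pairs = [p.parameter_pair(groups) for p in default_plans()]
        assert pairs[0] == ("dP_three_low", "dP_six_low")
        assert pairs[4] == ("g_three_low", "g_three_neutral")
        assert len(pairs) == 8

    def test_bad_stratum_rejected(self):
        with pytest.raises(Exception):
            HypothesisTestPlan("dP", "size", "nonexistent").parameter_pair(
                study_groups()
            )


class TestNestedTests:
    def test_delta_g2_nonnegative(self, exp1_analysis, exp2_analysis):
        for analysis in (exp1_analysis, exp2_analysis):
            for t in analysis.tests:
                assert t.delta_g2 >= 0
                assert t.df == 1

    def test_vacuous_restriction_changes_nothing(self):
        # data generated exactly at a point where the restricted pair is
        # already equal: the extra equality cannot reduce the fit
        groups = study_groups()
        model = build_joint_model(groups)
        point = {}
        for g in groups:
            point[f"dP_{g.label}"] = 0.3  # equal everywhere
            point[f"g_{g.label}"] = {"low": 0.4, "neutral": 0.6}[g.instruction]
            point[f"b_{g.label}"] = 0.05
            point[f"dA_{g.label}"] = 0.05
        probs = category_probabilities(model, point)
        freqs = FrequencyTable(
            {
                t.name: {
                    c: round(100000 * p)
                    for c, p in zip(t.categories, probs[t.name])
                }
                for t in model.trees
            }
        )
        analysis = run_model_analysis(
            freqs,
            [HypothesisTestPlan("dP", "size", "low")],
            groups,
            FitOptions(n_starts=3),
        )
        assert analysis.tests[0].delta_g2 == pytest.approx(0.0, abs=1e-2)

    def test_group_order_invariance(self, exp1_data, exp1_analysis):
        groups, freqs = exp1_data
        reordered = list(reversed(groups))
        analysis = run_model_analysis(
            freqs, default_plans(), reordered, FitOptions(seed=5)
        )
        assert analysis.base.g2 == pytest.approx(exp1_analysis.base.g2, abs=1e-6)
        for a, b in zip(analysis.tests, exp1_analysis.tests):
            assert a.delta_g2 == pytest.approx(b.delta_g2, abs=1e-5)
        for name, v in exp1_analysis.base.estimates.items():
            assert analysis.base.estimates[name] == pytest.approx(v, abs=1e-6)
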