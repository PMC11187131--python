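"""Unit tests for the generic MPT machinery: category probabilities,
G2, ML fitting against brute-force oracles, SEs, identifiability."""

import math

import numpy as np
import pytest

from mptlineup.lineup import GroupSpec, build_joint_model
from mptlineup.mpt import (
    Branch,
    DomainError,
    Factor,
    FitOptions,
    FrequencyTable,
    MissingAssignmentError,
    MptError,
    MptModel,
    Parameter,
    RestrictionSet,
    Tree,
    category_probabilities,
    check_identifiability,
    fit,
    g_squared,
    standard_errors,
)


def binomial_model():
    """One tree, two categories, P = (a, 1-a)."""
    tree = Tree(
        "t", ("hit", "miss"),
        (Branch((Factor("a"),), "hit"), Branch((Factor("a", True),), "miss")),
    )
    return MptModel([tree], [Parameter("a")])


def single_group_model():
    return build_joint_model([GroupSpec("grp", 3, "low")])


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "point, expected",
        [
            # certain detection: culprit identified with probability 1
            ({"dP_grp": 1.0, "b_grp": 0.7, "g_grp": 0.2, "dA_grp": 0.5},
             (1.0, 0.0, 0.0)),
            # all selection processes absent: rejection is certain
            ({"dP_grp": 0.0, "b_grp": 0.0, "g_grp": 0.0, "dA_grp": 0.5},
             (0.0, 0.0, 1.0)),
        ],
    )
    def test_degenerate_present_tree(self, point, expected):
        probs = category_probabilities(single_group_model(), point)
        assert probs["grp.present"] == pytest.approx(expected, abs=1e-12)

    def test_branch_product_hand_evaluation(self):
        # dP + (1-dP)b + (1-dP)(1-b)g/n at the published exp-1 point
        point = {"dP_grp": 0.31, "b_grp": 0.04, "g_grp": 0.39, "dA_grp": 0.0}
        probs = category_probabilities(single_group_model(), point)
        # 0.31 + 0.69*0.04 + 0.69*0.96*0.39*0.33333 = 0.42371114 (8 dp)
        assert probs["grp.present"][0] == pytest.approx(0.42371114, abs=5e-9)

    def test_vectors_sum_to_one(self):
        point = {"dP_grp": 0.31, "b_grp": 0.04, "g_grp": 0.39, "dA_grp": 0.03}
        for vec in category_probabilities(single_group_model(), point).values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)
            assert (vec >= 0).all()

    def test_missing_assignment_raises(self):
        with pytest.raises(MissingAssignmentError):
            category_probabilities(single_group_model(), {"dP_grp": 0.5})

    def test_out_of_domain_raises(self):
        point = {"dP_grp": 1.2, "b_grp": 0.0, "g_grp": 0.0, "dA_grp": 0.0}
        with pytest.raises(DomainError):
            category_probabilities(single_group_model(), point)


class TestGSquared:
    def test_saturated_agreement_is_zero(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 30, "miss": 70}})
        assert g_squared(model, {"a": 0.3}, freqs) == pytest.approx(0.0, abs=1e-10)

    def test_fixed_half_probabilities(self):
        # 2*(30 ln 0.6 + 70 ln 1.4) = 16.4566...
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 30, "miss": 70}})
        expected = 2 * (30 * math.log(0.6) + 70 * math.log(1.4))
        g2 = g_squared(model, {"a": 0.5}, freqs)
        assert g2 == pytest.approx(expected, abs=1e-10)
        assert round(g2, 2) == 16.46

    def test_zero_observed_cells_contribute_nothing(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 100, "miss": 0}})
        assert g_squared(model, {"a": 0.8}, freqs) == pytest.approx(
            2 * 100 * math.log(1 / 0.8)
        )

    def test_zero_expected_with_positive_observed_is_infinite(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 30, "miss": 70}})
        assert g_squared(model, {"a": 0.0}, freqs) == math.inf


class TestFit:
    def test_binomial_matches_grid_search_oracle(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 25, "miss": 75}})
        res = fit(model, freqs, options=FitOptions(seed=2))
        # brute-force maximization of the multinomial log-likelihood
        grid = np.linspace(1e-4, 1 - 1e-4, 10001)
        ll = 25 * np.log(grid) + 75 * np.log(1 - grid)
        best = grid[np.argmax(ll)]
        assert res.estimates["a"] == pytest.approx(best, abs=1e-4)
        assert res.estimates["a"] == pytest.approx(0.25, abs=1e-4)
        assert res.log_likelihood >= ll.max() - 1e-6

    def test_recovers_exact_expected_counts(self):
        # frequencies constructed as exact expected counts at an interior
        # point are recovered to high precision
        model = single_group_model()
        point = {"dP_grp": 0.31, "b_grp": 0.04, "g_grp": 0.39, "dA_grp": 0.03}
        probs = category_probabilities(model, point)
        counts = {
            tree.name: {
                cat: 1_000_000 * p
                for cat, p in zip(tree.categories, probs[tree.name])
            }
            for tree in model.trees
        }
        # FrequencyTable requires integers; scale to keep exact proportions
        freqs = FrequencyTable(
            {t: {c: round(v) for c, v in cats.items()} for t, cats in counts.items()}
        )
        res = fit(model, freqs, options=FitOptions(seed=3))
        for name, truth in point.items():
            assert res.estimates[name] == pytest.approx(truth, abs=1e-3)

    def test_empty_tree_is_an_error(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 0, "miss": 0}})
        with pytest.raises(MptError):
            fit(model, freqs)

    def test_fixed_value_restriction_is_honoured(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 25, "miss": 75}})
        res = fit(model, freqs, RestrictionSet(fixed={"a": 0.5}))
        assert res.estimates["a"] == 0.5
        assert res.n_free_parameters == 0
        assert res.g2 == pytest.approx(2 * (25 * math.log(0.5) + 75 * math.log(1.5)))


class TestStandardErrors:
    def test_binomial_closed_form(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 25, "miss": 75}})
        res = fit(model, freqs)
        se = standard_errors(model, res.estimates, freqs)
        assert se["a"] == pytest.approx(math.sqrt(0.25 * 0.75 / 100), abs=1e-4)

    def test_boundary_estimate_suppresses_se(self):
        model = binomial_model()
        freqs = FrequencyTable({"t": {"hit": 100, "miss": 0}})
        res = fit(model, freqs)
        assert res.standard_errors["a"] is None
        assert any("boundary" in w for w in res.warnings)


class TestIdentifiability:
    def test_joint_base_model_is_identifiable(self, exp1_data):
        from mptlineup.lineup import base_restrictions

        groups, _ = exp1_data
        model = build_joint_model(groups)
        rep = check_identifiability(model, base_restrictions(groups))
        assert rep.n_free_parameters == 10
        assert rep.n_independent_categories == 16
        assert rep.rank == 10
        assert rep.identifiable

    def test_single_present_tree_is_rank_deficient(self):
        # dP and b both free with only one culprit-present tree: dP and b
        # trade off, so the Jacobian loses rank
        model = single_group_model()
        model = MptModel([model.tree("grp.present")], model.parameters.values())
        rep = check_identifiability(
            model, RestrictionSet(fixed={"dA_grp": 0.5})
        )
        assert rep.rank < rep.n_free_parameters
        assert not rep.identifiable

    def test_fixed_parameters_are_excluded(self):
        model = binomial_model()
        rep = check_identifiability(model, RestrictionSet(fixed={"a": 0.3}))
        assert rep.n_free_parameters == 0


class TestRestrictionSet:
    def test_parameter_in_two_classes_rejected(self):
        with pytest.raises(MptError):
            RestrictionSet(equalities=[frozenset("ab"), frozenset("bc")])

    def test_with_equality_merges_classes(self):
        rs = RestrictionSet(equalities=[frozenset(["a", "b"])])
        merged = rs.with_equality(["b", "c"])
        assert frozenset(["a", "b", "c"]) in merged.equalities

    def test_fixed_value_domain_checked(self):
        with pytest.raises(DomainError):
            RestrictionSet(fixed={"a": 1.5})
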