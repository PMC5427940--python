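"""Birth-death transition probabilities, pruning likelihood, fitting, error."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famturnover import (
    ErrorModel,
    FamilyCountTable,
    RateModel,
    estimate_error,
    family_log_likelihood,
    fit_model,
    observation_probability,
    parse_chronogram,
    simulate_count_table,
    table_log_likelihood,
    transition_probability,
)
from famturnover.bd_likelihood import observation_matrix, transition_matrix

from conftest import drop_unobserved


def slow_transition(s, c, lam, mu, t):
    """Independent scalar evaluation of the survivor-sum closed form."""
    if abs(lam - mu) * t < 1e-8:
        a = b = lam * t / (1 + lam * t)
    else:
        e = math.exp((lam - mu) * t)
        a = mu * (e - 1) / (lam * e - mu)
        b = lam * (e - 1) / (lam * e - mu)
    if s == 0:
        return 1.0 if c == 0 else 0.0
    if c == 0:
        return a**s
    return sum(
        math.comb(s, j) * a ** (s - j) * (1 - a) ** j
        * math.comb(c - 1, j - 1) * (1 - b) ** j * b ** (c - j)
        for j in range(1, min(s, c) + 1)
    )


class TestTransitionProbability:
    def test_zero_rates_are_identity(self):
        assert transition_probability(3, 3, 0.0, 0.0, 50.0) == pytest.approx(1.0)
        assert transition_probability(3, 2, 0.0, 0.0, 50.0) == pytest.approx(0.0)

    def test_critical_extinction_closed_form(self):
        # alpha = lam t / (1 + lam t) = 0.1 / 1.1
        p = transition_probability(1, 0, 0.001, 0.001, 100.0)
        assert p == pytest.approx(0.1 / 1.1, rel=1e-12)

    def test_zero_is_absorbing(self):
        assert transition_probability(0, 0, 0.002, 0.001, 10.0) == 1.0
        assert transition_probability(0, 3, 0.002, 0.001, 10.0) == 0.0

    @pytest.mark.parametrize(
        "lam, mu, t",
        [(0.0008, 0.0008, 80.0), (0.0004, 0.0030, 80.0), (0.01, 0.002, 40.0),
         (0.0, 0.01, 50.0), (0.01, 0.0, 50.0)],
    )
    def test_rows_normalize_at_adequate_truncation(self, lam, mu, t):
        M = transition_matrix(50, lam, mu, t)
        sums = M[:6].sum(axis=1)
        assert np.all(sums >= 1 - 1e-9)
        assert np.all((M >= 0) & (M <= 1 + 1e-12))

    @pytest.mark.parametrize("lam, mu, t", [(0.003, 0.001, 30.0), (0.001, 0.004, 60.0)])
    def test_matches_independent_scalar_form(self, lam, mu, t):
        M = transition_matrix(15, lam, mu, t)
        for s in range(16):
            for c in range(16):
                assert M[s, c] == pytest.approx(
                    slow_transition(s, c, lam, mu, t), rel=1e-10, abs=1e-300
                )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(1, 1, -0.1, 0.1, 1.0)
        with pytest.raises(ValueError):
            transition_probability(1, 1, 0.1, 0.1, 0.0)


class TestObservationChannel:
    def test_identity_channel(self):
        assert observation_probability(5, 5, 0.0) == 1.0

    def test_neighbour_mass(self):
        assert observation_probability(5, 4, 0.2) == pytest.approx(0.1)
        assert observation_probability(5, 6, 0.2) == pytest.approx(0.1)

    def test_zero_boundary_reflection(self):
        assert observation_probability(0, 0, 0.2) == pytest.approx(0.9)
        assert observation_probability(0, 1, 0.2) == pytest.approx(0.1)

    @given(
        true=st.integers(min_value=0, max_value=12),
        eps=st.floats(min_value=0.0, max_value=0.99),
    )
    @settings(derandomize=True, max_examples=50)
    def test_rows_sum_to_one(self, true, eps):
        total = sum(observation_probability(true, o, eps) for o in range(15))
        assert total == pytest.approx(1.0)

    def test_matrix_rows_sum_to_one_with_fold(self):
        E = observation_matrix(6, 0.3)
        assert np.allclose(E.sum(axis=1), 1.0)

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            observation_probability(1, 1, 1.0)


class TestPruningLikelihood:
    def test_two_tip_point_mass_root_is_product_of_transitions(self):
        tree = parse_chronogram("(A:3.0,B:3.0);")
        lam, mu, r = 0.02, 0.01, 2
        model = RateModel.single(tree, lam, mu, tied=False)
        ll = family_log_likelihood({"A": 3, "B": 1}, tree, model,
                                   root_prior=("point", r))
        expected = math.log(
            slow_transition(r, 3, lam, mu, 3.0) * slow_transition(r, 1, lam, mu, 3.0)
        )
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_zero_rate_identical_counts_give_likelihood_one(self, three_tip_tree):
        model = RateModel.single(three_tip_tree, 0.0)
        ll = family_log_likelihood({"A": 3, "B": 3, "C": 3}, three_tip_tree,
                                   model, root_prior=("point", 3))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_pruning_equals_brute_force_enumeration(self, three_tip_tree):
        """Sum over all ancestral assignments on the 3-tip tree."""
        S = 4
        lam, mu = 0.1, 0.15
        model = RateModel.single(three_tip_tree, lam, mu, tied=False)
        prof = {"A": 2, "B": 1, "C": 0}
        PAB = transition_matrix(S, lam, mu, 1.0)
        PC = transition_matrix(S, lam, mu, 2.0)
        total = sum(
            (1 / S) * PAB[r, m] * PAB[m, prof["A"]] * PAB[m, prof["B"]]
            * PC[r, prof["C"]]
            for r in range(1, S + 1)
            for m in range(S + 1)
        )
        ll = family_log_likelihood(prof, three_tip_tree, model, S=S)
        assert ll == pytest.approx(math.log(total), rel=1e-10)

    def test_pruning_with_error_equals_brute_force(self, three_tip_tree):
        S = 4
        lam, mu, eps = 0.1, 0.15, 0.1
        model = RateModel.single(three_tip_tree, lam, mu, tied=False)
        prof = {"A": 2, "B": 1, "C": 0}
        PAB = transition_matrix(S, lam, mu, 1.0)
        PC = transition_matrix(S, lam, mu, 2.0)
        E = observation_matrix(S, eps)
        total = sum(
            (1 / S) * PAB[r, m]
            * PAB[m, a] * E[a, prof["A"]]
            * PAB[m, b] * E[b, prof["B"]]
            * PC[r, c] * E[c, prof["C"]]
            for r in range(1, S + 1)
            for m in range(S + 1)
            for a in range(S + 1)
            for b in range(S + 1)
            for c in range(S + 1)
        )
        ll = family_log_likelihood(prof, three_tip_tree, model,
                                   ErrorModel(eps), S=S)
        assert ll == pytest.approx(math.log(total), rel=1e-10)

    def test_invariant_under_species_and_family_relabeling(self, fixture_tree):
        model = RateModel.single(fixture_tree, 0.002)
        table, _, _ = simulate_count_table(fixture_tree, model, 30, seed=3)
        table = drop_unobserved(table)
        ll1 = table_log_likelihood(table, fixture_tree, model)
        shuffled = FamilyCountTable(
            table.df[list(reversed(table.species))].rename(
                index=lambda f: f + "_renamed"
            )
        )
        ll2 = table_log_likelihood(shuffled, fixture_tree, model)
        assert np.allclose(ll1, ll2)

    def test_zero_eps_matches_no_error_path_exactly(self, fixture_tree):
        model = RateModel.single(fixture_tree, 0.002)
        table, _, _ = simulate_count_table(fixture_tree, model, 20, seed=4)
        table = drop_unobserved(table)
        ll0 = table_log_likelihood(table, fixture_tree, model, None)
        llz = table_log_likelihood(table, fixture_tree, model, ErrorModel(0.0))
        assert np.array_equal(ll0, llz)

    def test_all_zero_profile_rejected(self, three_tip_tree):
        model = RateModel.single(three_tip_tree, 0.01)
        with pytest.raises(ValueError, match="all-zero"):
            family_log_likelihood({"A": 0, "B": 0, "C": 0}, three_tip_tree, model)

    def test_state_cap_overflow_advises(self, three_tip_tree):
        model = RateModel.single(three_tip_tree, 0.01)
        with pytest.raises(ValueError, match="increase S"):
            table_log_likelihood(
                np.array([[9, 1, 1]]), three_tip_tree, model, S=4
            )


class TestFitModel:
    def test_no_change_data_drives_rate_to_zero(self, three_tip_tree):
        rng = np.random.default_rng(0)
        roots = rng.integers(1, 5, size=60)
        df = pd.DataFrame(
            {sp: roots for sp in ["A", "B", "C"]},
            index=pd.Index([f"F{i}" for i in range(60)], name="family_id"),
        )
        res = fit_model(FamilyCountTable(df), three_tip_tree,
                        RateModel.single(three_tip_tree), n_restarts=2, seed=0)
        assert res.model.lams[0] < 1e-6

    def test_tied_rate_recovery_rough(self, fixture_tree):
        """Sanity-scale parameter recovery (the full-scale run lives in the
        acceptance suite)."""
        truth = RateModel.single(fixture_tree, 0.0017)
        table, _, _ = simulate_count_table(fixture_tree, truth, 300, seed=8)
        table = drop_unobserved(table)
        res = fit_model(table, fixture_tree, RateModel.single(fixture_tree),
                        n_restarts=2, seed=1)
        assert 0.5 * 0.0017 < res.model.lams[0] < 2.0 * 0.0017

    def test_fit_reproducible_given_seed(self, fixture_tree):
        truth = RateModel.single(fixture_tree, 0.001)
        table, _, _ = simulate_count_table(fixture_tree, truth, 100, seed=12)
        table = drop_unobserved(table)
        spec = RateModel.single(fixture_tree)
        r1 = fit_model(table, fixture_tree, spec, n_restarts=3, seed=7)
        r2 = fit_model(table, fixture_tree, spec, n_restarts=3, seed=7)
        assert r1.neg_log_likelihood == r2.neg_log_likelihood
        assert np.array_equal(r1.model.lams, r2.model.lams)

    def test_multi_class_model_reports_one_rate_per_class(self, fixture_tree):
        truth = RateModel.single(fixture_tree, 0.001)
        table, _, _ = simulate_count_table(fixture_tree, truth, 80, seed=13)
        table = drop_unobserved(table)
        spec = RateModel.from_clades(
            fixture_tree,
            {"owf": ["R._aegyptiacus", "P._vampyrus"],
             "yango": ["M._natalensis", "M._brandtii"]},
            tied=False,
        )
        res = fit_model(table, fixture_tree, spec, n_restarts=1, seed=1)
        assert len(res.model.lams) == 3 and len(res.model.mus) == 3
        assert res.aic == pytest.approx(2 * 6 + 2 * res.neg_log_likelihood)


@pytest.fixture(scope="module")
def five_tip_tree():
    return parse_chronogram("(((A:10,B:10):10,C:20):20,(D:25,E:25):15);")


class TestErrorEstimation:
    def test_global_error_recovery(self, five_tip_tree):
        truth = RateModel.single(five_tip_tree, 0.004)
        table, _, _ = simulate_count_table(five_tip_tree, truth, 2000, seed=20)
        table = drop_unobserved(table)
        from famturnover import corrupt_with_error

        noisy = corrupt_with_error(table, ErrorModel(0.10), seed=21)
        noisy = drop_unobserved(noisy)
        err, res = estimate_error(noisy, five_tip_tree,
                                  RateModel.single(five_tip_tree),
                                  scope="global", seed=1)
        assert 0.05 <= err.eps <= 0.15

    def test_clean_species_gets_near_zero_eps(self, five_tip_tree):
        truth = RateModel.single(five_tip_tree, 0.004)
        table, _, _ = simulate_count_table(five_tip_tree, truth, 800, seed=22)
        table = drop_unobserved(table)
        from famturnover import corrupt_with_error

        eps = {sp: 0.12 for sp in five_tip_tree.tip_labels}
        eps["A"] = 0.0
        noisy = drop_unobserved(
            corrupt_with_error(table, ErrorModel(eps), seed=23)
        )
        err, _ = estimate_error(noisy, five_tip_tree,
                                RateModel.single(five_tip_tree),
                                scope="per_species", seed=1, max_cycles=2)
        assert err.eps["A"] <= 0.02

    def test_estimate_never_worse_than_zero_error(self, five_tip_tree):
        truth = RateModel.single(five_tip_tree, 0.004)
        table, _, _ = simulate_count_table(five_tip_tree, truth, 400, seed=24)
        table = drop_unobserved(table)
        err, res = estimate_error(table, five_tip_tree,
                                  RateModel.single(five_tip_tree),
                                  scope="global", seed=1)
        base = fit_model(table, five_tip_tree, RateModel.single(five_tip_tree),
                         ErrorModel(0.0), n_restarts=2, seed=1)
        assert res.neg_log_likelihood <= base.neg_log_likelihood + 1e-6
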