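import numpy as np
import pytest

from rotshift import mk_models as mk
from rotshift import phylo_core as pc
from rotshift import synthetic_data as sd

from _oracles import enumeration_log_likelihood


class TestQSpec:
    @pytest.mark.parametrize(
        "model,scheme,k",
        [
            ("uncorrelated", "ARD", 30),
            ("correlated_hosts", "ARD", 14),
            ("correlated_hosts_norev", "ARD", 11),
            ("uncorrelated", "ER", 1),
            ("correlated_hosts", "ER", 1),
            ("correlated_hosts_norev", "ER", 1),
        ],
    )
    def test_free_parameter_counts(self, model, scheme, k):
        assert mk.build_qspec(model, scheme).k == k

    def test_no_direct_specialist_to_specialist_moves(self):
        qs = mk.build_qspec("correlated_hosts", "ARD")
        # angiosperm specialist <-> gymnosperm specialist forbidden (0-based 0<->2, 1<->3)
        for i, j in [(0, 2), (2, 0), (1, 3), (3, 1)]:
            assert not qs.mask[i, j]

    def test_norev_blocks_brown_to_white(self):
        qs = mk.build_qspec("correlated_hosts_norev", "ARD")
        for b in (1, 3, 5):
            for w in (0, 2, 4):
                assert not qs.mask[b, w]
        # but white -> brown decay switches remain
        assert qs.mask[0, 1] and qs.mask[2, 3] and qs.mask[4, 5]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            mk.build_qspec("nope", "ER")


class TestBuildQ:
    def test_zero_rates_give_zero_matrix(self):
        qs = mk.build_qspec("uncorrelated", "ARD")
        assert np.all(mk.build_q(qs, np.zeros(30)) == 0)

    def test_er_structure(self):
        qs = mk.build_qspec("uncorrelated", "ER")
        Q = mk.build_q(qs, np.array([0.4]))
        off = Q[~np.eye(6, dtype=bool)]
        assert np.allclose(off, 0.4)
        assert np.allclose(np.diag(Q), -2.0)
        assert np.allclose(Q.sum(axis=1), 0)

    def test_norev_zero_cells(self):
        qs = mk.build_qspec("correlated_hosts_norev", "ARD")
        Q = mk.build_q(qs, np.arange(1.0, 12.0))
        for b in (1, 3, 5):
            for w in (0, 2, 4):
                assert Q[b, w] == 0

    def test_negative_rate_rejected(self):
        qs = mk.build_qspec("uncorrelated", "ER")
        with pytest.raises(ValueError):
            mk.build_q(qs, np.array([-1.0]))


class TestTransitionProb:
    def test_identity_at_zero(self):
        Q = mk.build_q(mk.build_qspec("correlated_hosts", "ER"), np.array([1.3]))
        assert np.allclose(mk.transition_prob(Q, 0.0), np.eye(6), atol=1e-12)

    def test_equal_rates_closed_form(self):
        """Unconstrained ER chain: P_ii(t) = 1/6 + (5/6) e^{-6rt}."""
        r, t = 0.37, 0.9
        Q = mk.build_q(mk.build_qspec("uncorrelated", "ER"), np.array([r]))
        P = mk.transition_prob(Q, t)
        expected_diag = 1 / 6 + 5 / 6 * np.exp(-6 * r * t)
        assert np.allclose(np.diag(P), expected_diag, atol=1e-12)
        assert np.allclose(P[~np.eye(6, dtype=bool)],
                           (1 - expected_diag) / 5, atol=1e-12)

    def test_semigroup_property(self, rng):
        qs = mk.build_qspec("correlated_hosts_norev", "ARD")
        Q = mk.build_q(qs, rng.uniform(0.1, 2.0, qs.k))
        P1 = mk.transition_prob(Q, 0.4)
        P2 = mk.transition_prob(Q, 0.7)
        P3 = mk.transition_prob(Q, 1.1)
        assert np.allclose(P1 @ P2, P3, atol=1e-8)

    def test_rows_are_distributions(self, rng):
        for model in mk.MODEL_NAMES:
            qs = mk.build_qspec(model, "ARD")
            Q = mk.build_q(qs, rng.uniform(0, 5.0, qs.k))
            P = mk.transition_probs(Q, np.array([0.0, 0.1, 2.0, 50.0]))
            assert np.all(P >= 0)
            assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)

    def test_negative_time_rejected(self):
        Q = mk.build_q(mk.build_qspec("uncorrelated", "ER"), np.array([1.0]))
        with pytest.raises(ValueError):
            mk.transition_prob(Q, -0.1)


class TestTreeLikelihood:
    def test_single_tip_is_log_prior(self):
        tree = pc.tree_from_string("A:0;")
        Q = mk.build_q(mk.build_qspec("uncorrelated", "ER"), np.array([1.0]))
        lnL = mk.tree_likelihood(tree, {"A": 3}, Q, mk.RootPrior.flat())
        assert lnL == pytest.approx(np.log(1 / 6))

    def test_matches_enumeration_oracle(self, rng):
        """Pruning equals exhaustive summation on small random instances."""
        for rep in range(30):
            n = int(rng.integers(2, 7))
            tree = sd.simulate_tree(n, seed=int(rng.integers(2**31)))
            model = mk.MODEL_NAMES[rep % 3]
            qs = mk.build_qspec(model, "ARD")
            Q = mk.build_q(qs, rng.uniform(0.05, 2.0, qs.k))
            states = {lb: int(rng.integers(1, 7)) for lb in pc.tip_labels(tree)}
            pi = np.full(6, 1 / 6)
            l_pruning = mk.tree_likelihood(tree, states, Q, mk.RootPrior.flat())
            l_enum = enumeration_log_likelihood(tree, states, Q, pi)
            if np.isinf(l_enum):
                assert np.isinf(l_pruning)
            else:
                assert l_pruning == pytest.approx(l_enum, abs=1e-10)

    def test_ambiguous_tip_sums_states(self, three_tip_tree):
        qs = mk.build_qspec("uncorrelated", "ER")
        Q = mk.build_q(qs, np.array([0.3]))
        prior = mk.RootPrior.flat()
        ambiguous = mk.tree_likelihood(
            three_tip_tree, {"A": 1, "B": 2, "C": [3, 4]}, Q, prior
        )
        parts = [
            mk.tree_likelihood(three_tip_tree, {"A": 1, "B": 2, "C": s}, Q, prior)
            for s in (3, 4)
        ]
        assert np.exp(ambiguous) == pytest.approx(sum(np.exp(p) for p in parts))

    def test_rate_to_zero_limit(self, balanced_four_tree):
        qs = mk.build_qspec("uncorrelated", "ER")
        Q = mk.build_q(qs, np.array([1e-12]))
        states = {lb: 5 for lb in pc.tip_labels(balanced_four_tree)}
        lnL = mk.tree_likelihood(balanced_four_tree, states, Q, mk.RootPrior.flat())
        assert lnL == pytest.approx(np.log(1 / 6), abs=1e-6)

    def test_invariant_to_tip_ordering(self):
        a = pc.tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        b = pc.tree_from_string("((D:1,C:1):1,(B:1,A:1):1);")
        qs = mk.build_qspec("correlated_hosts", "ARD")
        rng = np.random.default_rng(3)
        Q = mk.build_q(qs, rng.uniform(0.1, 1.5, qs.k))
        states = {"A": 1, "B": 5, "C": 3, "D": 6}
        la = mk.tree_likelihood(a, states, Q, mk.RootPrior.flat())
        lb = mk.tree_likelihood(b, states, Q, mk.RootPrior.flat())
        assert la == pytest.approx(lb, abs=1e-12)

    def test_invariant_to_zero_length_resolution(self):
        """A polytomy and any of its zero-length resolutions agree."""
        star = pc.tree_from_string("(A:1,B:1,C:1,D:1,E:1);")
        states = {"A": 1, "B": 1, "C": 5, "D": 6, "E": 3}
        qs = mk.build_qspec("uncorrelated", "ARD")
        rng = np.random.default_rng(8)
        Q = mk.build_q(qs, rng.uniform(0.1, 1.0, qs.k))
        l_star = mk.tree_likelihood(star, states, Q, mk.RootPrior.flat())
        for seed in range(3):
            resolved = pc.resolve_polytomies_random(star, seed=seed)
            l_res = mk.tree_likelihood(resolved, states, Q, mk.RootPrior.flat())
            assert l_res == pytest.approx(l_star, abs=1e-10)

    def test_unknown_tip_state_rejected(self, three_tip_tree):
        Q = mk.build_q(mk.build_qspec("uncorrelated", "ER"), np.array([1.0]))
        with pytest.raises(KeyError):
            mk.tree_likelihood(three_tip_tree, {"A": 1, "B": 2}, Q, mk.RootPrior.flat())


class TestRootPrior:
    def test_white_rot_equal_vector(self):
        pi = mk.RootPrior.white_rot_equal().pi
        np.testing.assert_allclose(pi, [1 / 3, 0, 1 / 3, 0, 1 / 3, 0])

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            mk.RootPrior(np.array([0.5, 0.5, 0, 0, 0, 0.5]))


class TestAICAndComparison:
    @pytest.mark.parametrize(
        "lnL,k,printed",
        [
            (-1870.83, 1, 3743.65),   # within rounding of the printed value
            (-1180.64, 30, 2421.27),
            (-1774.09, 1, 3550.19),
            (-1183.56, 14, 2395.12),
            (-1941.71, 1, 3885.41),
            (-1183.66, 11, 2389.32),
            (-1182.97, 11, 2387.93),
        ],
    )
    def test_aic_formula_reproduces_model_table(self, lnL, k, printed):
        assert mk.aic(lnL, k) == pytest.approx(printed, abs=0.02)

    def test_akaike_weights_from_delta_vector(self):
        delta = np.array([1355.72, 33.34, 1162.25, 7.19, 1497.48, 1.39, 0.0])
        w = mk.akaike_weights(delta)
        # published weights are printed at 2 dp (and computed from
        # unrounded AICs), so compare at the printing resolution
        np.testing.assert_allclose(
            w, [0.00, 0.00, 0.00, 0.02, 0.00, 0.33, 0.65], atol=0.0075
        )

    def test_comparison_invariants(self, rng):
        fits = []
        for k, lnL in [(1, -500.0), (11, -430.0), (30, -428.0)]:
            qs = mk.build_qspec("uncorrelated", "ER")
            fits.append(
                mk.MkFit(qs, np.ones(1), lnL, k, mk.aic(lnL, k), True, 1,
                         mk.RootPrior.flat())
            )
        comp = mk.compare_models(fits)
        assert comp.delta_aic.min() == 0
        assert comp.weights.sum() == pytest.approx(1.0)
        assert np.argmax(comp.weights) == np.argmin([f.aic for f in fits])
        # permutation equivariance
        perm = rng.permutation(3)
        comp2 = mk.compare_models([fits[i] for i in perm])
        np.testing.assert_allclose(comp2.weights, comp.weights[perm])


@pytest.fixture(scope="module")
def er_fit():
    tree = sd.simulate_tree(80, seed=21)
    tree = pc.rescale_height(tree, 1.0)
    _, Q = sd.default_norev_q(1.0)
    states, _ = sd.simulate_discrete(
        tree, Q, mk.RootPrior.white_rot_equal(), seed=22
    )
    qs = mk.build_qspec("correlated_hosts_norev", "ER")
    fit = mk.fit_mk(tree, states, qs, n_restarts=3, seed=1)
    return tree, states, fit


class TestFitAndReport:
    def test_er_fit_beats_grid(self, er_fit):
        tree, states, fit = er_fit
        assert fit.converged
        qs = fit.qspec
        prior = fit.prior
        lik = mk.TreeLikelihood(tree, states)
        for rate in [0.05, 0.2, 0.5, 1.0, 2.0, 5.0]:
            grid_lnL = lik.log_likelihood(mk.build_q(qs, np.array([rate])), prior)
            assert fit.lnL >= grid_lnL - 1e-6

    def test_aic_consistent_with_lnl_and_k(self, er_fit):
        _, _, fit = er_fit
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.lnL)

    def test_er_report_shares_one_value(self, er_fit):
        _, _, fit = er_fit
        table = mk.report_rates(fit)
        assert len(table) == 11
        assert table["estimate"].nunique() == 1

    def test_nested_models_order_likelihoods(self, er_fit):
        """uncorrelated >= correlated_hosts >= norev in max lnL (nesting)."""
        tree, states, _ = er_fit
        lnls = {}
        for model in mk.MODEL_NAMES:
            qs = mk.build_qspec(model, "ARD")
            lnls[model] = mk.fit_mk(tree, states, qs, n_restarts=2, seed=5).lnL
        assert lnls["uncorrelated"] >= lnls["correlated_hosts"] - 0.05
        assert lnls["correlated_hosts"] >= lnls["correlated_hosts_norev"] - 0.05

    def test_norev_report_has_no_reversal_rows(self, er_fit):
        _, _, fit = er_fit
        table = mk.report_rates(fit)
        brown = {2, 4, 6}
        white = {1, 3, 5}
        assert not any(
            (r.from_state in brown) and (r.to_state in white)
            for r in table.itertuples(index=False)
        )
        assert len(table) == 11
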