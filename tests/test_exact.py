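"""Brute-force chain oracle: constituents, stationary solve, attractors,
influences."""

import numpy as np
import pytest

from pbnfit import (ReducibleChainError, StateSpaceError, bottom_sccs,
                    build_pbn, enumerate_constituents, exact_marginal,
                    influence, marginal_probability, parse_rules,
                    stationary_distribution, transition_matrix)
from pbnfit import casestudies as cs


class TestConstituents:
    def test_example_model_has_two(self, example_pbn):
        cons = enumerate_constituents(example_pbn)
        assert sorted(prob for _, prob in cons) == pytest.approx([0.4, 0.6])

    def test_single_rule_network_has_one(self):
        pbn = build_pbn(parse_rules("B = A\nC = B\n"))
        cons = enumerate_constituents(pbn)
        assert len(cons) == 1 and cons[0][1] == pytest.approx(1.0)

    def test_product_structure(self):
        pbn = build_pbn(parse_rules(
            "B = A : 0.3\nB = ~A : 0.7\n"
            "C = A : 0.5\nC = B : 0.25\nC = A | B : 0.25\n"))
        cons = enumerate_constituents(pbn)
        assert len(cons) == 6
        assert sum(p for _, p in cons) == pytest.approx(1.0)
        assert sorted(p for _, p in cons) == pytest.approx(
            sorted([0.3 * 0.5, 0.3 * 0.25, 0.3 * 0.25,
                    0.7 * 0.5, 0.7 * 0.25, 0.7 * 0.25]))

    def test_cap_enforced(self):
        pbn = cs.random_pbn(6, max_rules=3, seed=0)
        with pytest.raises(StateSpaceError):
            enumerate_constituents(pbn, cap=4)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self, example_pbn):
        for p in (0.0, 0.001, 0.3):
            chain = transition_matrix(example_pbn, {}, p=p)
            assert np.allclose(chain.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_two_state_subchain_under_both_inputs(self, example_pbn):
        chain = transition_matrix(example_pbn, {"N1": 1, "N2": 1}, p=0.0)
        # both rows: 0.4 to N3=0, 0.6 to N3=1
        assert chain.matrix == pytest.approx(np.array([[0.4, 0.6],
                                                       [0.4, 0.6]]))

    def test_deterministic_bn_gives_01_rows(self):
        pbn = build_pbn(parse_rules("B = A\nC = A & B\n"))
        chain = transition_matrix(pbn, {"A": 1}, p=0.0)
        assert set(np.unique(chain.matrix)) <= {0.0, 1.0}

    def test_perturbation_connects_all_states(self):
        pbn = cs.random_pbn(4, seed=5)
        P = transition_matrix(pbn, {}, p=0.01).matrix
        off = P[~np.eye(len(P), dtype=bool)]
        assert off.min() > 0.0

    def test_equals_weighted_sum_of_constituents_at_p0(self, example_pbn):
        chain = transition_matrix(example_pbn, {"N1": 1, "N2": 1}, p=0.0)
        cons = enumerate_constituents(example_pbn)
        acc = np.zeros_like(chain.matrix)
        for choice, prob in cons:
            det = np.zeros_like(chain.matrix)
            for s in range(chain.matrix.shape[0]):
                env = chain.state_bits(s)
                t = choice["N3"](env)
                det[s, t] = 1.0
            acc += prob * det
        assert np.allclose(acc, chain.matrix, atol=1e-12)

    def test_state_space_cap(self):
        pbn = cs.random_pbn(10, seed=1)
        with pytest.raises(StateSpaceError):
            transition_matrix(pbn, {}, p=0.001, max_entries=2 ** 10)


class TestStationary:
    def test_example_marginal_is_06(self, example_pbn):
        chain = transition_matrix(example_pbn, {"N1": 1, "N2": 1}, p=0.0)
        pi = stationary_distribution(chain)
        assert marginal_probability(pi, chain, "N3") == pytest.approx(0.6)
        # clamped nodes report their clamp value
        assert marginal_probability(pi, chain, "N1") == 1.0

    def test_limits_for_other_clamp_patterns(self, example_pbn):
        assert exact_marginal(example_pbn, "N3", {"N1": 1, "N2": 0},
                              p=0.0) == pytest.approx(1.0)
        assert exact_marginal(example_pbn, "N3", {"N1": 0, "N2": 0},
                              p=0.0) == pytest.approx(0.0)

    def test_reducible_chain_rejected(self):
        pbn = build_pbn(parse_rules("B = B\n"), perturbation_p=0.0)
        chain = transition_matrix(pbn, {}, p=0.0)   # identity: B holds
        with pytest.raises(ReducibleChainError):
            stationary_distribution(chain)

    @pytest.mark.parametrize("seed", [2, 9])
    def test_two_solvers_agree(self, seed):
        """Eigen solve vs explicit power iteration on a random perturbed
        chain."""
        pbn = cs.random_pbn(4, seed=seed)
        chain = transition_matrix(pbn, {}, p=0.001)
        pi = stationary_distribution(chain)
        pw = np.full(len(pi), 1 / len(pi))
        for _ in range(200_000):
            nxt = pw @ chain.matrix
            if np.max(np.abs(nxt - pw)) < 1e-14:
                pw = nxt
                break
            pw = nxt
        assert np.max(np.abs(pi - pw)) < 1e-10
        assert np.max(np.abs(pi @ chain.matrix - pi)) < 1e-10


class TestBottomSccs:
    def test_example_model_attractors(self, example_pbn):
        chain = transition_matrix(example_pbn, {}, p=0.0)

        def render(states):
            return sorted(
                "".join(str(chain.state_bits(s)[n]) for n in example_pbn.nodes)
                for s in states)

        comps = [render(c) for c in bottom_sccs(example_pbn)]
        assert sorted(map(tuple, comps)) == [("000",), ("010",), ("101",),
                                             ("110", "111")]

    def test_fixed_point_of_deterministic_bn(self):
        pbn = build_pbn(parse_rules("B = A\nC = A & B\n"),
                        perturbation_p=0.0)
        comps = bottom_sccs(pbn, {"A": 0})
        assert {frozenset(c) for c in comps} == {frozenset({0})}

    def test_perturbation_merges_everything(self, example_pbn):
        chain = transition_matrix(example_pbn, {}, p=0.01)
        # every off-diagonal transition possible: one communicating class
        P = chain.matrix
        assert P[~np.eye(len(P), dtype=bool)].min() > 0


class TestInfluence:
    def test_partial_inhibitor_influence(self, example_pbn):
        """Influence of N2 on N3 is 0.4 * P(N1=1): toggling N2 only matters
        under the second predictor, and only when N1 is ON."""
        chain = transition_matrix(example_pbn, {}, p=0.01)
        pi = stationary_distribution(chain)
        states = np.arange(len(pi))
        p_n1 = pi[chain.node_bit(states, "N1") == 1].sum()
        val = influence(example_pbn, "N2", "N3", pi, chain)
        assert val == pytest.approx(0.4 * p_n1, abs=1e-12)

    def test_activator_influence_is_total_when_inhibitor_off(self, example_pbn):
        chain = transition_matrix(example_pbn, {"N2": 0}, p=0.01)
        pi = stationary_distribution(chain)
        assert influence(example_pbn, "N1", "N3", pi, chain) == \
            pytest.approx(1.0)

    def test_non_parent_has_zero_influence(self, example_pbn):
        chain = transition_matrix(example_pbn, {}, p=0.01)
        pi = stationary_distribution(chain)
        assert influence(example_pbn, "N3", "N3", pi, chain) == 0.0
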