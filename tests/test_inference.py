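"""Problem assembly, decoding, the SSE objective and the optimisers."""

import math

import numpy as np
import pytest

from pbnfit import (ConvergenceSettings, ExperimentCondition, PBNInference,
                    assemble_problem, decode_continuous, decode_discrete,
                    optimize, resimulate, sse_cost)


class TestAssemble:
    def test_case1_is_5dim(self, bundle1):
        prob = assemble_problem(bundle1.pbn(), bundle1.experiments,
                                mode="discrete")
        assert prob.k == 5
        assert prob.free_index == tuple(("NFkB", j) for j in range(5))

    def test_case2_is_4dim_continuous(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments,
                                mode="continuous")
        assert prob.k == 4

    def test_empty_experiments_rejected(self, bundle1):
        with pytest.raises(ValueError, match="experiment"):
            assemble_problem(bundle1.pbn(), [], mode="discrete")

    def test_no_free_parameters_rejected(self, bundle2):
        fixed = bundle2.truth_pbn()
        with pytest.raises(ValueError, match="free"):
            assemble_problem(fixed, bundle2.experiments)

    def test_conflicting_clamped_measurement_rejected(self, bundle2):
        bad = ExperimentCondition("bad", {"PI3K": 1, "PTEN": 0},
                                  {"PI3K": 0.0, "PIP3": 1.0})
        with pytest.raises(ValueError, match="clamped"):
            assemble_problem(bundle2.pbn(), [bad])


class TestDecoding:
    @pytest.fixture
    def prob1(self, bundle1):
        return assemble_problem(bundle1.pbn(), bundle1.experiments,
                                mode="discrete")

    def test_single_selection_gets_full_mass(self, prob1):
        decoded, valid = decode_discrete([0, 1, 0, 0, 0], prob1)
        assert valid
        assert [decoded[("NFkB", j)] for j in range(5)] == [0, 1.0, 0, 0, 0]

    def test_equal_split_over_selected(self, prob1):
        decoded, valid = decode_discrete([0, 1, 0, 1, 1], prob1)
        assert valid
        assert decoded[("NFkB", 1)] == pytest.approx(1 / 3)
        assert decoded[("NFkB", 0)] == 0.0

    def test_all_zero_candidate_invalid(self, prob1):
        _, valid = decode_discrete([0, 0, 0, 0, 0], prob1)
        assert not valid

    def test_continuous_normalisation(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments)
        decoded = decode_continuous([0.3, 0.1, 0.2, 0.0], prob)
        assert [decoded[("PIP3", j)] for j in range(4)] == \
            pytest.approx([0.5, 1 / 6, 1 / 3, 0.0])
        uniform = decode_continuous([1, 1, 1, 1], prob)
        assert all(v == pytest.approx(0.25) for v in uniform.values())

    def test_continuous_all_zero_falls_back_to_uniform(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments)
        with pytest.warns(UserWarning, match="all-zero"):
            decoded = decode_continuous([0, 0, 0, 0], prob,
                                        warn_all_zero=True)
        assert all(v == pytest.approx(0.25) for v in decoded.values())


class TestCost:
    def test_truth_parameters_have_zero_cost(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments,
                                backend="exact")
        assert sse_cost(bundle2.truth, prob) == pytest.approx(0.0, abs=1e-18)

    def test_cost_bounds(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments)
        rng = np.random.default_rng(0)
        for _ in range(10):
            c = decode_continuous(rng.random(4), prob)
            cost = sse_cost(c, prob)
            assert 0.0 <= cost <= sum(len(e.measurements)
                                      for e in prob.experiments)

    def test_simulation_backend_converges_to_exact(self, bundle2):
        """As the precision r tightens, the simulated cost approaches the
        exact-chain cost."""
        truth_c = bundle2.truth
        exact_prob = assemble_problem(bundle2.pbn(), bundle2.experiments,
                                      backend="exact")
        exact_cost = sse_cost(truth_c, exact_prob)
        gaps = []
        for r in (0.05, 0.025, 0.01):
            prob = assemble_problem(
                bundle2.pbn(), bundle2.experiments, backend="simulation",
                settings=ConvergenceSettings(r=r))
            gaps.append(abs(sse_cost(truth_c, prob, seed=3) - exact_cost))
        assert gaps[-1] <= 4 * (0.01 + 0.001) ** 2 * 4
        assert gaps[-1] <= gaps[0] + 1e-3


class TestOptimize:
    def test_discrete_exhaustive_equals_brute_force(self, bundle1):
        prob = assemble_problem(bundle1.pbn(), bundle1.experiments,
                                mode="discrete")
        samples = optimize(prob, seed=0)
        assert len(samples) == 2 ** 5
        # invalid all-zero candidate scored +inf, not raised
        assert any(math.isinf(smp.cost) for smp in samples)
        assert samples[0].cost == pytest.approx(0.0, abs=1e-18)

    def test_genetic_search_never_beats_exhaustive(self, bundle1):
        prob = assemble_problem(bundle1.pbn(), bundle1.experiments,
                                mode="discrete")
        best_exh = optimize(prob, seed=0)[0].cost
        best_ga = optimize(prob, seed=0, method="ga", budget=300)[0].cost
        assert best_ga >= best_exh - 1e-15
        assert best_ga == pytest.approx(0.0, abs=1e-12)

    def test_continuous_budget_is_spent_and_ranked(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments)
        samples = optimize(prob, seed=1, budget=600)
        assert len(samples) >= 600
        costs = [smp.cost for smp in samples]
        assert costs == sorted(costs)

    def test_reproducible_given_seed(self, bundle2):
        prob = assemble_problem(bundle2.pbn(), bundle2.experiments)
        s1 = optimize(prob, seed=7, budget=300)
        s2 = optimize(prob, seed=7, budget=300)
        assert s1[0].raw == s2[0].raw and s1[0].cost == s2[0].cost


class TestResimulate:
    def test_table_matches_cost(self, bundle2):
        model = PBNInference(bundle2.pbn(), bundle2.experiments)
        res = model.fit(budget=400, seed=2)
        table = res.resimulate()
        assert set(table.columns) == {"experiment", "node", "estimate",
                                      "measured", "squared_error"}
        # exact backend: the resimulated total reproduces the fitted cost
        assert table["squared_error"].sum() == pytest.approx(res.cost)

    def test_simulation_backend_seed_wobble_is_bounded(self, bundle2):
        r = 0.025
        model = PBNInference(bundle2.pbn(), bundle2.experiments,
                             backend="simulation",
                             settings=ConvergenceSettings(r=r))
        prob = model.problem
        sample_decoded = bundle2.truth
        t1 = resimulate(
            optimize(prob, seed=3, budget=8)[0], prob, seed=11)
        t2 = resimulate(
            optimize(prob, seed=3, budget=8)[0], prob, seed=12)
        diff = abs(t1["squared_error"].sum() - t2["squared_error"].sum())
        assert diff < 4 * r


class TestFacade:
    def test_summary_mentions_mode_and_cost(self, bundle2):
        res = PBNInference(bundle2.pbn(), bundle2.experiments).fit(
            budget=300, seed=0)
        text = res.summary(K=100)
        assert "continuous" in text and "best cost" in text
        assert res.params.index.size == 4

    def test_from_files_roundtrip(self, tmp_path, bundle2):
        model_file = tmp_path / "model.txt"
        model_file.write_text(bundle2.rules)
        import json
        exp_file = tmp_path / "exp.json"
        exp_file.write_text(json.dumps([
            {"name": e.name, "clamps": dict(e.clamps),
             "measurements": {k: float(v) for k, v in e.measurements.items()}}
            for e in bundle2.experiments]))
        model = PBNInference.from_files(model_file, exp_file)
        assert model.problem.k == 4
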