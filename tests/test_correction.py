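"""Local and global cycle removal, admissible coefficients, overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxloops as fl
from fluxloops.correction import LinearConstraints


def toy_loop():
    return fl.Loop(k=np.array([1, 1, 0, 0]), n=np.array([1, 1, 0, 0]))


class TestCorrectLocal:
    def test_toy_worked_example_zeroes_the_smaller_flux(self, toy):
        net, v = toy
        result = fl.correct_local(net, v, toy_loop())
        assert result.corrected
        assert result.coefficient == -1.0
        assert result.v_after.values.tolist() == [2.0, 0.0, 2.0, 2.0]

    def test_positive_epsilon_bound_makes_loop_uncorrectable(self):
        net, v = fl.toy_network(0.5)
        result = fl.correct_local(net, v, toy_loop())
        assert not result.corrected
        assert result.v_after is v
        assert any("R2" in label for label in result.violated)

    def test_multiplicity_two_scales_the_coefficient(self):
        # loop with k = (2, 1): the k=2 reaction at flux 4 sets L = -2
        S = np.array([[-1.0, 2.0, 1.0, 0.0], [1.0, -2.0, 0.0, -1.0]])
        net = fl.MetabolicNetwork(S, ["a", "b", "ex1", "ex2"], ["A", "B"],
                                  [-100] * 4, [100] * 4)
        v = fl.FluxVector(np.array([4.0, 5.0, 6.0, -6.0]))
        loop = fl.Loop(k=np.array([2, 1, 0, 0]), n=np.array([2, 1, 0, 0]))
        result = fl.correct_local(net, v, loop)
        assert result.coefficient == -2.0
        assert result.v_after.values[:2].tolist() == [0.0, 3.0]

    def test_mass_balance_and_signs_preserved(self, toy):
        net, v = toy
        v_after = fl.correct_local(net, v, toy_loop()).v_after
        assert np.allclose(net.stoichiometry @ v_after.values, 0.0)
        assert (np.sign(v_after.values) * np.sign(v.values) >= 0).all()

    def test_bogus_loop_is_rejected(self, toy):
        net, v = toy
        bad = fl.Loop(k=np.array([1, 0, 0, 0]), n=np.array([1, 0, 0, 0]))
        with pytest.raises(ValueError, match="null space"):
            fl.correct_local(net, v, bad)


class TestAdmissibleInterval:
    def test_unconstrained_interval_is_minus_three_to_minus_one(self, toy):
        net, v = toy
        ivs = fl.admissible_L_interval(net, v, toy_loop(), constraints=None)
        assert len(ivs) == 1
        assert (ivs[0].lo, ivs[0].hi) == (-3.0, -1.0)

    def test_irreversibility_pins_the_coefficient(self, toy):
        net, v = toy  # epsilon = 0
        cons = LinearConstraints.from_network(net)
        ivs = fl.admissible_L_interval(net, v, toy_loop(), constraints=cons)
        assert len(ivs) == 1
        assert ivs[0].lo == ivs[0].hi == -1.0

    @pytest.mark.parametrize("epsilon,expected_lo", [(-0.5, -1.5), (-2.0, -3.0)])
    def test_negative_epsilon_leaves_an_interval(self, epsilon, expected_lo):
        # C1 = {L >= epsilon - 1} intersected with C2 = [-3, -1]
        net, v = fl.toy_network(epsilon)
        cons = LinearConstraints.from_network(net)
        ivs = fl.admissible_L_interval(net, v, toy_loop(), constraints=cons)
        assert len(ivs) == 1
        assert (ivs[0].lo, ivs[0].hi) == (expected_lo, -1.0)

    def test_positive_epsilon_empties_the_intersection(self):
        net, v = fl.toy_network(0.5)
        cons = LinearConstraints.from_network(net)
        assert fl.admissible_L_interval(net, v, toy_loop(), cons) == []


class TestCorrectGlobal:
    def test_deep_bound_recovers_antisymmetric_minimizer(self):
        net, v = fl.toy_network(-2.0)
        v_new = fl.correct_global(net, v)
        assert np.allclose(v_new.values, [1.0, -1.0, 2.0, 2.0], atol=1e-6)

    @pytest.mark.parametrize("epsilon", [-1.0, -0.5, 0.0])
    def test_clamped_branch_is_feasible_with_flux_at_bound(self, epsilon):
        net, v = fl.toy_network(epsilon)
        v_new = fl.correct_global(net, v)
        assert v_new.values[1] == pytest.approx(epsilon, abs=1e-6)
        assert v_new.values[0] == pytest.approx(2.0 + epsilon, abs=1e-6)
        sub = fl.build_thermo_subnetwork(net, v_new)
        assert sub.is_trivially_feasible or \
            fl.check_feasibility(sub, seed=0).converged

    def test_positive_epsilon_minimizer_keeps_the_loop(self):
        net, v = fl.toy_network(0.5)
        v_new = fl.correct_global(net, v)
        sub = fl.build_thermo_subnetwork(net, v_new)
        assert not fl.check_feasibility(sub, seed=0).converged
        assert fl.brute_force_loops(sub, k_max=2)

    def test_exchanges_stay_pinned(self, toy):
        net, v = toy
        v_new = fl.correct_global(net, v)
        assert np.allclose(v_new.values[2:], [2.0, 2.0], atol=1e-9)

    def test_q1_minimizers_are_loop_free_with_irreversibility_only(self):
        """On random loopy networks with only sign constraints the taxicab
        minimizer contains no cycles (enumeration-verified)."""
        rng = np.random.default_rng(31)
        checked = 0
        for trial in range(10):
            net, _ = fl.generate_random_loopy_network(
                8, 11, 1, seed=int(rng.integers(2**31)), cycle_length=(3, 4))
            v = _loopy_solution(net)
            if v is None:
                continue
            v_new = fl.correct_global(net, v, fix_objective=False)
            sub = fl.build_thermo_subnetwork(net, v_new)
            if not sub.is_trivially_feasible:
                assert fl.brute_force_loops(sub, k_max=2) == []
            checked += 1
        assert checked >= 5

    def test_p_above_one_is_unsupported(self, toy):
        net, v = toy
        with pytest.raises(NotImplementedError):
            fl.correct_global(net, v, p=2)


def _loopy_solution(net):
    """A mass-balanced flux vector carrying the planted cycle, if the
    network admits one with all cycle fluxes active."""
    from scipy.optimize import linprog

    rng = np.random.default_rng(0)
    c = rng.normal(size=net.n_reactions) * 0.01
    cycle = [i for i, rid in enumerate(net.reaction_ids)
             if rid.startswith("C0_")]
    bounds = []
    for r in range(net.n_reactions):
        lb, ub = net.lower_bounds[r], net.upper_bounds[r]
        if r in cycle:
            lb = 1.0  # force the planted cycle to run forward
        bounds.append((lb, ub))
    res = linprog(c=c, A_eq=net.stoichiometry,
                  b_eq=np.zeros(net.n_metabolites), bounds=bounds,
                  method="highs")
    return fl.FluxVector(res.x) if res.status == 0 else None


class TestOverlap:
    def test_reference_values(self):
        a = fl.FluxVector(np.array([3.0, 1.0, 2.0, 2.0]))
        assert fl.overlap(a, a) == 1.0
        assert fl.overlap(a, fl.FluxVector(-a.values)) == -1.0
        assert fl.overlap(fl.FluxVector([1.0, 1.0]),
                          fl.FluxVector([1.0, -1.0])) == 0.0

    def test_doubly_null_reactions_score_one(self):
        a = fl.FluxVector(np.array([0.0, 2.0]))
        b = fl.FluxVector(np.array([0.0, 2.0]))
        assert fl.overlap(a, b) == 1.0
        # a flux null on one side only contributes (almost) zero
        c = fl.FluxVector(np.array([5.0, 2.0]))
        assert fl.overlap(a, c) == pytest.approx(0.5, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fl.overlap(fl.FluxVector([1.0]), fl.FluxVector([1.0, 2.0]))

    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=1, max_size=8),
           st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=1, max_size=8),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_bounds_and_rescaling(self, xs, ys, scale):
        size = min(len(xs), len(ys))
        a = fl.FluxVector(np.array(xs[:size]))
        b = fl.FluxVector(np.array(ys[:size]))
        q = fl.overlap(a, b)
        assert -1.0 <= q <= 1.0 + 1e-12
        assert q == fl.overlap(b, a)
        # joint positive rescaling of one reaction's flux pair is neutral
        a2, b2 = a.values.copy(), b.values.copy()
        a2[0] *= scale
        b2[0] *= scale
        if (abs(a2[0]) >= a.zero_threshold) == (abs(a.values[0]) >= a.zero_threshold) \
                and (abs(b2[0]) >= b.zero_threshold) == (abs(b.values[0]) >= b.zero_threshold):
            q2 = fl.overlap(fl.FluxVector(a2), fl.FluxVector(b2))
            assert q2 == pytest.approx(q, abs=1e-9)


class TestCorrectAll:
    def test_local_strategy_on_the_toy(self, toy, fast_schedule):
        net, v = toy
        report = fl.correct_all(net, v, strategy="local",
                                schedule=fast_schedule, seed=4)
        assert report.status == "corrected"
        assert len(report.removed_loops) == 1
        assert report.v_after.values.tolist() == [2.0, 0.0, 2.0, 2.0]
        assert report.active_counts_after[0] < report.active_counts_before[0]

    def test_feasible_input_is_a_fixed_point(self, toy, fast_schedule):
        net, v = toy
        v_ok = v.copy_with([3.0, -1.0, 2.0, 2.0])
        report = fl.correct_all(net, v_ok, strategy="local",
                                schedule=fast_schedule, seed=4)
        assert report.status == "feasible"
        assert np.array_equal(report.v_after.values, v_ok.values)
        assert report.removed_loops == []
        assert report.overlap_before_after == 1.0

    def test_maintenance_style_bound_reports_uncorrectable(self, fast_schedule):
        # a strictly positive lower bound inside the cycle (like an ATP
        # maintenance flux) blocks the local rule
        net, v = fl.toy_network(0.5)
        report = fl.correct_all(net, v, strategy="local",
                                schedule=fast_schedule, seed=4)
        assert report.status == "uncorrectable loops remain"
        loop, violated = report.uncorrectable_loops[0]
        assert loop.k.tolist() == [1, 1, 0, 0]
        assert any("R2" in label for label in violated)

    def test_global_strategy_on_the_toy(self, toy, fast_schedule):
        net, v = toy
        report = fl.correct_all(net, v, strategy="global",
                                schedule=fast_schedule, seed=4)
        assert report.status == "corrected"
        assert report.feasible

    def test_constraints_hold_on_output(self, toy, fast_schedule):
        net, v = toy
        for strategy in ("local", "global"):
            report = fl.correct_all(net, v, strategy=strategy,
                                    schedule=fast_schedule, seed=4)
            assert np.allclose(net.stoichiometry @ report.v_after.values,
                               0.0, atol=1e-9)
            assert (report.v_after.values >= net.lower_bounds - 1e-9).all()
            assert (report.v_after.values <= net.upper_bounds + 1e-9).all()

    def test_objective_value_is_preserved(self, fast_schedule):
        net, v = fl.toy_network(0.0)
        net = fl.MetabolicNetwork(
            net.stoichiometry, net.reaction_ids, net.metabolite_ids,
            net.lower_bounds, net.upper_bounds,
            exchange_flags=net.exchange_flags,
            objective=np.array([0.0, 0.0, 0.0, 1.0]))
        report = fl.correct_all(net, v, strategy="local",
                                schedule=fast_schedule, seed=4)
        assert float(net.objective @ report.v_after.values) == \
            pytest.approx(float(net.objective @ v.values), rel=1e-8)

    def test_local_is_closer_to_input_than_global_on_most_fixtures(
            self, fast_schedule):
        """Statistical check: the local strategy usually yields a larger
        overlap with the uncorrected configuration than the global one."""
        wins = ties = losses = 0
        for seed in range(6):
            net, _ = fl.generate_random_loopy_network(
                9, 12, 1, seed=100 + seed, cycle_length=(3, 4))
            v = _loopy_solution(net)
            if v is None:
                continue
            local = fl.correct_all(net, v, strategy="local",
                                   schedule=fast_schedule, seed=seed)
            glob = fl.correct_all(net, v, strategy="global",
                                  schedule=fast_schedule, seed=seed)
            q_l = fl.overlap(v, local.v_after)
            q_g = fl.overlap(v, glob.v_after)
            if q_l > q_g + 1e-9:
                wins += 1
            elif q_g > q_l + 1e-9:
                losses += 1
            else:
                ties += 1
        assert wins + ties >= losses

    def test_report_serializes_to_json(self, toy, fast_schedule):
        import json

        net, v = toy
        report = fl.correct_all(net, v, strategy="local",
                                schedule=fast_schedule, seed=4)
        payload = json.loads(report.to_json(net.reaction_ids))
        assert payload["status"] == "corrected"
        assert payload["removed_loops"][0]["reactions"] == ["R1", "R2"]


class TestDeltaGSign:
    def test_certificate_sign_matches_flux_direction(self, toy, fast_schedule):
        net, v = toy
        report = fl.correct_all(net, v, strategy="local",
                                schedule=fast_schedule, seed=4)
        # after correction only R1 is active, running forward; a feasible
        # certificate must assign it a negative Gibbs energy change
        assert fl.delta_g_sign(net, report.v_after, "R1", seed=1) == -1

    def test_inactive_reaction_is_rejected(self, toy, fast_schedule):
        net, v = toy
        report = fl.correct_all(net, v, strategy="local",
                                schedule=fast_schedule, seed=4)
        with pytest.raises(ValueError, match="R2"):
            fl.delta_g_sign(net, report.v_after, "R2", seed=1)
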