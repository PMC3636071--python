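import math

import numpy as np
import pytest

from conftest import random_coding, random_dated_tree, random_params
from oracles import brute_force_log_likelihood, uniformization_expm
from stratdec import dec_core
from stratdec.dec_core import (
    DECParams,
    StateSpace,
    branch_transition,
    build_generator,
    enumerate_splits,
    fit_parameters,
    node_split_likelihoods,
    range_marginals,
    tree_log_likelihood,
)
from stratdec.geography import (
    CodingTable,
    DispersalMultiplierMatrix,
    EpochModel,
    RangeState,
)


class TestGenerator:
    def test_zero_rates_zero_matrix(self, two_area_space):
        q = build_generator(
            DECParams(0, 0), DispersalMultiplierMatrix.ones(2), two_area_space
        )
        assert np.all(q == 0)

    def test_hand_computed_rates(self, two_area_space):
        q = build_generator(
            DECParams(0.1, 0.05), DispersalMultiplierMatrix.ones(2), two_area_space
        )
        idx = two_area_space.index
        assert q[idx[0b01], idx[0b11]] == pytest.approx(0.1)  # {A} -> {A,B}
        assert q[idx[0b11], idx[0b01]] == pytest.approx(0.05)  # {A,B} -> {A}
        assert q[idx[0b01], idx[0b00]] == pytest.approx(0.05)  # {A} -> null

    def test_multiplier_scales_dispersal(self, two_area_space):
        m = np.ones((2, 2))
        m[0, 1] = 0.1
        q = build_generator(
            DECParams(0.1, 0.05), DispersalMultiplierMatrix(m), two_area_space
        )
        idx = two_area_space.index
        assert q[idx[0b01], idx[0b11]] == pytest.approx(0.01)

    def test_rows_sum_to_zero_null_absorbing(self):
        space = StateSpace(4)
        rng = np.random.default_rng(1)
        m = DispersalMultiplierMatrix(rng.uniform(0, 1, size=(4, 4)))
        q = build_generator(DECParams(0.2, 0.07), m, space)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        assert np.all(q[space.null_index] == 0)
        off = q[~np.eye(len(q), dtype=bool)]
        assert off.min() >= 0


class TestBranchTransition:
    def test_zero_duration_is_identity(self, two_area_space, flat_epochs_2):
        p = branch_transition(
            DECParams(0.1, 0.05), flat_epochs_2, 50.0, 50.0, two_area_space
        )
        assert np.allclose(p, np.eye(two_area_space.n_states))

    def test_equal_multipliers_collapse_to_single_exponential(self, two_area_space):
        strat = EpochModel.uniform([105, 80, 50, 30, 0], 2)
        flat = EpochModel.uniform([105, 0], 2)
        params = DECParams(0.13, 0.04)
        p1 = branch_transition(params, strat, 95.0, 10.0, two_area_space)
        p2 = branch_transition(params, flat, 95.0, 10.0, two_area_space)
        assert np.abs(p1 - p2).max() < 1e-10

    def test_matches_uniformization_series(self, two_area_space, flat_epochs_2):
        params = DECParams(0.1, 0.05)
        p = branch_transition(params, flat_epochs_2, 1.0, 0.0, two_area_space)
        q = build_generator(
            params, DispersalMultiplierMatrix.ones(2), two_area_space
        )
        assert np.abs(p - uniformization_expm(q, 1.0)).max() < 1e-8

    def test_rows_stochastic(self):
        space = StateSpace(3)
        epochs = EpochModel.uniform([105, 80, 50, 30, 0], 3)
        p = branch_transition(DECParams(0.3, 0.1), epochs, 100.0, 3.0, space)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-10
        assert p.min() >= -1e-15 and p.max() <= 1 + 1e-12


class TestEnumerateSplits:
    def test_singleton_identity_split(self):
        r = RangeState(0b001, 3)
        assert enumerate_splits(r) == [(r, r)]

    def test_two_area_range_has_six_splits(self):
        r = RangeState(0b11, 2)
        splits = {(l.bits, rr.bits) for l, rr in enumerate_splits(r)}
        assert splits == {(1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2)}

    def test_three_area_range_has_twelve_splits(self):
        assert len(enumerate_splits(RangeState(0b111, 3))) == 12

    def test_no_duplicates_and_split_validity(self):
        for bits in range(1, 16):
            r = RangeState(bits, 4)
            splits = enumerate_splits(r)
            assert len(splits) == len(set((l.bits, rr.bits) for l, rr in splits))
            for l, rr in splits:
                assert l.bits | rr.bits == r.bits
                overlap = l.bits & rr.bits
                assert overlap == 0 or l.bits == r.bits or rr.bits == r.bits
                if r.size > 1:
                    assert min(l.size, rr.size) == 1

    def test_null_rejected(self):
        with pytest.raises(Exception):
            enumerate_splits(RangeState(0, 2))


class TestTreeLikelihood:
    def test_no_events_flat_root_prior(self, cherry_tree, cherry_coding, flat_epochs_2):
        ll = tree_log_likelihood(
            cherry_tree, cherry_coding, DECParams(0, 0), flat_epochs_2
        )
        assert ll == pytest.approx(math.log(1 / 3))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        for n_tips in (3, 4):
            for k in (2, 3):
                tree = random_dated_tree(rng, n_tips, 10.0)
                space = StateSpace(k)
                coding = random_coding(rng, tree, k)
                epochs = EpochModel.uniform([10, 6, 3, 0], k)
                params = random_params(rng)
                ll = tree_log_likelihood(tree, coding, params, epochs, space)
                bf = brute_force_log_likelihood(
                    tree, coding, params, epochs, space
                )
                assert ll == pytest.approx(bf, rel=1e-10)

    def test_invariant_under_area_relabeling(self):
        rng = np.random.default_rng(8)
        tree = random_dated_tree(rng, 6, 50.0)
        k = 3
        perm = [2, 0, 1]
        m = rng.uniform(0.1, 1.0, size=(k, k))
        np.fill_diagonal(m, 1.0)
        epochs = EpochModel.single(DispersalMultiplierMatrix(m), 50.0)
        # tip bits move area a -> perm.index(a), so entry (i, j) of the
        # permuted matrix must come from (perm[i], perm[j])
        mp = m[np.ix_(perm, perm)]
        epochs_p = EpochModel.single(DispersalMultiplierMatrix(mp), 50.0)
        coding = random_coding(rng, tree, k)

        def permute_bits(bits):
            return sum(1 << perm.index(a) for a in range(k) if bits >> a & 1)

        coding_p = CodingTable(
            "x",
            {
                lbl: RangeState(permute_bits(r.bits), k)
                for lbl, r in coding.assignments.items()
            },
        )
        params = DECParams(0.1, 0.03)
        ll = tree_log_likelihood(tree, coding, params, epochs)
        # permuted coding with consistently permuted multipliers
        ll_p = tree_log_likelihood(tree, coding_p, params, epochs_p)
        assert ll == pytest.approx(ll_p, rel=1e-12)

    def test_monotone_in_d_for_single_shared_area(self, flat_epochs_2):
        rng = np.random.default_rng(4)
        tree = random_dated_tree(rng, 8, 60.0)
        coding = CodingTable(
            "x", {t.label: RangeState(1, 2) for t in tree.tips()}
        )
        epochs = EpochModel.uniform([60, 0], 2)
        lls = [
            tree_log_likelihood(tree, coding, DECParams(d, 0.0), epochs)
            for d in [0.0, 0.01, 0.05, 0.1, 0.5]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(lls, lls[1:]))


class TestNodeScenarios:
    def setup_case(self, seed=3, n_tips=3, k=2):
        rng = np.random.default_rng(seed)
        tree = random_dated_tree(rng, n_tips, 20.0)
        space = StateSpace(k)
        coding = random_coding(rng, tree, k)
        epochs = EpochModel.uniform([20, 12, 0], k)
        params = random_params(rng)
        return tree, space, coding, epochs, params

    def test_scenarios_sum_to_total_likelihood(self):
        tree, space, coding, epochs, params = self.setup_case(seed=21, n_tips=6)
        total = tree_log_likelihood(tree, coding, params, epochs, space)
        for node in tree.internal_nodes():
            scens = node_split_likelihoods(
                tree, coding, params, epochs, node, space
            )
            fin = [s.log_likelihood for s in scens if math.isfinite(s.log_likelihood)]
            m = max(fin)
            agg = m + math.log(sum(math.exp(x - m) for x in fin))
            assert agg == pytest.approx(total, abs=1e-8)

    def test_each_scenario_matches_restricted_enumeration(self):
        tree, space, coding, epochs, params = self.setup_case()
        node = tree.internal_nodes()[0]
        scens = node_split_likelihoods(tree, coding, params, epochs, node, space)
        for s in scens[:40]:
            bf = brute_force_log_likelihood(
                tree,
                coding,
                params,
                epochs,
                space,
                restrict_node=node,
                restrict_scenario=(
                    space.index[s.ancestral.bits],
                    space.index[s.left.bits],
                    space.index[s.right.bits],
                ),
            )
            if math.isfinite(s.log_likelihood):
                assert s.log_likelihood == pytest.approx(bf, rel=1e-10)
            else:
                assert bf == -math.inf

    def test_static_history_when_no_events_possible(self, flat_epochs_2):
        rng = np.random.default_rng(5)
        tree = random_dated_tree(rng, 5, 40.0)
        coding = CodingTable("x", {t.label: RangeState(1, 2) for t in tree.tips()})
        epochs = EpochModel.uniform([40, 0], 2)
        for node in tree.internal_nodes():
            scens = node_split_likelihoods(
                tree, coding, DECParams(0, 0), epochs, node
            )
            alive = [s for s in scens if math.isfinite(s.log_likelihood)]
            assert len(alive) == 1
            s = alive[0]
            assert (s.ancestral.bits, s.left.bits, s.right.bits) == (1, 1, 1)

    def test_tip_rejected(self, cherry_tree, cherry_coding, flat_epochs_2):
        with pytest.raises(Exception):
            node_split_likelihoods(
                cherry_tree,
                cherry_coding,
                DECParams(0.1, 0.1),
                flat_epochs_2,
                cherry_tree.tips()[0],
            )


class TestRangeMarginals:
    def _scenario(self, anc_bits, ll, k=2):
        r = RangeState(anc_bits, k)
        return dec_core.SplitScenario(r, r, r, ll)

    def test_sums_by_ancestral_range(self):
        scens = [
            self._scenario(1, math.log(0.2)),
            self._scenario(1, math.log(0.3)),
            self._scenario(3, math.log(0.5)),
        ]
        marg = range_marginals(scens)
        assert math.exp(marg[RangeState(1, 2)]) == pytest.approx(0.5)
        assert math.exp(marg[RangeState(3, 2)]) == pytest.approx(0.5)

    def test_total_conserved(self):
        rng = np.random.default_rng(6)
        scens = [
            self._scenario(int(rng.integers(1, 4)), float(rng.normal(-30, 2)))
            for _ in range(30)
        ]
        marg = range_marginals(scens)
        t1 = sum(math.exp(s.log_likelihood + 30) for s in scens)
        t2 = sum(math.exp(v + 30) for v in marg.values())
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_single_scenario_identity(self):
        s = self._scenario(1, -5.0)
        assert range_marginals([s]) == {RangeState(1, 2): pytest.approx(-5.0)}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            range_marginals([])


class TestFitParameters:
    def test_deterministic(self):
        rng = np.random.default_rng(10)
        tree = random_dated_tree(rng, 12, 80.0)
        coding = random_coding(rng, tree, 2)
        epochs = EpochModel.uniform([80, 0], 2)
        r1 = fit_parameters(tree, coding, epochs)
        r2 = fit_parameters(tree, coding, epochs)
        assert (r1.params, r1.log_likelihood) == (r2.params, r2.log_likelihood)

    def test_identical_tips_push_extinction_to_lower_bound(self):
        rng = np.random.default_rng(12)
        tree = random_dated_tree(rng, 10, 60.0)
        coding = CodingTable("x", {t.label: RangeState(1, 2) for t in tree.tips()})
        epochs = EpochModel.uniform([60, 0], 2)
        res = fit_parameters(tree, coding, epochs)
        assert res.params.e < 1e-4
        # the optimum must dominate every multi-start endpoint
        assert all(res.log_likelihood >= ll - 1e-9 for _, ll in res.starts)
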