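"""Fused single-pass likelihood: prelike, clp, rescaling and root combination."""

import numpy as np
import pytest

from phylofuse.io_formats import (Alignment, CompressedAlignment,
                                  compress_alignment, read_newick)
from phylofuse.likelihood_fused import (FusedEvaluator, brute_force_loglikelihood,
                                        evaluate, prelike,
                                        pruning_reference_loglikelihood)
from phylofuse.simulate import SimSpec, random_tree, simulate_alignment
from phylofuse.subst_model import (GTRParams, build_rate_matrix,
                                   discrete_gamma_rates, jc_params,
                                   transition_block)
from phylofuse.tree import reroot_on_edge


def _block(params, t=0.3):
    rm = build_rate_matrix(params)
    return transition_block(rm, t, discrete_gamma_rates(params.alpha, params.n_cat))


class TestPrelike:
    def test_single_bit_mask_reproduces_tip_column(self, rng):
        block = _block(jc_params(alpha=0.8))
        table = prelike(block, [1, 2, 4, 8])
        for bit, state in zip((1, 2, 4, 8), range(4)):
            np.testing.assert_array_equal(table[bit], block[:, :, state])

    def test_full_ambiguity_gives_ones(self):
        block = _block(jc_params())
        table = prelike(block, [15])
        np.testing.assert_allclose(table[15], 1.0, atol=1e-12)

    def test_purine_mask_is_brute_force_sum(self, rng):
        from phylofuse.subst_model import GTRParams
        params = GTRParams(tuple(rng.dirichlet(np.ones(6))),
                           (0.3, 0.2, 0.25, 0.25), alpha=0.6)
        block = _block(params)
        table = prelike(block, [5])  # R = A|G
        np.testing.assert_allclose(table[5], block[:, :, 0] + block[:, :, 2],
                                   atol=1e-14)

    def test_mask_zero_rejected(self):
        with pytest.raises(ValueError):
            prelike(_block(jc_params()), [0])


def _pure_pattern_data(rows, labels=None):
    n_taxa = len(rows)
    patterns = np.array(rows, dtype=np.uint8)
    L = patterns.shape[1]
    if labels is None:
        labels = list("abcdefghijklmnop"[:n_taxa])
    return CompressedAlignment(labels, patterns,
                               np.ones(L, dtype=np.int64), np.arange(L))


class TestClpDown:
    def test_zero_length_cherry_is_indicator(self):
        # two terminal children observed 'A' on zero-length branches:
        # the cherry's clp is 1 at state A and 0 elsewhere
        tree = read_newick("((a:0.0,b:0.0):0.1,c:0.1);")
        data = _pure_pattern_data([[1], [1], [1]])
        params = jc_params(alpha=1.0)
        ev = FusedEvaluator(tree, data, params, scaler_policy="none")
        ev.evaluate()
        cherry = next(n for n in tree.down_nodes())
        clp = ev._clp[cherry]
        np.testing.assert_allclose(clp[0, :, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(clp[0, :, 1:], 0.0, atol=1e-12)

    def test_fully_ambiguous_child_contributes_factor_one(self):
        # a cherry whose second child is all-'N' has the clp of one-child
        # pruning: the ambiguous child's factor is 1 everywhere
        tree = read_newick("((a:0.2,b:0.3):0.1,c:0.15);")
        params = jc_params(alpha=0.7)
        data = _pure_pattern_data([[1], [15], [2]])
        ev = FusedEvaluator(tree, data, params, scaler_policy="none")
        ev.evaluate()
        cherry = next(n for n in tree.down_nodes())
        one_child = prelike(_block(params, 0.2), [1])[1]
        np.testing.assert_allclose(ev._clp[cherry][0], one_child, atol=1e-12)

    def test_site_likelihoods_match_exhaustive_enumeration(self, rng, random_fixture):
        for _ in range(8):
            tree, data, params = random_fixture(rng, 5, 3, with_ambiguity=True)
            got = evaluate(tree, data, params)
            want = brute_force_loglikelihood(tree, data, params)
            assert got == pytest.approx(want, rel=1e-10)


class TestFusedRescale:
    def test_uniform_clp_scales_to_one(self):
        # all 16 values equal c: scaler = c, clp becomes 1, lnScaler gains ln c
        tree = read_newick("((a:0.0,b:0.0):0.1,c:0.1);")
        data = _pure_pattern_data([[15], [15], [15]])
        params = jc_params(alpha=1.0)
        ev = FusedEvaluator(tree, data, params, scaler_policy="all")
        ev.evaluate()
        cherry = next(n for n in tree.down_nodes())
        np.testing.assert_allclose(ev._clp[cherry], 1.0, atol=1e-12)
        np.testing.assert_allclose(ev._node_scaler[cherry], 1.0, atol=1e-12)

    def test_scaling_on_vs_off_identical_loglik(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 6, 10)
        on = evaluate(tree, data, params, scaler_policy="all")
        off = evaluate(tree, data, params, scaler_policy="none")
        every2 = evaluate(tree, data, params, scaler_policy=2)
        assert on == pytest.approx(off, rel=1e-10)
        assert every2 == pytest.approx(off, rel=1e-10)

    def test_shortcut_zero_leaves_scaler_state_untouched(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 5, 4)
        ev = FusedEvaluator(tree, data, params, scaler_policy="none")
        ev.evaluate()
        assert not ev._node_scaler
        assert np.all(ev._ln_scaler == 0.0)
        assert not any(n.scalers_set for n in tree.internal_nodes())

    def test_deferred_vs_immediate_switches(self, rng, random_fixture):
        # identical lnL now and identical behaviour on the next (warm) pass
        tree, data, params = random_fixture(rng, 6, 8)
        results = {}
        for mode in ("deferred", "immediate"):
            t2, _ = tree.copy()
            ev = FusedEvaluator(t2, data, params, switch_mode=mode)
            cold = ev.evaluate()
            warm = ev.propose_update(dirty_nodes=None, dirty_branches=None)
            ev.accept()
            results[mode] = (cold, warm)
        assert results["deferred"][0] == pytest.approx(results["immediate"][0],
                                                       rel=1e-12)
        assert results["deferred"][1] == pytest.approx(results["immediate"][1],
                                                       rel=1e-12)

    def test_warm_reevaluation_reproduces_cold_value(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 10, 25)
        ev = FusedEvaluator(tree, data, params)
        cold = ev.evaluate()
        for _ in range(3):
            warm = ev.propose_update(dirty_nodes=None, dirty_branches=None)
            ev.accept()
            assert warm == pytest.approx(cold, rel=1e-10)


class TestRootLikelihood:
    def test_pinvar_zero_is_pure_gamma_mixture(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 5, 6)
        params0 = params.replace(pinvar=0.0)
        got = evaluate(tree, data, params0)
        want = pruning_reference_loglikelihood(tree, data, params0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_all_invariable_constant_pattern(self):
        # pinvar -> 1 with a single constant all-'A' pattern: lnL -> w ln(pi_A)
        tree = read_newick("((a:0.2,b:0.1):0.1,c:0.3);")
        patterns = np.array([[1], [1], [1]], dtype=np.uint8)
        data = CompressedAlignment(["a", "b", "c"], patterns,
                                   np.array([7]), np.zeros(7, dtype=int))
        params = GTRParams((1.0,) * 6, (0.4, 0.2, 0.2, 0.2),
                           pinvar=1.0 - 1e-12, alpha=1.0)
        lnl = evaluate(tree, data, params)
        assert lnl == pytest.approx(7 * np.log(0.4), rel=1e-6)

    def test_impossible_data_reports_zero_likelihood(self):
        # conflicting states across zero-length branches leave no state
        # assignment with positive probability: likelihood 0, warned lnL=-inf
        tree = read_newick("((a:0.0,b:0.0):0.1,c:0.3);")
        data = _pure_pattern_data([[1], [2], [4]])
        params = GTRParams((1.0,) * 6, (0.25,) * 4, pinvar=0.0, alpha=1.0)
        with pytest.warns(RuntimeWarning, match="zero likelihood"):
            lnl = evaluate(tree, data, params, scaler_policy="none")
        assert lnl == -np.inf

    def test_mixture_matches_scaler_free_reference(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 4, 5)
        params = params.replace(pinvar=0.3)
        got = evaluate(tree, data, params)
        want = pruning_reference_loglikelihood(tree, data, params)
        assert got == pytest.approx(want, rel=1e-10)


class TestEvaluate:
    def test_cross_layout_equality(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 10, 60)
        a = evaluate(tree, data, params, layout="state_major")
        b = evaluate(tree, data, params, layout="site_major")
        assert a == pytest.approx(b, rel=1e-12)

    def test_auto_layout_threshold(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 5, 10)
        ev = FusedEvaluator(tree, data, params, layout="auto", site_threshold=512)
        assert ev._effective_layout() == "state_major"
        ev2 = FusedEvaluator(tree, data, params, layout="auto", site_threshold=5)
        assert ev2._effective_layout() == "site_major"

    def test_duplicating_columns_doubles_loglik(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 6, 12)
        doubled = CompressedAlignment(data.taxon_labels, data.patterns,
                                      data.weights * 2, data.column_pattern)
        assert evaluate(tree, doubled, params) == \
            pytest.approx(2 * evaluate(tree, data, params), rel=1e-12)

    def test_rerooting_invariance(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 8, 15)
        base = evaluate(tree, data, params)
        for edge in tree.edges()[:5]:
            rerooted = reroot_on_edge(tree, edge, fraction=0.3)
            assert evaluate(rerooted, data, params) == \
                pytest.approx(base, rel=1e-10)

    def test_compression_preserves_likelihood(self, rng):
        spec = SimSpec(n_taxa=6, n_columns=120, seed=5)
        ali, _ = simulate_alignment(spec)
        data = compress_alignment(ali)
        # uncompressed: one pattern per column, weight one each
        from phylofuse.io_formats import encode_states
        enc = encode_states(ali)
        flat = CompressedAlignment(ali.taxon_labels, enc,
                                   np.ones(enc.shape[1], dtype=np.int64),
                                   np.arange(enc.shape[1]))
        tree = random_tree(6, rng)
        params = spec.params
        assert evaluate(tree, data, params) == \
            pytest.approx(evaluate(tree, flat, params), rel=1e-12)

    def test_taxon_mismatch_rejected(self, rng, random_fixture):
        tree, data, params = random_fixture(rng, 5, 4)
        other = random_tree(6, rng)
        with pytest.raises(ValueError, match="taxon"):
            FusedEvaluator(other, data, params)


class TestUnderflowRobustness:
    def test_scaled_finite_where_reference_underflows(self, rng):
        # large tree, long branches, single precision (the hardware width the
        # scaler machinery was built for): the linear-domain reference dies
        tree = random_tree(192, rng, branch_dist=("uniform", 0.5, 2.0))
        states = np.array([1, 2, 4, 8], dtype=np.uint8)
        patterns = rng.choice(states, size=(192, 10))
        data = CompressedAlignment(tree.taxon_labels, patterns,
                                   np.ones(10, dtype=np.int64), np.arange(10))
        params = jc_params(alpha=1.0)
        ref = pruning_reference_loglikelihood(tree, data, params,
                                              dtype=np.float32)
        assert ref == -np.inf
        ev = FusedEvaluator(tree, data, params, dtype=np.float32)
        scaled = ev.evaluate()
        assert np.isfinite(scaled)
        # and the double-precision value agrees with the scaled float32 one
        exact = evaluate(tree, data, params)
        assert scaled == pytest.approx(exact, rel=1e-3)


class TestIncrementalUpdates:
    def test_incremental_equals_fresh_after_random_proposals(self, rng, random_fixture):
        # random accepted/rejected branch-length changes: cached state must
        # track a from-scratch evaluation
        tree, data, params = random_fixture(rng, 9, 20)
        ev = FusedEvaluator(tree, data, params)
        ev.evaluate()
        edges = tree.edges()
        for step in range(60):
            node = edges[rng.integers(len(edges))]
            old = node.length
            node.length = float(old * np.exp(rng.normal(0, 0.3)))
            dirty = set()
            p = node.parent
            while p is not None:
                dirty.add(p)
                p = p.parent
            lnl = ev.propose_update(dirty, {node})
            if rng.random() < 0.5:
                ev.accept()
                fresh = FusedEvaluator(tree, data, params).evaluate()
                assert lnl == pytest.approx(fresh, rel=1e-9)
            else:
                ev.reject()
                node.length = old
        final = ev.propose_update(None, None)
        ev.accept()
        assert final == pytest.approx(FusedEvaluator(tree, data, params).evaluate(),
                                      rel=1e-9)
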