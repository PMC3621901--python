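"""Metropolis-coupled sampler: proposals, acceptance, swaps, diagnostics."""

import numpy as np
import pytest
from scipy.integrate import quad

from phylofuse.io_formats import CompressedAlignment, compress_alignment, read_newick
from phylofuse.likelihood_fused import FusedEvaluator
from phylofuse.mcmc import (Chain, RunConfig, asdsf, credible_interval,
                            log_prior, propose, run_mc3, split_frequencies,
                            swap_chains, write_run_files, MOVE_NAMES)
from phylofuse.simulate import SimSpec, preset, random_tree, simulate_alignment
from phylofuse.subst_model import GTRParams, jc_params


def _tiny_chain(rng, seed=0, n_taxa=6, n_pat=8, data=True):
    from phylofuse.cli import _random_fixture

    tree, dat, params = _random_fixture(rng, n_taxa, n_pat)
    cfg = RunConfig(n_generations=0, n_runs=1, n_chains=1)
    return Chain(tree, params, dat if data else None,
                 np.random.default_rng(seed), config=cfg)


def _state_signature(chain):
    return (chain.tree.newick(), chain.params)


class TestProposals:
    @pytest.mark.parametrize("move", MOVE_NAMES)
    def test_undo_restores_state_exactly(self, rng, move):
        chain = _tiny_chain(rng, data=False)
        for trial in range(25):
            before = _state_signature(chain)
            result = propose(chain, move)
            if result.aborted:
                if result.undo is not None:
                    result.undo()
            else:
                assert result.new_params is not None or \
                    _state_signature(chain) != before or \
                    result.ln_hastings == pytest.approx(0.0)
                if result.undo is not None:
                    result.undo()
            assert _state_signature(chain) == before

    def test_aborted_proposal_commits_nothing(self, rng):
        # force aborts by shrinking every branch to the floor ceiling range
        chain = _tiny_chain(rng, data=False)
        for node in chain.tree.postorder():
            if node.parent is not None:
                node.length = 95.0  # multiplier above ~1.05 exceeds BRLEN_MAX
        aborted = 0
        for _ in range(200):
            before = _state_signature(chain)
            result = propose(chain, "brlen_multiplier")
            if result.aborted:
                aborted += 1
                assert _state_signature(chain) == before
            elif result.undo:
                result.undo()
        assert aborted > 0

    def test_dirichlet_proposals_stay_on_simplex(self, rng):
        chain = _tiny_chain(rng, data=False)
        for _ in range(50):
            for move in ("exch_dirichlet", "freq_dirichlet"):
                result = propose(chain, move)
                if not result.aborted:
                    assert abs(sum(result.new_params.freqs) - 1.0) < 1e-12
                    exch = np.asarray(result.new_params.exch)
                    assert np.all(exch > 0)

    def test_pinvar_window_stays_in_unit_interval(self, rng):
        chain = _tiny_chain(rng, data=False)
        for _ in range(200):
            result = propose(chain, "pinvar_window")
            assert 0.0 <= result.new_params.pinvar < 1.0
            chain.params = result.new_params

    def test_unknown_move_kind(self, rng):
        with pytest.raises(ValueError, match="unknown move"):
            propose(_tiny_chain(rng, data=False), "teleport")

    def test_nni_changes_topology_and_undo_restores_it(self, rng):
        chain = _tiny_chain(rng, data=False, n_taxa=8)
        changed = 0
        for _ in range(30):
            before = chain.tree.splits()
            result = propose(chain, "nni")
            if not result.aborted:
                changed += int(chain.tree.splits() != before)
                # NNI Hastings carries only the branch multiplier: |ln c|
                # bounded by half the tuning constant
                assert abs(result.ln_hastings) <= 0.5 * 2.0 * np.log(1.6) + 1e-12
                result.undo()
                assert chain.tree.splits() == before
        assert changed > 0


class TestChainStepping:
    def test_chain_advances_and_caches_consistent_loglik(self, rng):
        chain = _tiny_chain(rng, n_taxa=7, n_pat=15)
        for _ in range(150):
            chain.step()
        fresh = FusedEvaluator(chain.tree, chain.evaluator.data,
                               chain.params).evaluate()
        assert chain.ln_like == pytest.approx(fresh, rel=1e-9)

    def test_prior_only_sampling_recovers_prior_moments(self):
        # flat Dirichlet freqs (mean 1/4), Exp(1) alpha (mean 1),
        # U(0,1) pinvar (mean 1/2), Exp(10) branches (mean 0.1)
        rng = np.random.default_rng(17)
        tree = random_tree(6, rng)
        cfg = RunConfig(n_generations=0, n_runs=1, n_chains=1, prior_only=True)
        chain = Chain(tree, GTRParams((1 / 6.0,) * 6, (0.25,) * 4,
                                      pinvar=0.3, alpha=1.0),
                      None, np.random.default_rng(3), config=cfg)
        draws = {"pi_A": [], "alpha": [], "pinvar": [], "mean_branch": []}
        for step in range(24000):
            chain.step()
            if step % 8 == 0:
                draws["pi_A"].append(chain.params.freqs[0])
                draws["alpha"].append(chain.params.alpha)
                draws["pinvar"].append(chain.params.pinvar)
                draws["mean_branch"].append(
                    chain.tree.total_length() / len(chain.tree.edges()))
        expected = {"pi_A": 0.25, "alpha": 1.0, "pinvar": 0.5,
                    "mean_branch": 0.1}
        for name, values in draws.items():
            values = np.asarray(values)
            batches = np.array_split(values, 12)
            means = [b.mean() for b in batches]
            mcse = np.std(means, ddof=1) / np.sqrt(len(means))
            assert abs(values.mean() - expected[name]) < 3 * mcse + 1e-9, \
                f"{name}: {values.mean():.4f} vs {expected[name]} (mcse {mcse:.4f})"

    def test_multiplier_move_matches_numeric_posterior_on_one_branch(self):
        # 2-taxon Jukes-Cantor: posterior of the path length T has a closed
        # 1-D form; numeric quadrature is the oracle for the MCMC mean
        k_diff, n_sites = 6, 40
        patterns = np.array([[1] * n_sites,
                             [1] * (n_sites - k_diff) + [2] * k_diff],
                            dtype=np.uint8)
        from phylofuse.io_formats import compress_patterns
        comp = compress_patterns(patterns, ["a", "b"])
        params = jc_params(alpha=1.0, n_cat=1)
        tree = read_newick("(a:0.05,b:0.05);")

        def lik(T):
            p_diff = 0.25 - 0.25 * np.exp(-4.0 * T / 3.0)
            p_same = 0.25 + 0.75 * np.exp(-4.0 * T / 3.0)
            return ((p_diff / 3.0) ** k_diff) * (p_same ** (n_sites - k_diff))

        # prior on T = t1 + t2 with t_i ~ Exp(10): Gamma(2, rate 10)
        post = lambda T: lik(T) * (100.0 * T * np.exp(-10.0 * T))
        Z = quad(post, 0, 5)[0]
        want_mean = quad(lambda T: T * post(T), 0, 5)[0] / Z

        cfg = RunConfig(n_generations=0, n_runs=1, n_chains=1,
                        move_weights={"brlen_multiplier": 1.0})
        chain = Chain(tree, params, comp, np.random.default_rng(8), config=cfg)
        totals = []
        for step in range(40000):
            chain.step()
            if step % 10 == 0:
                totals.append(chain.tree.total_length())
        totals = np.asarray(totals[100:])
        batches = np.array_split(totals, 12)
        mcse = np.std([b.mean() for b in batches], ddof=1) / np.sqrt(12)
        assert abs(totals.mean() - want_mean) < 3 * mcse + 0.002


class TestSwaps:
    def test_equal_posteriors_always_swap(self, rng):
        chains = [_tiny_chain(rng, seed=s, data=False) for s in (1, 2)]
        # identical states: copy one onto the other
        chains[1].tree, _ = chains[0].tree.copy()
        chains[1].params = chains[0].params
        chains[0].beta, chains[1].beta = 1.0, 0.8
        swap_rng = np.random.default_rng(4)
        for _ in range(30):
            _, _, ok = swap_chains(chains, swap_rng)
            assert ok

    def test_equal_heats_always_swap(self, rng):
        chains = [_tiny_chain(rng, seed=s, data=False) for s in (1, 2)]
        chains[0].beta = chains[1].beta = 0.9
        swap_rng = np.random.default_rng(4)
        for _ in range(30):
            assert swap_chains(chains, swap_rng)[2]

    def test_single_chain_never_swaps(self, rng):
        chain = _tiny_chain(rng, data=False)
        assert swap_chains([chain], np.random.default_rng(0))[2] is False


class TestRunMc3:
    def _small_data(self, seed=5):
        ali, truth = simulate_alignment(SimSpec(n_taxa=6, n_columns=120,
                                                seed=seed))
        return compress_alignment(ali), truth

    def test_zero_generations_initial_sample_only(self):
        data, _ = self._small_data()
        cfg = RunConfig(n_generations=0, n_runs=2, n_chains=2, seed=3)
        res = run_mc3(data, cfg)
        assert all(len(r.samples) == 1 and r.samples[0].gen == 0
                   for r in res.runs)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        data, _ = self._small_data()
        cfg = RunConfig(n_generations=60, n_runs=2, n_chains=2,
                        sample_freq=20, diag_freq=30, seed=11)
        files = []
        for tag in ("x", "y"):
            res = run_mc3(data, cfg)
            t, p = write_run_files(res.runs[0], str(tmp_path / f"{tag}"))
            files.append((open(t, "rb").read(), open(p, "rb").read()))
        assert files[0] == files[1]

    def test_heats_follow_heating_scheme(self):
        data, _ = self._small_data()
        cfg = RunConfig(n_generations=0, n_runs=1, n_chains=4,
                        heat_lambda=0.1, seed=1)
        from phylofuse.mcmc import _Run
        run = _Run(data, cfg, np.random.SeedSequence(0).spawn(1)[0], None,
                   data.taxon_labels)
        betas = sorted((c.beta for c in run.chains), reverse=True)
        assert betas == pytest.approx([1.0, 1 / 1.1, 1 / 1.2, 1 / 1.3])
        assert run.cold_chain().beta == 1.0


class TestSplitFrequencies:
    def test_identical_trees_frequency_one(self, rng):
        tree = random_tree(8, rng)
        freqs = split_frequencies([tree] * 10, burnin_frac=0.0)
        assert set(freqs.values()) == {1.0}
        assert len(freqs) == len(tree.splits())

    def test_two_topologies_sampled_equally(self):
        a = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = read_newick("((a:1,c:1):1,(b:1,d:1):1);")
        freqs = split_frequencies([a, b] * 5, burnin_frac=0.0)
        assert all(f == 0.5 for f in freqs.values())

    def test_hand_counted_toy_trees(self):
        newicks = (["((a:1,b:1):1,(c:1,d:1):1,e:1);"] * 6
                   + ["((a:1,c:1):1,(b:1,d:1):1,e:1);"] * 3
                   + ["((a:1,e:1):1,(b:1,d:1):1,c:1);"] * 1)
        trees = [read_newick(s) for s in newicks]
        freqs = split_frequencies(trees, burnin_frac=0.0)
        # {a,b} and {c,d} appear in 6 of 10 trees; {b,d} in 4; the rest in 3, 1
        by_value = sorted(freqs.values())
        assert by_value == pytest.approx([0.1, 0.3, 0.4, 0.6, 0.6])

    def test_burnin_removed(self):
        a = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = read_newick("((a:1,c:1):1,(b:1,d:1):1);")
        freqs = split_frequencies([a] + [b] * 3, burnin_frac=0.25)
        assert all(f == 1.0 for f in freqs.values())
        assert set(freqs) == set(b.splits())


class TestAsdsf:
    def test_identical_maps_zero(self):
        f = {3: 0.9, 5: 0.4}
        assert asdsf(f, dict(f)) == 0.0

    def test_single_disagreeing_split(self):
        assert asdsf({3: 1.0}, {}, min_freq=0.1) == pytest.approx(0.7071, abs=1e-4)

    def test_below_threshold_split_ignored(self):
        base = asdsf({3: 1.0, 5: 0.6}, {3: 1.0, 5: 0.5})
        with_noise = asdsf({3: 1.0, 5: 0.6, 9: 0.05},
                           {3: 1.0, 5: 0.5, 9: 0.01})
        assert with_noise == pytest.approx(base, abs=1e-12)

    def test_no_qualifying_splits_is_error(self):
        with pytest.raises(ValueError):
            asdsf({3: 0.01}, {3: 0.02}, min_freq=0.1)


class TestPriorUtilities:
    def test_log_prior_decreases_with_tree_length(self, rng):
        tree = random_tree(6, rng)
        params = jc_params()
        lp1 = log_prior(tree, params)
        for node in tree.postorder():
            if node.parent is not None:
                node.length += 1.0
        assert log_prior(tree, params) < lp1

    def test_credible_interval_quantiles(self):
        x = np.linspace(0, 1, 1001)
        lo, hi = credible_interval(x, 0.9)
        assert lo == pytest.approx(0.05, abs=1e-3)
        assert hi == pytest.approx(0.95, abs=1e-3)
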