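import math

import numpy as np
import pytest

from rjcnv.model import Hyperparameters
from rjcnv.sampler import (SamplerConfig, SectionChain, initialize_chain,
                           run_section)


def make_chain(d, hp, mode="sample", seed=0, starts=None, states=None):
    cfg = SamplerConfig(burn_in=10, check_interval=10 ** 9,
                        state_update_mode=mode)
    if starts is None:
        starts, states = [0, len(d)], [2]
    return SectionChain(np.asarray(d, float), starts, states, hp, cfg,
                        np.random.default_rng(seed))


class TestInitialization:
    def test_constant_signal_single_normal_region(self, rng):
        starts, states = initialize_chain(np.full(300, 1.7), rng, hp_k=5)
        assert starts == [0, 300] and states == [2]

    def test_step_signal_breakpoint_near_truth(self, rng):
        d = np.concatenate([rng.normal(0.0, 0.1, 100),
                            rng.normal(1.0, 0.1, 100)])
        starts, states = initialize_chain(d, rng, hp_k=5)
        assert any(abs(b - 100) <= 5 for b in starts[1:-1])

    def test_interior_event_seeded_despite_smoothing(self, rng):
        # a short strong excursion deep inside a long flat track
        d = rng.normal(0.0, 0.2, 2000)
        d[900:950] += 1.2
        starts, states = initialize_chain(d, rng, hp_k=5)
        gains = [m for m in range(len(states)) if states[m] > 2]
        assert any(starts[m] < 950 and starts[m + 1] > 900 for m in gains)

    def test_invariants_on_random_tracks(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 400))
            d = rng.normal(0, 1, n) + np.repeat(
                rng.normal(0, 1, 4), math.ceil(n / 4))[:n]
            starts, states = initialize_chain(d, rng, hp_k=5)
            assert starts[0] == 0 and starts[-1] == n
            assert all(b > a for a, b in zip(starts, starts[1:]))
            assert len(states) == len(starts) - 1
            assert all(a != b for a, b in zip(states, states[1:]))
            assert all(1 <= s <= 5 for s in states)


class TestStateUpdate:
    def test_strong_data_selects_matching_state(self, hp3, rng):
        d = rng.normal(hp3.mu0[2], 0.05, 30)
        chain = make_chain(d, hp3, mode="argmax")
        chain.update_states()
        assert chain.states == [3]

    def test_argmax_is_idempotent(self, hp3, rng):
        d = rng.normal(0.0, 0.6, 12)
        chain = make_chain(d, hp3, mode="argmax",
                           starts=[0, 4, 8, 12], states=[1, 2, 3])
        chain.update_states()
        first = list(chain.states)
        chain.update_states()
        assert chain.states == first

    def test_sample_mode_matches_conditional_with_frozen_boundaries(
            self, hp3, rng, exact_marginals):
        # freeze B and compare empirical state frequencies with the exact
        # conditional obtained by enumerating P(C|D,B)
        d = rng.normal([0.0, 0.0, 0.4, 0.4, -0.7, -0.7], 0.4)
        chain = make_chain(d, hp3, mode="sample", seed=3,
                           starts=[0, 2, 4, 6], states=[2, 3, 1])
        cache = chain._enumerate_conditional()
        p = np.exp(cache["ll"] - cache["ll"].max())
        p /= p.sum()
        counts = {}
        n_draws = 4000
        for _ in range(n_draws):
            chain.update_states()
            key = tuple(chain.states)
            counts[key] = counts.get(key, 0) + 1
        for seq, prob in zip(map(tuple, cache["seqs"] + 1), p):
            if prob < 0.005:
                continue
            obs = counts.get(seq, 0) / n_draws
            se = math.sqrt(prob * (1 - prob) / n_draws)
            assert abs(obs - prob) < 4 * se + 0.01

    def test_sweep_agrees_with_enumeration_argmax(self, rng):
        # the incremental-delta sweep must reach the same fixed point as
        # the exact joint argmax on well-separated alternating data
        hp5 = Hyperparameters(k=5, lam=0.2, w0=(0.05, 0.8, 0.05, 0.05, 0.05),
                              mu0=(-0.7, 0.0, 0.4, 0.7, 0.9),
                              kappa=(25.0,) * 5, alpha=(2.0,) * 5,
                              beta=(0.1,) * 5)
        d = np.concatenate([rng.normal(hp5.mu0[0], 0.05, 6),
                            rng.normal(hp5.mu0[2], 0.05, 6),
                            rng.normal(hp5.mu0[0], 0.05, 6)])
        starts, states = [0, 6, 12, 18], [2, 1, 2]
        enum_chain = make_chain(d, hp5, mode="argmax", starts=list(starts),
                                states=list(states))
        enum_chain.update_states()
        assert enum_chain.states == [1, 3, 1]
        sweep_chain = make_chain(d, hp5, mode="argmax", starts=list(starts),
                                 states=list(states))
        sweep_chain.config.enumeration_limit = 0   # force the sweep path
        sweep_chain.update_states()
        sweep_chain.update_states()
        assert sweep_chain.states == enum_chain.states


class TestMoves:
    def test_cached_kernel_tracks_recomputation(self, hp3, rng):
        d = rng.normal(0, 0.8, 20)
        chain = make_chain(d, hp3, mode="sample", seed=7)
        for _ in range(300):
            chain.step()
            assert chain.log_kernel == pytest.approx(chain.audit(), abs=1e-8)
            chain._validate_structure()

    def test_double_merge_trigger_produces_one_region(self, hp3):
        d = np.zeros(6)
        chain = make_chain(d, hp3, mode="argmax",
                           starts=[0, 2, 4, 6], states=[3, 1, 3])
        merged = False
        for seed in range(200):
            c = make_chain(d, hp3, mode="argmax",
                           starts=[0, 2, 4, 6], states=[3, 1, 3])
            c.rng = np.random.default_rng(seed)
            if c.propose_merge() and c.M == 1:
                assert c.states == [3]
                merged = True
                break
        assert merged

    def test_split_candidate_states_exclude_original_and_neighbour(self, hp3):
        d = np.zeros(6)
        for seed in range(100):
            c = make_chain(d, hp3, mode="argmax",
                           starts=[0, 3, 6], states=[2, 3])
            c.rng = np.random.default_rng(seed)
            if c.propose_split():
                assert all(a != b for a, b in zip(c.states, c.states[1:]))

    def test_trifid_outer_states_keep_original(self, hp3):
        d = np.zeros(9)
        for seed in range(100):
            c = make_chain(d, hp3, mode="argmax")
            c.rng = np.random.default_rng(seed)
            if c.propose_trifid():
                assert c.M == 3
                assert c.states[0] == c.states[2] == 2
                assert c.states[1] != 2
                break

    def test_boundary_change_cannot_empty_a_region(self, hp3):
        d = np.zeros(4)
        c = make_chain(d, hp3, mode="argmax", starts=[0, 1, 4], states=[1, 2])
        # any left shift of the only breakpoint would empty region 1
        for seed in range(50):
            c.rng = np.random.default_rng(seed)
            c.propose_boundary_change()
            assert c.starts[1] >= 1

    def test_moves_noop_on_single_region_chain(self, hp3):
        d = np.zeros(1)
        c = make_chain(d, hp3, mode="argmax", starts=[0, 1], states=[2])
        assert not c.propose_merge()
        assert not c.propose_split()
        assert not c.propose_trifid()
        assert not c.propose_boundary_change()
        assert c.starts == [0, 1] and c.states == [2]


class TestPosteriorOracle:
    def test_chain_matches_enumeration_on_small_instance(
            self, hp3, rng, exact_marginals):
        # the flagship sanity check at unit-test scale: full RJMCMC in
        # sample mode against exhaustive (B, C) enumeration
        d = rng.normal([0.0, 0.0, 0.4, -0.7, 0.0], 0.5)
        exact = exact_marginals(d, hp3)
        cfg = SamplerConfig(burn_in=2000, check_interval=10 ** 9,
                            max_iterations=10 ** 9,
                            state_update_mode="sample")
        chain = SectionChain(d, [0, len(d)], [2], hp3, cfg,
                             np.random.default_rng(11))
        n_iter, burn = 22000, 2000
        nb = 30
        batches = np.zeros((nb, len(d), hp3.k))
        per = (n_iter - burn) // nb
        for t in range(1, n_iter + 1):
            chain.step()
            if t > burn:
                j = min((t - burn - 1) // per, nb - 1)
                for m in range(chain.M):
                    batches[j, chain.starts[m]:chain.starts[m + 1],
                            chain.states[m] - 1] += 1
        freq = batches.sum(axis=0)
        freq /= freq.sum(axis=1, keepdims=True)
        bfreq = batches / batches.sum(axis=2, keepdims=True)
        se = bfreq.std(axis=0, ddof=1) / math.sqrt(nb)
        assert np.all(np.abs(freq - exact) <= 3 * np.maximum(se, 0.005))


class TestRunSection:
    def test_homogeneous_section_converges_to_all_normal(self, hp3, rng):
        from rjcnv.caller import bayes_factors, call_window_states
        d = rng.normal(hp3.mu0[1], 0.3, 400)
        cfg = SamplerConfig(burn_in=500, check_interval=200,
                            max_iterations=10000)
        res = run_section(
            d, hp3, cfg, np.random.default_rng(5),
            call_predicate=lambda t: call_window_states(
                bayes_factors(t, hp3.w0), 20.0))
        assert res.converged
        assert res.iterations < 10000
        calls = call_window_states(bayes_factors(res.tally, hp3.w0), 20.0)
        assert (calls != 2).mean() <= 0.02

    def test_tally_rows_sum_to_post_burn_iterations(self, hp3, rng):
        d = rng.normal(0, 0.5, 50)
        cfg = SamplerConfig(burn_in=100, check_interval=10 ** 9,
                            max_iterations=600)
        res = run_section(d, hp3, cfg, np.random.default_rng(2))
        assert np.all(res.tally.sum(axis=1) == res.iterations - 100)

    def test_identical_seeds_give_identical_results(self, hp3, rng):
        d = rng.normal(0, 0.6, 120)
        cfg = SamplerConfig(burn_in=200, check_interval=10 ** 9,
                            max_iterations=1500, state_update_mode="sample")
        r1 = run_section(d, hp3, cfg, np.random.default_rng(9))
        r2 = run_section(d, hp3, cfg, np.random.default_rng(9))
        assert np.array_equal(r1.tally, r2.tally)
        assert r1.starts == r2.starts and r1.states == r2.states

    def test_empty_section_rejected(self, hp3):
        with pytest.raises(ValueError):
            run_section(np.array([]), hp3, SamplerConfig(burn_in=1,
                                                         max_iterations=10),
                        np.random.default_rng(0))
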