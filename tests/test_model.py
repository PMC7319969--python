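import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import dblquad

from rjcnv.model import (BoundaryVector, Hyperparameters, RegionStateSequence,
                         estimate_hyperparameters, log_boundary_prior,
                         log_depth_likelihood, log_posterior_kernel,
                         log_state_prior)
from conftest import nig_marginal_quadrature


def all_distinct_sequences(m, k):
    for s in itertools.product(range(1, k + 1), repeat=m):
        if all(a != b for a, b in zip(s, s[1:])):
            yield s


class TestBoundaryVector:
    def test_end_indicators_must_be_one(self):
        with pytest.raises(ValueError):
            BoundaryVector((0, 1, 1))

    def test_region_lengths_sum_to_window_count(self):
        b = BoundaryVector((1, 0, 1, 0, 0, 1))
        assert b.n_windows == 5
        assert b.region_lengths == (2, 3)
        assert b.n_regions == 2


class TestBoundaryPrior:
    def test_single_region_value(self):
        b = BoundaryVector.from_breaks(10, [])
        assert log_boundary_prior(b, 0.1) == pytest.approx(9 * math.log(0.9))

    def test_all_boundaries_on(self):
        b = BoundaryVector.from_breaks(10, list(range(1, 10)))
        assert log_boundary_prior(b, 0.1) == pytest.approx(9 * math.log(0.1))

    @pytest.mark.parametrize("lam", [0.1, 0.37, 0.8])
    def test_normalizes_over_all_configurations(self, lam):
        i_n = 6
        total = sum(
            math.exp(log_boundary_prior(
                BoundaryVector((1,) + bits + (1,)), lam))
            for bits in itertools.product([0, 1], repeat=i_n - 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_lambda_domain_checked(self):
        b = BoundaryVector.from_breaks(4, [])
        with pytest.raises(ValueError):
            log_boundary_prior(b, 1.0)


class TestStatePrior:
    def test_single_region_is_prior_weight(self):
        w0 = (0.2, 0.5, 0.3)
        for k in (1, 2, 3):
            v = log_state_prior(RegionStateSequence((k,), 3), w0)
            assert v == pytest.approx(math.log(w0[k - 1]))

    def test_two_region_closed_form(self):
        # first-state weight times the reduced-simplex mean of the follower
        v = log_state_prior(RegionStateSequence((2, 1), 3), (0.1, 0.8, 0.1))
        assert math.exp(v) == pytest.approx(0.8 * (0.1 / 0.2), rel=1e-12)

    @pytest.mark.parametrize("m,k", [(3, 3), (4, 3), (3, 4), (5, 3)])
    def test_normalizes_over_neighbour_distinct_sequences(self, m, k, rng):
        w0 = rng.dirichlet(np.ones(k))
        total = sum(
            math.exp(log_state_prior(RegionStateSequence(s, k), tuple(w0)))
            for s in all_distinct_sequences(m, k))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_sequential_polya_predictive(self, rng):
        # independent oracle: the Dirichlet-multinomial predictive applied
        # region by region (urn per predecessor state, concentration 1)
        k = 4
        w0 = tuple(rng.dirichlet(np.ones(k)))
        for _ in range(20):
            m = int(rng.integers(2, 9))
            s = [int(rng.integers(1, k + 1))]
            while len(s) < m:
                c = int(rng.integers(1, k + 1))
                if c != s[-1]:
                    s.append(c)
            log_p = math.log(w0[s[0] - 1])
            counts, totals = {}, {}
            for prev, cur in zip(s, s[1:]):
                a = w0[cur - 1] / (1.0 - w0[prev - 1])
                c_prev = counts.get((prev, cur), 0)
                t_prev = totals.get(prev, 0)
                log_p += math.log((a + c_prev) / (1.0 + t_prev))
                counts[(prev, cur)] = c_prev + 1
                totals[prev] = t_prev + 1
            v = log_state_prior(RegionStateSequence(tuple(s), k), w0)
            assert v == pytest.approx(log_p, abs=1e-10)

    def test_exchangeable_in_transition_order(self):
        # sequences with identical transition multisets have equal prior
        w0 = (0.3, 0.4, 0.3)
        # (1,2,1,3,1) and (1,3,1,2,1) share the same first state and the
        # same multiset of transitions, so the Polya closed form agrees
        a = log_state_prior(RegionStateSequence((1, 2, 1, 3, 1), 3), w0)
        b = log_state_prior(RegionStateSequence((1, 3, 1, 2, 1), 3), w0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_neighbour_equal_sequence_rejected(self):
        with pytest.raises(ValueError):
            RegionStateSequence((1, 1, 2), 3)


class TestDepthLikelihood:
    def test_single_window_matches_student_t(self, hp3):
        # the NIG marginal of one observation is location-scale t with
        # 2*alpha df, location mu0, scale^2 = beta (kappa+1)/(alpha kappa)
        d = np.array([0.15])
        b = BoundaryVector.from_breaks(1, [])
        for state in (1, 2, 3):
            s = RegionStateSequence((state,), 3)
            ll = log_depth_likelihood(d, b, s, hp3)
            j = state - 1
            scale = math.sqrt(hp3.beta[j] * (hp3.kappa[j] + 1)
                              / (hp3.alpha[j] * hp3.kappa[j]))
            expected = stats.t.logpdf(d[0], df=2 * hp3.alpha[j],
                                      loc=hp3.mu0[j], scale=scale)
            assert ll == pytest.approx(expected, rel=1e-12)

    def test_matches_numerical_quadrature(self, rng):
        # marginal equals the 2-D integral of normal x normal x inv-gamma
        for _ in range(5):
            l_m = int(rng.integers(1, 6))
            d = rng.normal(0.2, 0.7, l_m)
            mu0 = float(rng.normal(0, 0.5))
            kap = float(rng.uniform(0.5, 3.0))
            al = float(rng.uniform(1.5, 3.0))
            be = float(rng.uniform(0.3, 1.5))
            hp = Hyperparameters(k=3, lam=0.3, w0=(0.2, 0.6, 0.2),
                                 mu0=(mu0 - 1, mu0, mu0 + 1),
                                 kappa=(kap,) * 3, alpha=(al,) * 3,
                                 beta=(be,) * 3)
            b = BoundaryVector.from_breaks(l_m, [])
            s = RegionStateSequence((2,), 3)
            ll = log_depth_likelihood(d, b, s, hp)

            q = nig_marginal_quadrature(d, mu0, kap, al, be)
            assert ll == pytest.approx(math.log(q), rel=1e-6)

    def test_invariant_to_window_permutation_within_region(self, rng, hp3):
        d = rng.normal(0.0, 1.0, 8)
        b = BoundaryVector.from_breaks(8, [3])
        s = RegionStateSequence((1, 2), 3)
        base = log_depth_likelihood(d, b, s, hp3)
        d2 = np.concatenate([d[:3][::-1], rng.permutation(d[3:])])
        assert log_depth_likelihood(d2, b, s, hp3) == pytest.approx(base, rel=1e-12)

    def test_length_mismatch_rejected(self, hp3):
        with pytest.raises(ValueError):
            log_depth_likelihood(np.zeros(3), BoundaryVector.from_breaks(4, []),
                                 RegionStateSequence((2,), 3), hp3)


class TestPosteriorKernel:
    def test_additivity_of_log_factors(self, rng, hp3):
        d = rng.normal(0, 1, 6)
        b = BoundaryVector.from_breaks(6, [2, 4])
        s = RegionStateSequence((1, 3, 2), 3)
        total = log_posterior_kernel(d, b, s, hp3)
        parts = (log_boundary_prior(b, hp3.lam)
                 + log_state_prior(s, hp3)
                 + log_depth_likelihood(d, b, s, hp3))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_kernel_increases_as_data_approach_state_mean(self, hp3):
        b = BoundaryVector.from_breaks(4, [])
        s = RegionStateSequence((3,), 3)
        offsets = np.linspace(1.5, 0.0, 10)
        vals = [log_posterior_kernel(np.full(4, hp3.mu0[2] + off), b, s, hp3)
                for off in offsets]
        assert all(b2 >= a2 for a2, b2 in zip(vals, vals[1:]))


class TestEstimateHyperparameters:
    def test_single_mode_mu0_ladder(self):
        d = np.full(200, math.log(100.0))
        with pytest.warns(RuntimeWarning, match="near-constant"):
            hp = estimate_hyperparameters(d, mode="single")
        expected = [math.log(100.0) + math.log(k / 2.0) for k in (1, 2, 3, 4, 5)]
        assert hp.mu0 == pytest.approx(expected)

    def test_paired_mode_centred_ratios(self, rng):
        d = rng.normal(0.0, 0.1, 500)
        d -= np.median(d)
        hp = estimate_hyperparameters(d, mode="paired")
        assert hp.k == 3
        assert hp.mu0 == pytest.approx((math.log(0.5), 0.0, math.log(1.5)),
                                       abs=1e-9)

    @pytest.mark.parametrize("mode", ["single", "paired"])
    def test_w0_on_the_simplex(self, mode, rng):
        d = rng.normal(5.0, 0.3, 300)
        hp = estimate_hyperparameters(d, mode=mode)
        assert sum(hp.w0) == pytest.approx(1.0)
        assert all(w > 0 for w in hp.w0)

    def test_beta_matches_prior_variance_mean(self, rng):
        d = rng.normal(5.0, 0.4, 5000)
        hp = estimate_hyperparameters(d, mode="single")
        s2 = (1.4826 * np.median(np.abs(d - np.median(d)))) ** 2
        # E[sigma^2] = beta/(alpha-1) should equal the MAD-based estimate
        assert hp.beta[0] / (hp.alpha[0] - 1.0) == pytest.approx(s2, rel=1e-9)

    def test_lambda_from_initial_breakpoint_density(self, rng):
        d = rng.normal(0, 0.2, 1000)
        hp = estimate_hyperparameters(d, mode="single", m_init=11)
        assert hp.lam == pytest.approx(10 / 999)
        hp1 = estimate_hyperparameters(d, mode="single", m_init=1)
        assert hp1.lam == pytest.approx(1 / 1000)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="100"):
            estimate_hyperparameters(np.zeros(50), mode="single")

    def test_overrides_take_precedence(self, rng):
        d = rng.normal(0, 0.3, 200)
        hp = estimate_hyperparameters(d, mode="single",
                                      overrides={"lam": 0.123,
                                                 "kappa": (9.0,) * 5})
        assert hp.lam == 0.123 and hp.kappa == (9.0,) * 5
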