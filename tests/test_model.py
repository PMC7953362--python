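import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsroc.dta_io import DTADataset, StudyRecord
from hsroc.model import (
    HSROCParams,
    PriorConfig,
    log_likelihood,
    log_posterior,
    log_prior,
    simulate_dataset,
    study_probabilities,
)


def invlogit(x):
    return 1.0 / (1.0 + math.exp(-x))


def _random_params(n, rng):
    return HSROCParams(
        theta=rng.normal(0, 1, n),
        alpha=rng.normal(2, 1, n),
        theta_g=rng.normal(),
        alpha_g=rng.normal(2, 1),
        beta=rng.normal(0, 0.5),
        s_theta=rng.uniform(0.2, 2.0),
        s_alpha=rng.uniform(0.2, 2.0),
    )


def brute_force_log_posterior(d, p):
    """Term-by-term oracle built from scalar math only (no scipy, no vectorization)."""
    total = 0.0
    for i, s in enumerate(d):
        th, al = float(p.theta[i]), float(p.alpha[i])
        l1 = (th + al / 2.0) * math.exp(-p.beta / 2.0)
        l0 = (th - al / 2.0) * math.exp(p.beta / 2.0)
        pi1, pi0 = invlogit(l1), invlogit(l0)
        for k, n, pi in ((s.tp, s.tp + s.fn, pi1), (s.fp, s.fp + s.tn, pi0)):
            total += (
                math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                + k * math.log(pi) + (n - k) * math.log(1.0 - pi)
            )
        for x, mu, sd in ((th, p.theta_g, p.s_theta), (al, p.alpha_g, p.s_alpha)):
            total += -0.5 * math.log(2 * math.pi) - math.log(sd) - (x - mu) ** 2 / (2 * sd * sd)
    return total


class TestStudyProbabilities:
    def test_symmetric_point(self):
        assert study_probabilities(0.0, 0.0, 0.0) == (0.5, 0.5)

    def test_closed_form_alpha_two(self):
        pi1, pi0 = study_probabilities(0.0, 2.0, 0.0)
        assert pi1 == pytest.approx(invlogit(1.0), abs=1e-6)
        assert pi0 == pytest.approx(invlogit(-1.0), abs=1e-6)
        assert pi1 == pytest.approx(0.731059, abs=1e-6)

    def test_asymmetric_point(self):
        # evaluated independently: logit(pi1) = 2.0*e^{-0.1}, logit(pi0) = -1.0*e^{0.1}
        pi1, pi0 = study_probabilities(0.5, 3.0, 0.2)
        assert pi1 == pytest.approx(invlogit(2.0 * math.exp(-0.1)), rel=1e-12)
        assert pi0 == pytest.approx(invlogit(-1.0 * math.exp(0.1)), rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            study_probabilities(math.nan, 0.0, 0.0)
        with pytest.raises(ValueError):
            study_probabilities(0.0, math.inf, 0.0)

    @given(
        theta=st.floats(-5, 5),
        alpha=st.floats(-5, 5),
    )
    def test_beta_zero_gives_log_dor_alpha(self, theta, alpha):
        pi1, pi0 = study_probabilities(theta, alpha, 0.0)
        log_dor = math.log(pi1 / (1 - pi1)) - math.log(pi0 / (1 - pi0))
        assert log_dor == pytest.approx(alpha, abs=1e-9)

    def test_vectorized(self):
        pi1, pi0 = study_probabilities(np.zeros(3), np.full(3, 2.0), 0.0)
        assert pi1.shape == (3,)
        assert np.all((0 < pi1) & (pi1 < 1)) and np.all((0 < pi0) & (pi0 < 1))


class TestLogLikelihood:
    def test_single_balanced_study(self):
        d = DTADataset([StudyRecord("a", 1, 1, 1, 1)])
        p = HSROCParams([0.0], [0.0], 0.0, 0.0, 0.0, 1.0, 1.0)
        # Binom(1 | 2, 0.5) = 0.5 twice
        assert log_likelihood(d, p) == pytest.approx(2 * math.log(0.5), abs=1e-9)

    def test_matches_bruteforce_oracle(self, table1, rng):
        for _ in range(10):
            p = _random_params(9, rng)
            oracle = 0.0
            for s in table1:
                i = table1.studies.index(s)
                l1 = (p.theta[i] + p.alpha[i] / 2) * math.exp(-p.beta / 2)
                l0 = (p.theta[i] - p.alpha[i] / 2) * math.exp(p.beta / 2)
                for k, n, l in ((s.tp, s.n_diseased, l1), (s.fp, s.n_nondiseased, l0)):
                    pi = invlogit(l)
                    oracle += (math.lgamma(n + 1) - math.lgamma(k + 1)
                               - math.lgamma(n - k + 1)
                               + k * math.log(pi) + (n - k) * math.log(1 - pi))
            assert log_likelihood(table1, p) == pytest.approx(oracle, rel=1e-10)

    def test_finite_with_zero_cells(self):
        d = DTADataset([StudyRecord("a", 0, 10, 5, 5), StudyRecord("b", 5, 5, 0, 10)])
        p = HSROCParams([0.0, 0.0], [1.0, 1.0], 0.0, 1.0, 0.0, 1.0, 1.0)
        assert math.isfinite(log_likelihood(d, p))

    def test_dimension_mismatch(self, table1):
        p = HSROCParams([0.0], [0.0], 0.0, 0.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="length"):
            log_likelihood(table1, p)

    def test_maximized_at_empirical_logits(self):
        # grid-search oracle: for one study with beta=0 the likelihood peaks
        # where pi1, pi0 equal the empirical proportions
        d = DTADataset([StudyRecord("a", 30, 10, 10, 30)])
        l1_hat = math.log(30 / 10)
        l0_hat = math.log(10 / 30)
        grid = np.linspace(-3, 3, 121)
        best, best_ta = -np.inf, None
        for th in grid:
            for al in grid:
                p = HSROCParams([th], [al], 0.0, 0.0, 0.0, 1.0, 1.0)
                ll = log_likelihood(d, p)
                if ll > best:
                    best, best_ta = ll, (th, al)
        step = grid[1] - grid[0]
        assert best_ta[0] == pytest.approx((l1_hat + l0_hat) / 2, abs=step)
        assert best_ta[1] == pytest.approx(l1_hat - l0_hat, abs=step)


class TestLogPrior:
    def test_negative_sd_excluded(self):
        p = HSROCParams([0.0], [0.0], 0.0, 0.0, 0.0, -0.1, 1.0)
        assert log_prior(p, PriorConfig()) == -math.inf

    def test_flat_inside_support(self):
        p = HSROCParams([0.0], [0.0], 0.0, 0.0, 0.0, 1.0, 1.0)
        assert log_prior(p, PriorConfig()) == 0.0

    def test_hypermean_truncation(self):
        p = HSROCParams([0.0], [0.0], 0.0, 0.0, 9.0, 1.0, 1.0)
        assert log_prior(p, PriorConfig(hypermean_halfwidth=5.0)) == -math.inf
        assert log_prior(p, PriorConfig()) == 0.0

    def test_sd_upper_truncation(self):
        p = HSROCParams([0.0], [0.0], 0.0, 0.0, 0.0, 3.0, 1.0)
        assert log_prior(p, PriorConfig(sd_upper=2.0)) == -math.inf


class TestLogPosterior:
    def test_matches_bruteforce_oracle(self, table1, rng):
        for _ in range(10):
            p = _random_params(9, rng)
            assert log_posterior(table1, p) == pytest.approx(
                brute_force_log_posterior(table1, p), rel=1e-10)

    def test_additivity_over_studies(self, table1, rng):
        p = _random_params(9, rng)
        reduced = DTADataset(table1.studies[:-1])
        p_red = HSROCParams(p.theta[:-1], p.alpha[:-1], p.theta_g, p.alpha_g,
                            p.beta, p.s_theta, p.s_alpha)
        last = DTADataset([table1.studies[-1]])
        p_last = HSROCParams(p.theta[-1:], p.alpha[-1:], p.theta_g, p.alpha_g,
                             p.beta, p.s_theta, p.s_alpha)
        whole = log_posterior(table1, p)
        # prior contributes 0 inside the support, so the split is exact
        assert whole == pytest.approx(
            log_posterior(reduced, p_red) + log_posterior(last, p_last), rel=1e-10)

    def test_invariant_to_study_order(self, table1, rng):
        p = _random_params(9, rng)
        perm = rng.permutation(9)
        shuffled = DTADataset([table1.studies[i] for i in perm])
        p_perm = HSROCParams(p.theta[perm], p.alpha[perm], p.theta_g, p.alpha_g,
                             p.beta, p.s_theta, p.s_alpha)
        assert log_posterior(shuffled, p_perm) == pytest.approx(
            log_posterior(table1, p), rel=1e-12)

    def test_degenerate_sd_is_minus_inf(self, table1, rng):
        p = _random_params(9, rng)
        p.s_theta = 0.0
        assert log_posterior(table1, p) == -math.inf


class TestSimulateDataset:
    def test_reproducible_and_sized(self):
        a = simulate_dataset((0.0, 2.0, 0.0, 0.5, 0.5), 9, 100, 100, seed=42)
        b = simulate_dataset((0.0, 2.0, 0.0, 0.5, 0.5), 9, 100, 100, seed=42)
        assert len(a) == 9
        assert [vars(s) for s in a] == [vars(s) for s in b]

    def test_different_seed_differs(self):
        a = simulate_dataset((0.0, 2.0, 0.0, 0.5, 0.5), 9, 100, 100, seed=1)
        b = simulate_dataset((0.0, 2.0, 0.0, 0.5, 0.5), 9, 100, 100, seed=2)
        assert [vars(s) for s in a] != [vars(s) for s in b]

    def test_invariants_respected(self):
        d = simulate_dataset((0.0, 0.0, 0.0, 2.0, 2.0), 50, 5, 5, seed=7)
        for s in d:
            assert s.tp + s.fn == 5 and s.fp + s.tn == 5

    def test_law_of_large_numbers_recovers_lambda(self):
        # sigma = 0, beta = 0: every study's empirical log-DOR converges to Lambda
        lam = 2.0
        d = simulate_dataset((0.3, lam, 0.0, 0.0, 0.0), 5, 100_000, 100_000, seed=11)
        for s in d:
            log_dor = (math.log(s.tp / s.fn) - math.log(s.fp / s.tn))
            assert log_dor == pytest.approx(lam, abs=0.05)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_dataset((0, 1, 0, 0.5, 0.5), 0, 10, 10, seed=1)
        with pytest.raises(ValueError):
            simulate_dataset((0, 1, 0, -0.5, 0.5), 5, 10, 10, seed=1)
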