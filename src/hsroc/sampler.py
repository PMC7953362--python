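"""Posterior sampling for the HSROC model.

The reference sampler is a blocked MCMC scheme on the centered
parameterization:

* per-study pairs (theta_i, alpha_i): adaptive random-walk Metropolis,
  proposed and accepted independently across studies (they are conditionally
  independent given the hyper-parameters);
* hyper-means Theta and Lambda: exact Gibbs draws — with a flat prior the
  full conditional is Normal(mean of the study parameters, sd^2/n);
* hyper-variances: exact Gibbs draws — a flat prior on the SD makes the full
  conditional of the variance Inverse-Gamma((n-1)/2, S/2);
* shape parameter beta: scalar adaptive random-walk Metropolis.

Proposal scales adapt during warmup toward a 25-45% acceptance rate and are
frozen afterwards.  Several full sweeps are performed per recorded
iteration (``sweeps_per_iter``) so that the default recorded configuration
(4 chains x 500 post-warmup draws) delivers effective sample sizes
comparable to a NUTS backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .dta_io import DTADataset, validate_dataset
from .model import HSROCParams, PriorConfig, log_posterior

__all__ = ["MCMCConfig", "PosteriorDraws", "initialize_chain", "run_mcmc", "param_names"]

_HYPER_KEYS = ("beta", "theta_g", "alpha_g", "s_theta", "s_alpha")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration; defaults replicate the reference application."""

    chains: int = 4
    iter: int = 1000
    warmup: int = 500
    thin: int = 1
    seed: int = 0
    #: internal full Gibbs sweeps per recorded iteration; purely a mixing
    #: control, does not change the recorded-draw arithmetic above
    sweeps_per_iter: int = 5

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required (split-Rhat needs them)")
        if not (0 <= self.warmup < self.iter):
            raise ValueError("warmup must satisfy 0 <= warmup < iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sweeps_per_iter < 1:
            raise ValueError("sweeps_per_iter must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iter - self.warmup) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC states, indexed (chain, draw, quantity)."""

    names: list[str]
    values: np.ndarray
    config: MCMCConfig

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError("values must have shape (chains, draws, len(names))")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def get(self, name: str) -> np.ndarray:
        """Draws of one quantity as a (chains, draws) array."""
        try:
            return self.values[:, :, self._index[name]]
        except KeyError:
            raise ValueError(f"no monitored quantity named {name!r}") from None

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one quantity pooled across chains (1-D)."""
        return self.get(name).reshape(-1)

    def with_quantities(self, names: Sequence[str], values: np.ndarray) -> "PosteriorDraws":
        """A new object with extra monitored quantities appended."""
        if values.shape != (self.n_chains, self.n_draws, len(names)):
            raise ValueError("appended values have wrong shape")
        return PosteriorDraws(
            names=list(self.names) + list(names),
            values=np.concatenate([self.values, values], axis=2),
            config=self.config,
        )


def param_names(n_studies: int) -> list[str]:
    """Monitored-quantity labels for the model parameters, in report order."""
    return (
        [f"theta {i + 1}" for i in range(n_studies)]
        + [f"alpha {i + 1}" for i in range(n_studies)]
        + ["beta", "theta_g", "alpha_g", "s_theta", "s_alpha"]
    )


def initialize_chain(
    d: DTADataset,
    rng: np.random.Generator,
    jitter: float = 0.1,
    prior: Optional[PriorConfig] = None,
) -> HSROCParams:
    """Empirical-logit starting values, jittered per chain.

    A continuity correction of +0.5 per cell (for initialization only; the
    likelihood itself never uses one) keeps the logits finite for studies
    with zero cells.
    """
    prior = prior or PriorConfig()
    tp = np.array([s.tp for s in d], dtype=float)
    n1 = np.array([s.n_diseased for s in d], dtype=float)
    fp = np.array([s.fp for s in d], dtype=float)
    n0 = np.array([s.n_nondiseased for s in d], dtype=float)
    l1 = np.log((tp + 0.5) / (n1 - tp + 0.5))
    l0 = np.log((fp + 0.5) / (n0 - fp + 0.5))
    theta0 = (l1 + l0) / 2.0
    alpha0 = l1 - l0

    h = prior.hypermean_halfwidth
    s_cap = prior.sd_upper

    for _ in range(100):
        theta = theta0 + jitter * rng.standard_normal(theta0.size)
        alpha = alpha0 + jitter * rng.standard_normal(alpha0.size)
        theta_g = float(np.clip(theta.mean() + jitter * rng.standard_normal(), -h, h))
        alpha_g = float(np.clip(alpha.mean() + jitter * rng.standard_normal(), -h, h))
        beta = float(np.clip(jitter * rng.standard_normal(), -h, h))
        s_theta = float(max(np.std(theta, ddof=1), 0.1) * math.exp(jitter * rng.standard_normal()))
        s_alpha = float(max(np.std(alpha, ddof=1), 0.1) * math.exp(jitter * rng.standard_normal()))
        if math.isfinite(s_cap):
            s_theta = min(s_theta, 0.9 * s_cap)
            s_alpha = min(s_alpha, 0.9 * s_cap)
        p = HSROCParams(theta, alpha, theta_g, alpha_g, beta, s_theta, s_alpha)
        if math.isfinite(log_posterior(d, p, prior)):
            return p
    raise RuntimeError("could not find a finite-posterior initial state")


def _truncated_normal_draw(rng, mu, sd, halfwidth, current):
    if not math.isfinite(halfwidth):
        return mu + sd * rng.standard_normal()
    for _ in range(100):
        x = mu + sd * rng.standard_normal()
        if abs(x) <= halfwidth:
            return x
    return current


def _sd_gibbs_draw(rng, x, center, sd_upper, current):
    # flat prior on the SD => variance | rest ~ InvGamma((n-1)/2, S/2)
    n = x.size
    s_sq = float(np.sum((x - center) ** 2))
    if s_sq <= 0.0:
        return current
    shape = (n - 1) / 2.0
    for _ in range(100):
        sd = math.sqrt(0.5 * s_sq / rng.standard_gamma(shape))
        if sd <= sd_upper:
            return sd
    return current


def _run_chain(d, config, prior, fix, rng):
    tp = np.array([s.tp for s in d], dtype=float)
    n1 = np.array([s.n_diseased for s in d], dtype=float)
    fp = np.array([s.fp for s in d], dtype=float)
    n0 = np.array([s.n_nondiseased for s in d], dtype=float)
    n = tp.size

    def ll_terms(theta, alpha, beta):
        # per-study binomial log-likelihood up to count-only constants
        e = math.exp(-beta / 2.0)
        l1 = (theta + alpha / 2.0) * e
        l0 = (theta - alpha / 2.0) / e
        return (tp * l1 - n1 * np.logaddexp(0.0, l1)
                + fp * l0 - n0 * np.logaddexp(0.0, l0))

    init = initialize_chain(d, rng, prior=prior)
    theta = init.theta.copy()
    alpha = init.alpha.copy()
    state = {
        "beta": init.beta, "theta_g": init.theta_g, "alpha_g": init.alpha_g,
        "s_theta": init.s_theta, "s_alpha": init.s_alpha,
    }
    state.update(fix)

    h = prior.hypermean_halfwidth
    sd_upper = prior.sd_upper
    sqrt_n = math.sqrt(n)

    stud_scale = np.full(n, 0.5)
    beta_scale = 0.3
    rescale_scale = 0.3
    stud_acc = np.zeros(n)
    beta_acc = 0
    rescale_acc = 0
    batch = 25  # recorded iterations per adaptation batch

    n_keep = config.draws_per_chain
    out = np.empty((n_keep, 2 * n + 5))
    keep = 0

    cur_ll = ll_terms(theta, alpha, state["beta"])
    for it in range(config.iter):
        for _ in range(config.sweeps_per_iter):
            # per-study (theta_i, alpha_i) random-walk updates, vectorized
            th_p = theta + stud_scale * rng.standard_normal(n)
            al_p = alpha + stud_scale * rng.standard_normal(n)
            ll_p = ll_terms(th_p, al_p, state["beta"])
            st, sa = state["s_theta"], state["s_alpha"]
            d_hier = (
                ((theta - state["theta_g"]) ** 2 - (th_p - state["theta_g"]) ** 2) / (2 * st * st)
                + ((alpha - state["alpha_g"]) ** 2 - (al_p - state["alpha_g"]) ** 2) / (2 * sa * sa)
            )
            accept = np.log(rng.random(n)) < (ll_p - cur_ll + d_hier)
            theta[accept] = th_p[accept]
            alpha[accept] = al_p[accept]
            cur_ll[accept] = ll_p[accept]
            stud_acc += accept

            # exact Gibbs draws for the conjugate hyper-parameter blocks
            if "theta_g" not in fix:
                state["theta_g"] = _truncated_normal_draw(
                    rng, float(theta.mean()), state["s_theta"] / sqrt_n, h, state["theta_g"])
            if "alpha_g" not in fix:
                state["alpha_g"] = _truncated_normal_draw(
                    rng, float(alpha.mean()), state["s_alpha"] / sqrt_n, h, state["alpha_g"])
            if "s_theta" not in fix:
                state["s_theta"] = _sd_gibbs_draw(rng, theta, state["theta_g"], sd_upper, state["s_theta"])
            if "s_alpha" not in fix:
                state["s_alpha"] = _sd_gibbs_draw(rng, alpha, state["alpha_g"], sd_upper, state["s_alpha"])

            # beta: scalar random-walk Metropolis
            if "beta" not in fix:
                b_p = state["beta"] + beta_scale * rng.standard_normal()
                if abs(b_p) <= h:
                    ll_b = ll_terms(theta, alpha, b_p)
                    if math.log(rng.random()) < float(ll_b.sum() - cur_ll.sum()):
                        state["beta"] = b_p
                        cur_ll = ll_b
                        beta_acc += 1

                # likelihood-invariant reparameterization move along the stiff
                # direction: shift beta and rescale every (theta_i, alpha_i) so
                # that all study probabilities stay exactly fixed (the map is
                # linear per study with unit Jacobian), so only the hierarchy
                # terms enter the acceptance ratio
                eps = rescale_scale * rng.standard_normal()
                b_p = state["beta"] + eps
                if abs(b_p) <= h:
                    c = math.exp(eps / 2.0)
                    u = (theta + alpha / 2.0) * c
                    v = (theta - alpha / 2.0) / c
                    th_p = (u + v) / 2.0
                    al_p = u - v
                    st, sa = state["s_theta"], state["s_alpha"]
                    d_hier = float(
                        (((theta - state["theta_g"]) ** 2 - (th_p - state["theta_g"]) ** 2)
                         / (2 * st * st)
                         + ((alpha - state["alpha_g"]) ** 2 - (al_p - state["alpha_g"]) ** 2)
                         / (2 * sa * sa)).sum()
                    )
                    if math.log(rng.random()) < d_hier:
                        state["beta"] = b_p
                        theta = th_p
                        alpha = al_p
                        cur_ll = ll_terms(theta, alpha, b_p)
                        rescale_acc += 1

        if it < config.warmup and (it + 1) % batch == 0:
            attempts = batch * config.sweeps_per_iter
            rate = stud_acc / attempts
            stud_scale = stud_scale * np.where(rate > 0.45, 1.5, np.where(rate < 0.25, 1 / 1.5, 1.0))
            b_rate = beta_acc / attempts
            if b_rate > 0.45:
                beta_scale *= 1.5
            elif b_rate < 0.25:
                beta_scale /= 1.5
            r_rate = rescale_acc / attempts
            if r_rate > 0.45:
                rescale_scale *= 1.5
            elif r_rate < 0.25:
                rescale_scale /= 1.5
            stud_acc[:] = 0.0
            beta_acc = 0
            rescale_acc = 0

        if it >= config.warmup and (it - config.warmup) % config.thin == 0 and keep < n_keep:
            out[keep, :n] = theta
            out[keep, n:2 * n] = alpha
            out[keep, 2 * n:] = (state["beta"], state["theta_g"], state["alpha_g"],
                                 state["s_theta"], state["s_alpha"])
            keep += 1
    return out


def run_mcmc(
    d: DTADataset,
    config: Optional[MCMCConfig] = None,
    prior: Optional[PriorConfig] = None,
    target=None,
    fix_params: Optional[Mapping[str, float]] = None,
) -> PosteriorDraws:
    """Sample the HSROC posterior.

    Parameters
    ----------
    d : dataset of 2x2 tables (must pass :func:`validate_dataset`)
    config : chain configuration (defaults: 4 chains x 1000 iter, 500 warmup)
    prior : prior truncation limits
    target : optional :class:`hsroc.summary_points.FixedTarget`; when given,
        the derived quantities (pi, sn, sp, other_snsp) are monitored too
    fix_params : optionally clamp hyper-parameters (keys among beta, theta_g,
        alpha_g, s_theta, s_alpha) at fixed values — used for collapsed-model
        checks, not part of the ordinary workflow

    Returns
    -------
    PosteriorDraws, deterministic for identical (d, config, prior, seed).
    """
    config = config or MCMCConfig()
    prior = prior or PriorConfig()
    validate_dataset(d)
    fix = dict(fix_params or {})
    unknown = set(fix) - set(_HYPER_KEYS)
    if unknown:
        raise ValueError(f"fix_params keys must be among {_HYPER_KEYS}, got {sorted(unknown)}")

    children = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [
        _run_chain(d, config, prior, fix, np.random.default_rng(children[c]))
        for c in range(config.chains)
    ]
    draws = PosteriorDraws(
        names=param_names(len(d)),
        values=np.stack(chains, axis=0),
        config=config,
    )
    if target is not None:
        from .summary_points import derived_quantities

        draws = derived_quantities(draws, target)
    return draws
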