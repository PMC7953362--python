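"""The Rutter-Gatsonis HSROC generative model.

Each study i has a cut-point (positivity-threshold) parameter ``theta_i`` and
an accuracy parameter ``alpha_i`` (a log diagnostic odds ratio).  With the
disease-group coding X = +1/2 (diseased) and -1/2 (non-diseased), the
true- and false-positive probabilities of study i are

    logit(pi1_i) = (theta_i + alpha_i / 2) * exp(-beta / 2)
    logit(pi0_i) = (theta_i - alpha_i / 2) * exp(+beta / 2)

where ``beta`` is a shape parameter controlling the asymmetry of the summary
ROC curve (beta = 0 gives a constant log-DOR curve).  Across studies the
study parameters are exchangeable:

    theta_i ~ Normal(Theta, sigma_theta^2)
    alpha_i ~ Normal(Lambda, sigma_alpha^2)

with hyper-means ``Theta`` (theta_g) and ``Lambda`` (alpha_g).  Observed
counts are binomial: TP_i ~ Bin(TP_i + FN_i, pi1_i), FP_i ~ Bin(FP_i + TN_i,
pi0_i).  Priors are non-informative: improper flat on Theta, Lambda, beta
(optionally truncated) and Uniform(0, sd_upper) on the two hyper-SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .dta_io import DTADataset, StudyRecord

__all__ = [
    "HSROCParams",
    "PriorConfig",
    "study_probabilities",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "simulate_dataset",
]


@dataclass
class HSROCParams:
    """One point in HSROC parameter space.

    theta, alpha are per-study vectors (logit / log-DOR scale); theta_g and
    alpha_g their hyper-means; beta the SROC shape parameter; s_theta,
    s_alpha the between-study SDs.  Negative SDs are representable (the
    prior assigns them -inf) so that samplers may propose freely.
    """

    theta: np.ndarray
    alpha: np.ndarray
    theta_g: float
    alpha_g: float
    beta: float
    s_theta: float
    s_alpha: float

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.theta.shape != self.alpha.shape:
            raise ValueError(
                f"theta and alpha must have equal length, got "
                f"{self.theta.shape} vs {self.alpha.shape}"
            )

    @property
    def n_studies(self) -> int:
        return self.theta.size


@dataclass
class PriorConfig:
    """Truncation limits for the non-informative priors.

    sd_upper: upper bound of Uniform(0, sd_upper) on s_theta and s_alpha
    (default +inf).  hypermean_halfwidth: the flat priors on Theta, Lambda
    and beta are restricted to [-halfwidth, +halfwidth] when finite
    (default: improper flat on the whole line).
    """

    sd_upper: float = math.inf
    hypermean_halfwidth: float = math.inf

    def __post_init__(self) -> None:
        if not self.sd_upper > 0:
            raise ValueError("sd_upper must be positive")
        if not self.hypermean_halfwidth > 0:
            raise ValueError("hypermean_halfwidth must be positive")


def study_probabilities(theta_i, alpha_i, beta):
    """True- and false-positive probabilities (pi1, pi0) of one study.

    Accepts scalars or broadcastable arrays; all inputs must be finite.
    """
    theta_i = np.asarray(theta_i, dtype=float)
    alpha_i = np.asarray(alpha_i, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(theta_i)) and np.all(np.isfinite(alpha_i))
            and np.all(np.isfinite(beta))):
        raise ValueError("study_probabilities requires finite inputs")
    half = np.exp(-beta / 2.0)
    pi1 = expit((theta_i + alpha_i / 2.0) * half)
    pi0 = expit((theta_i - alpha_i / 2.0) / half)
    if pi1.ndim == 0:
        return float(pi1), float(pi0)
    return pi1, pi0


def _check_dims(d: DTADataset, p: HSROCParams) -> None:
    if p.n_studies != len(d):
        raise ValueError(
            f"parameter vectors have length {p.n_studies} but dataset has {len(d)} studies"
        )


def log_likelihood(d: DTADataset, p: HSROCParams) -> float:
    """Binomial log-likelihood of the 2x2 counts given one parameter state."""
    _check_dims(d, p)
    tp = np.array([s.tp for s in d])
    n1 = np.array([s.n_diseased for s in d])
    fp = np.array([s.fp for s in d])
    n0 = np.array([s.n_nondiseased for s in d])
    pi1, pi0 = study_probabilities(p.theta, p.alpha, p.beta)
    ll = stats.binom.logpmf(tp, n1, pi1).sum() + stats.binom.logpmf(fp, n0, pi0).sum()
    return float(ll)


def log_prior(p: HSROCParams, c: PriorConfig | None = None) -> float:
    """Log density (up to a constant) of the truncated flat priors.

    Returns 0 inside the support and -inf outside; -inf is the only way an
    invalid state (negative SD, out-of-bounds hyper-parameter) is signalled.
    """
    c = c or PriorConfig()
    if p.s_theta < 0 or p.s_alpha < 0:
        return -math.inf
    if p.s_theta > c.sd_upper or p.s_alpha > c.sd_upper:
        return -math.inf
    h = c.hypermean_halfwidth
    if math.isfinite(h):
        for v in (p.theta_g, p.alpha_g, p.beta):
            if abs(v) > h:
                return -math.inf
    return 0.0


def log_posterior(d: DTADataset, p: HSROCParams, c: PriorConfig | None = None) -> float:
    """Unnormalised log posterior: likelihood + hierarchy + prior.

    The hierarchy contributes log N(theta_i | Theta, s_theta^2) and
    log N(alpha_i | Lambda, s_alpha^2) per study.  An SD of exactly zero is
    treated as degenerate and yields -inf.
    """
    lp = log_prior(p, c)
    if lp == -math.inf:
        return -math.inf
    if p.s_theta == 0.0 or p.s_alpha == 0.0:
        return -math.inf
    hier = (
        stats.norm.logpdf(p.theta, loc=p.theta_g, scale=p.s_theta).sum()
        + stats.norm.logpdf(p.alpha, loc=p.alpha_g, scale=p.s_alpha).sum()
    )
    return float(log_likelihood(d, p) + hier + lp)


def simulate_dataset(
    p_hyper: tuple[float, float, float, float, float],
    n_studies: int,
    n_diseased: int,
    n_nondiseased: int,
    seed: int,
) -> DTADataset:
    """Draw a synthetic dataset from the generative model.

    p_hyper is (Theta, Lambda, beta, s_theta, s_alpha).  Study parameters are
    drawn from the hyper-normals and counts from the two binomials.  A group
    that comes out empty of events keeps its invariants because group sizes
    are >= 1 by precondition.
    """
    theta_g, alpha_g, beta, s_theta, s_alpha = (float(v) for v in p_hyper)
    if n_studies < 1 or n_diseased < 1 or n_nondiseased < 1:
        raise ValueError("n_studies and group sizes must be >= 1")
    if s_theta < 0 or s_alpha < 0:
        raise ValueError("hyper-SDs must be >= 0")
    rng = np.random.default_rng(seed)
    theta = rng.normal(theta_g, s_theta, size=n_studies)
    alpha = rng.normal(alpha_g, s_alpha, size=n_studies)
    pi1, pi0 = study_probabilities(theta, alpha, beta)
    tp = rng.binomial(n_diseased, pi1)
    fp = rng.binomial(n_nondiseased, pi0)
    records = [
        StudyRecord(
            study_name=str(i + 1),
            tp=int(tp[i]),
            fn=int(n_diseased - tp[i]),
            fp=int(fp[i]),
            tn=int(n_nondiseased - fp[i]),
        )
        for i in range(n_studies)
    ]
    return DTADataset(records)
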