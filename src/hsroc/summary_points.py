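"""Summary points: the accuracy measure left free when the other is fixed.

The summary ROC curve implied by the accuracy hyper-mean Lambda and the
shape parameter beta is

    logit(sens) = Lambda * exp(-beta/2) + exp(-beta) * logit(1 - spec)

Fixing specificity (say at the median reported by the included studies)
yields a posterior distribution of sensitivity by pushing each retained
draw of (Lambda, beta) through the curve; the headline output is its
posterior mean and central 95% credible interval.  Per-study analogues use
that study's accuracy parameter alpha_i in place of Lambda.  The hyper-mean
based quantity carries the label ``other_snsp <N+1>`` (a.k.a.
``other_snsp[max]``), which is also the quantity whose convergence the user
must check before interpreting anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .model import study_probabilities
from .sampler import PosteriorDraws

__all__ = [
    "FixedTarget",
    "SummaryPoint",
    "sens_at_spec",
    "spec_at_sens",
    "derived_quantities",
    "summary_point",
    "other_snsp_max_label",
]

_MEASURES = {"sensitivity", "specificity"}
_ALIASES = {"sens": "sensitivity", "sn": "sensitivity",
            "spec": "specificity", "sp": "specificity"}


@dataclass(frozen=True)
class FixedTarget:
    """Which accuracy measure the user fixes, and at what value."""

    fixed_measure: str
    value: float

    def __post_init__(self) -> None:
        measure = _ALIASES.get(self.fixed_measure, self.fixed_measure)
        object.__setattr__(self, "fixed_measure", measure)
        if measure not in _MEASURES:
            raise ValueError(
                f"fixed_measure must be 'sensitivity' or 'specificity', got {self.fixed_measure!r}"
            )
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"fixed value must be in (0, 1), got {self.value}")

    @property
    def free_measure(self) -> str:
        return "specificity" if self.fixed_measure == "sensitivity" else "sensitivity"


@dataclass(frozen=True)
class SummaryPoint:
    """Posterior mean and central 95% CrI of the non-fixed measure."""

    measure: str
    estimate: float
    cri_low: float
    cri_high: float

    def __post_init__(self) -> None:
        if not (self.cri_low <= self.cri_high):
            raise ValueError("credible interval endpoints out of order")
        if not (0.0 < self.estimate < 1.0):
            raise ValueError("estimate must be a probability in (0, 1)")

    def __str__(self) -> str:
        return (f"{self.measure}: {self.estimate:.3f} "
                f"(95% CrI {self.cri_low:.3f} to {self.cri_high:.3f})")


def sens_at_spec(Lambda, beta, spec):
    """Sensitivity on the summary ROC curve at a fixed specificity."""
    spec = np.asarray(spec, dtype=float)
    if np.any(spec <= 0.0) or np.any(spec >= 1.0):
        raise ValueError("spec must lie strictly in (0, 1)")
    Lambda = np.asarray(Lambda, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = expit(Lambda * np.exp(-beta / 2.0) + np.exp(-beta) * logit(1.0 - spec))
    return float(out) if out.ndim == 0 else out


def spec_at_sens(Lambda, beta, sens):
    """Specificity on the summary ROC curve at a fixed sensitivity (exact inverse)."""
    sens = np.asarray(sens, dtype=float)
    if np.any(sens <= 0.0) or np.any(sens >= 1.0):
        raise ValueError("sens must lie strictly in (0, 1)")
    Lambda = np.asarray(Lambda, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = 1.0 - expit(np.exp(beta) * (logit(sens) - Lambda * np.exp(-beta / 2.0)))
    return float(out) if out.ndim == 0 else out


def other_snsp_max_label(n_studies: int) -> str:
    """Label of the hyper-mean-based summary quantity ('other_snsp[max]')."""
    return f"other_snsp {n_studies + 1}"


def _n_studies(draws: PosteriorDraws) -> int:
    n = 0
    while f"theta {n + 1}" in draws:
        n += 1
    if n == 0:
        raise ValueError("draws do not contain per-study theta parameters")
    return n


def derived_quantities(draws: PosteriorDraws, target: FixedTarget) -> PosteriorDraws:
    """Append pi, sn, sp and other_snsp draws per retained state.

    For each study i: pi_1_i and pi_0_i are the model true/false-positive
    probabilities, sn_i = pi_1_i, sp_i = 1 - pi_0_i, and other_snsp_i is the
    non-fixed measure at the fixed value computed from (alpha_i, beta).  The
    extra element other_snsp_{N+1} uses the hyper-mean Lambda (alpha_g)
    instead and is the headline summary quantity.
    """
    for needed in ("beta", "alpha_g"):
        if needed not in draws:
            raise ValueError(f"draws are missing monitored quantity {needed!r}")
    n = _n_studies(draws)
    beta = draws.get("beta")
    alpha_g = draws.get("alpha_g")

    theta = np.stack([draws.get(f"theta {i + 1}") for i in range(n)], axis=-1)
    alpha = np.stack([draws.get(f"alpha {i + 1}") for i in range(n)], axis=-1)
    pi1, pi0 = study_probabilities(theta, alpha, beta[..., None])

    if target.fixed_measure == "specificity":
        transform = lambda lam: sens_at_spec(lam, beta if lam.ndim == 2 else beta[..., None], target.value)
    else:
        transform = lambda lam: spec_at_sens(lam, beta if lam.ndim == 2 else beta[..., None], target.value)
    other_per_study = transform(alpha)          # (chain, draw, study)
    other_max = transform(alpha_g)              # (chain, draw)

    names = (
        [f"pi_1_{i + 1}" for i in range(n)]
        + [f"pi_0_{i + 1}" for i in range(n)]
        + [f"sn {i + 1}" for i in range(n)]
        + [f"sp {i + 1}" for i in range(n)]
        + [f"other_snsp {i + 1}" for i in range(n)]
        + [other_snsp_max_label(n)]
    )
    values = np.concatenate(
        [pi1, pi0, pi1, 1.0 - pi0, other_per_study, other_max[..., None]], axis=2
    )
    return draws.with_quantities(names, values)


def summary_point(draws: PosteriorDraws, target: FixedTarget) -> SummaryPoint:
    """The headline estimate: pooled mean and 95% CrI of other_snsp[max]."""
    label = other_snsp_max_label(_n_studies(draws))
    if label not in draws:
        raise ValueError(
            f"draws lack {label!r}; run derived_quantities (or pass target to run_mcmc) first"
        )
    pooled = draws.pooled(label)
    low, high = np.quantile(pooled, [0.025, 0.975])
    return SummaryPoint(
        measure=target.free_measure,
        estimate=float(pooled.mean()),
        cri_low=float(low),
        cri_high=float(high),
    )
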