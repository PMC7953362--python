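"""MCMC summary statistics and convergence checks.

Implements the classic (pre-rank-normalization) Stan estimators: split-R-hat
and the autocorrelation-based effective sample size with Geyer's initial
monotone truncation.  The summary table mirrors the layout users of RStan's
``print`` output expect: mean, Monte-Carlo standard error, sd, the 2.5/25/
50/75/97.5 percent quantiles, n_eff and R-hat per monitored quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = [
    "SummaryRow",
    "SummaryTable",
    "ConvergenceReport",
    "split_rhat",
    "effective_sample_size",
    "summarize",
    "check_convergence",
]

#: CSV/display header, fixed by the RStan summary layout.
TABLE_COLUMNS = ["Statistics", "Mean", "se_mean", "sd",
                 "X2.5.", "X25.", "X50.", "X75.", "X97.5.", "n_eff", "Rhat"]


@dataclass(frozen=True)
class SummaryRow:
    name: str
    mean: float
    se_mean: float
    sd: float
    q2_5: float
    q25: float
    q50: float
    q75: float
    q97_5: float
    n_eff: float
    rhat: float

    def as_list(self) -> list:
        return [self.name, self.mean, self.se_mean, self.sd,
                self.q2_5, self.q25, self.q50, self.q75, self.q97_5,
                self.n_eff, self.rhat]


@dataclass
class SummaryTable:
    rows: list[SummaryRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, name: str) -> SummaryRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(f"no summary row named {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_list() for r in self.rows], columns=TABLE_COLUMNS)


@dataclass
class ConvergenceReport:
    converged: bool
    offending: list[tuple[str, float]]
    threshold: float = 1.1

    def __str__(self) -> str:
        if self.converged:
            return f"Converged: all split-Rhat <= {self.threshold}"
        worst = ", ".join(f"{n} (Rhat={r:.4f})" for n, r in self.offending)
        return (f"NOT converged: split-Rhat > {self.threshold} for {worst}. "
                "Do not interpret the results; check the trace plots.")


def _check_shape(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    if x.shape[0] < 2:
        raise ValueError("split-Rhat / ESS require at least 2 chains")
    if x.shape[1] < 4:
        raise ValueError("at least 4 draws per chain are required")
    return x


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half; R-hat compares between- and within-half-chain
    variance over the resulting 2m half-chains.  Returns NaN when the draws
    are constant (zero within variance).
    """
    x = _check_shape(x)
    if np.ptp(x) == 0.0:
        return math.nan
    n_half = x.shape[1] // 2
    halves = np.concatenate([x[:, :n_half], x[:, n_half:2 * n_half]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0.0 or not math.isfinite(w):
        return math.nan
    b_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (n_half - 1) / n_half * w + b_over_n
    return float(math.sqrt(var_plus / w))


def _autocovariances(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance of each row via FFT."""
    m, n = x.shape
    centered = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=size, axis=1)[:, :n].real
    return acov / n


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size (Geyer truncation).

    n_eff = m*n / (1 + 2 * sum rho_t) with chain-averaged autocorrelations;
    the sum is truncated where consecutive paired sums first go negative and
    forced monotone non-increasing.  Returns NaN for constant draws.
    """
    x = _check_shape(x)
    if np.ptp(x) == 0.0:
        return math.nan
    m, n = x.shape
    acov = _autocovariances(x)
    chain_var = acov[:, 0] * n / (n - 1)
    w = chain_var.mean()
    if w == 0.0 or not math.isfinite(w):
        return math.nan
    var_plus = w * (n - 1) / n + x.mean(axis=1).var(ddof=1)

    rho = 1.0 - (w - acov.mean(axis=0) * n / (n - 1)) / var_plus
    rho[0] = 1.0

    # Geyer initial positive + monotone sequence over paired sums
    # P_k = rho_{2k} + rho_{2k+1}; keep while positive, force non-increasing
    pair_sums: list[float] = []
    k = 0
    while 2 * k + 1 < n:
        p = rho[2 * k] + rho[2 * k + 1]
        if p <= 0.0:
            break
        if pair_sums and p > pair_sums[-1]:
            p = pair_sums[-1]
        pair_sums.append(float(p))
        k += 1
    tau = -1.0 + 2.0 * sum(pair_sums)
    # guard against pathological anti-correlation (Stan uses the same floor)
    tau = max(tau, 1.0 / math.log10(m * n + 10.0))
    return float(m * n / tau)


def summarize(draws: PosteriorDraws) -> SummaryTable:
    """One summary row per monitored quantity, in monitored order.

    Means, SDs and quantiles are computed on the draws pooled across chains
    (quantiles by linear interpolation of order statistics); n_eff and
    split-R-hat from the per-chain structure; se_mean = sd / sqrt(n_eff).
    """
    if draws.n_draws == 0:
        raise ValueError("cannot summarize an empty draws object")
    rows = []
    for name in draws.names:
        x = draws.get(name)
        pooled = x.reshape(-1)
        q = np.quantile(pooled, [0.025, 0.25, 0.5, 0.75, 0.975])
        sd = float(pooled.std(ddof=1))
        n_eff = effective_sample_size(x)
        se = sd / math.sqrt(n_eff) if (n_eff and not math.isnan(n_eff)) else math.nan
        rows.append(SummaryRow(
            name=name, mean=float(pooled.mean()), se_mean=se, sd=sd,
            q2_5=float(q[0]), q25=float(q[1]), q50=float(q[2]),
            q75=float(q[3]), q97_5=float(q[4]),
            n_eff=n_eff, rhat=split_rhat(x),
        ))
    return SummaryTable(rows)


def check_convergence(t: SummaryTable, threshold: float = 1.1) -> ConvergenceReport:
    """Apply the usage rule: every finite split-R-hat must be <= threshold.

    NaN R-hat rows (constant draws) are excluded from the maximum but
    reported with a warning.
    """
    offending = []
    nan_rows = []
    for r in t:
        if math.isnan(r.rhat):
            nan_rows.append(r.name)
        elif r.rhat > threshold:
            offending.append((r.name, r.rhat))
    if nan_rows:
        warnings.warn(
            f"R-hat undefined (constant draws) for: {nan_rows}", RuntimeWarning,
            stacklevel=2,
        )
    return ConvergenceReport(converged=not offending, offending=offending,
                             threshold=threshold)
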