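"""Output artifacts: density plot, trace plot, summary CSV, SoF row."""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .diagnostics import TABLE_COLUMNS, SummaryTable
from .sampler import PosteriorDraws
from .summary_points import FixedTarget, SummaryPoint

__all__ = ["PlotSpec", "density_plot", "trace_plot", "export_mcmc_csv", "sof_row"]


@dataclass
class PlotSpec:
    quantity: str
    output_path: Union[str, os.PathLike]
    title: Optional[str] = None
    xlabel: Optional[str] = None
    ylabel: Optional[str] = None


def _check_quantity(draws: PosteriorDraws, spec: PlotSpec) -> None:
    if spec.quantity not in draws:
        raise ValueError(f"no monitored quantity named {spec.quantity!r}")


def density_plot(draws: PosteriorDraws, spec: PlotSpec) -> plt.Figure:
    """Write a filled kernel-density plot of the pooled draws as PNG.

    Probability-scale quantities (all draws inside (0,1)) get a (0,1) x-axis.
    Constant draws degrade gracefully to a vertical marker line.  Returns the
    figure (also saved to ``spec.output_path``) so callers can inspect the
    plotted series.
    """
    _check_quantity(draws, spec)
    x = draws.pooled(spec.quantity)
    if x.size < 100:
        raise ValueError("density plot requires at least 100 draws")
    fig, ax = plt.subplots(figsize=(6, 4))
    if np.ptp(x) == 0.0:
        ax.axvline(x[0], color="C0")
        ax.set_title(spec.title or f"{spec.quantity} (constant draws)")
    else:
        kde = stats.gaussian_kde(x)  # Silverman-type rule-of-thumb bandwidth
        lo, hi = x.min(), x.max()
        pad = 0.05 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, 512)
        dens = kde(grid)
        ax.plot(grid, dens, color="C0")
        ax.fill_between(grid, dens, alpha=0.4, color="C0")
        ax.set_title(spec.title or f"Posterior density of {spec.quantity}")
    if np.all((x > 0.0) & (x < 1.0)):
        ax.set_xlim(0.0, 1.0)
    ax.set_xlabel(spec.xlabel or spec.quantity)
    ax.set_ylabel(spec.ylabel or "prob density")
    fig.savefig(spec.output_path, dpi=100)
    plt.close(fig)
    return fig


def trace_plot(draws: PosteriorDraws, spec: PlotSpec) -> plt.Figure:
    """Write a per-chain trace plot of the post-warmup draws as PNG."""
    _check_quantity(draws, spec)
    x = draws.get(spec.quantity)
    fig, ax = plt.subplots(figsize=(7, 4))
    for c in range(x.shape[0]):
        ax.plot(np.arange(1, x.shape[1] + 1), x[c], lw=0.7, label=f"chain {c + 1}")
    ax.set_xlabel(spec.xlabel or "post-warmup iteration")
    ax.set_ylabel(spec.ylabel or spec.quantity)
    ax.set_title(spec.title or f"Trace of {spec.quantity}")
    ax.legend(loc="upper right", fontsize="small")
    fig.savefig(spec.output_path, dpi=100)
    plt.close(fig)
    return fig


def export_mcmc_csv(t: SummaryTable, path: Union[str, os.PathLike]) -> Path:
    """Write the summary table as CSV with the standard column headers.

    Values are written at full repr precision, so a re-read reproduces the
    in-memory table exactly.
    """
    if len(t) == 0:
        raise ValueError("cannot export an empty summary table")
    frame = t.to_dataframe()
    assert list(frame.columns) == TABLE_COLUMNS
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def sof_row(
    sp: SummaryPoint,
    target: FixedTarget,
    n_per_1000: int = 1000,
    prevalence: Optional[float] = None,
) -> str:
    """A quantitative summary-of-findings line for a DTA review table.

    With a prevalence, the expected true/false positive/negative counts per
    ``n_per_1000`` patients are appended, computed from the estimated and
    fixed accuracy measures.
    """
    lines = [
        f"Fixed {target.fixed_measure}: {target.value:.3f}",
        f"Estimated {sp.measure}: {sp.estimate:.3f} "
        f"[95% CrI {sp.cri_low:.3f} to {sp.cri_high:.3f}]",
    ]
    if prevalence is not None:
        if not 0.0 < prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
        if sp.measure == "sensitivity":
            sens, spec = sp.estimate, target.value
        else:
            sens, spec = target.value, sp.estimate
        n_dis = n_per_1000 * prevalence
        n_non = n_per_1000 - n_dis
        tp = round(n_dis * sens)
        fn = round(n_dis) - tp
        tn = round(n_non * spec)
        fp = round(n_non) - tn
        lines.append(
            f"Per {n_per_1000} patients (prevalence {prevalence:.3f}): "
            f"TP={tp}, FN={fn}, TN={tn}, FP={fp}"
        )
    return "\n".join(lines)
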