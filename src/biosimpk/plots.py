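"""Diagnostic figures (goodness of fit, eta panels, VPC bands).

All functions take an output path and write PNG via the Agg backend; they
return the path for report cross-linking.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .model_qualification import VPCResult  # noqa: E402
from .nlme_engine import FitResult  # noqa: E402

__all__ = ["plot_gof", "plot_eta", "plot_eta_covariates", "plot_vpc"]


def plot_gof(residuals: pd.DataFrame, path: str | Path) -> Path:
    """Observed vs predicted (log scale) and CWRES vs time / prediction."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, pred in zip(axes[0], ("PRED", "IPRED")):
        ax.loglog(residuals[pred], residuals["DV"], ".", ms=3, alpha=0.4)
        lim = [min(residuals[pred].min(), residuals["DV"].min()),
               max(residuals[pred].max(), residuals["DV"].max())]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(f"{pred} (mg/L)")
        ax.set_ylabel("observed (mg/L)")
    for ax, (x, label) in zip(
        axes[1], [("TIME", "time (h)"), ("PRED", "population prediction (mg/L)")]
    ):
        ax.plot(residuals[x], residuals["CWRES"], ".", ms=3, alpha=0.4)
        ax.axhline(0.0, color="k", lw=1)
        ax.set_xlabel(label)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_eta(fit: FitResult, path: str | Path) -> Path:
    """Histograms of the empirical Bayes etas."""
    cols = [c for c in fit.eta.columns if c.startswith("eta_")]
    fig, axes = plt.subplots(1, max(len(cols), 1), figsize=(4 * max(len(cols), 1), 3.2))
    axes = np.atleast_1d(axes)
    for ax, c in zip(axes, cols):
        ax.hist(fit.eta[c], bins=30, color="steelblue", alpha=0.8)
        ax.axvline(0.0, color="k", lw=1)
        ax.set_xlabel(c)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_eta_covariates(
    fit: FitResult, covariates: pd.DataFrame, names: list[str], path: str | Path
) -> Path:
    """Eta vs covariate panels (scatter for continuous, box for categorical)."""
    cols = [c for c in fit.eta.columns if c.startswith("eta_")]
    covs = covariates.set_index("ID").loc[fit.eta["ID"]]
    fig, axes = plt.subplots(
        len(cols), len(names), figsize=(3.2 * len(names), 3.0 * len(cols)),
        squeeze=False,
    )
    for i, ec in enumerate(cols):
        eta = fit.eta[ec].to_numpy()
        for j, name in enumerate(names):
            ax = axes[i][j]
            x = covs[name].to_numpy(dtype=float)
            if len(np.unique(x)) <= 6:
                levels = np.unique(x)
                ax.boxplot([eta[x == lv] for lv in levels],
                           tick_labels=[f"{lv:g}" for lv in levels])
            else:
                ax.plot(x, eta, ".", ms=3, alpha=0.5)
            ax.axhline(0.0, color="k", lw=0.8)
            if i == len(cols) - 1:
                ax.set_xlabel(name)
            if j == 0:
                ax.set_ylabel(ec)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_vpc(result: VPCResult, path: str | Path, logy: bool = True) -> Path:
    """Observed percentiles over simulated percentile CIs per bin."""
    t = result.table
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(max(7, 0.5 * len(t)), 4.5))
    for tag, color in (("lo", "lightblue"), ("med", "pink"), ("hi", "lightblue")):
        ax.fill_between(
            x, t[f"sim_{tag}_lower"], t[f"sim_{tag}_upper"],
            color=color, alpha=0.6, lw=0,
        )
        ax.plot(x, t[f"sim_{tag}"], "k-", lw=1)
    ax.plot(x, t["obs_med"], "r-", lw=1.5, label="observed median")
    ax.plot(x, t["obs_lo"], "r--", lw=1, label="observed 2.5/97.5%")
    ax.plot(x, t["obs_hi"], "r--", lw=1)
    if logy:
        ax.set_yscale("log")
    ax.set_xticks(x)
    ax.set_xticklabels(t["bin"], rotation=90, fontsize=7)
    ax.set_ylabel("concentration (mg/L)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
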