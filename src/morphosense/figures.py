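"""Deterministic figure datasets: precision-vs-shape curves, the DT/SDC
precision-ratio crossover, and the morphogen classification band plot.

The tabular datasets are the contract; rendering a plot is optional
convenience (matplotlib, written to a file, never shown interactively).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .comparison import (MorphogenRecord, classify_morphogens,
                         fraction_sdc_better, lambda50, precision_ratio)
from .dt_model import DTShape, DTRates, precision_dt

__all__ = ["figure_data", "dt_precision_curves", "rho_crossover_curves",
           "classification_dataset"]

#: lengthscales whose P^2(phi) curves have interior maxima in the phi window
FIG3A_LAMBDAS = (1.0, 2.0, 5.0, 10.0, 20.0)


def dt_precision_curves(N: int = 100, j: int = 50,
                        lambdas: Sequence[float] = FIG3A_LAMBDAS,
                        n_phi: int = 200) -> pd.DataFrame:
    """DT squared precision P^2_j versus shape parameter phi, one curve per
    lengthscale (beta = T = nu = 1)."""
    phis = np.logspace(-3, np.log10(30.0), n_phi)
    rows = []
    rates = DTRates(beta=1.0, nu=1.0, T=30.0)  # T only rescales P^2
    for lam in lambdas:
        for phi in phis:
            shape = DTShape.from_lengthscale(float(phi), float(lam), N)
            p2 = precision_dt(shape, rates).p_squared[j - 1] / 30.0
            rows.append({"lambda_hat": lam, "phi": phi, "p_squared": p2})
    return pd.DataFrame(rows)


def rho_crossover_curves(N: int = 100, j: int = 50,
                         dims: Sequence[int] = (1, 2, 3),
                         lam_lo: float = 1.0, lam_hi: float = 100.0,
                         n_lam: int = 25) -> pd.DataFrame:
    """Precision ratio rho_j over a lengthscale grid for 1D/2D/3D geometry."""
    lams = np.logspace(np.log10(lam_lo), np.log10(lam_hi), n_lam)
    rows = []
    for dim in dims:
        for lam in lams:
            res = precision_ratio(N, float(lam), dim=dim)
            rows.append({"dim": dim, "lambda_hat": lam,
                         "rho": res.rho[j - 1],
                         "phi_star": res.phi_star[j - 1]})
    return pd.DataFrame(rows)


def classification_dataset(records: Iterable[MorphogenRecord],
                           dim: int = 1,
                           levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                           reference_N: int = 100) -> dict[str, pd.DataFrame]:
    """Per-record lambda_hat/lambda50 placement plus fraction-level contours.

    The contour table reports, for the reference system size, the
    lambda_hat/lambda50 values at which the fraction of SDC-favouring cells
    crosses each requested level (0 and 1 are reported as the last/first
    lengthscale attaining them on a log grid)."""
    annotated, summary = classify_morphogens(list(records), dim=dim)
    rec_df = pd.DataFrame([{
        "name": r.name, "species": r.species, "lambda_hat": r.lambda_hat,
        "lambda_hat_over_lambda50": r.lambda_hat_over_lambda50,
        "fraction_sdc": r.fraction_sdc, "evidence_class": r.evidence_class,
        "predicted": r.predicted, "provenance": r.provenance,
    } for r in annotated]).sort_values("lambda_hat_over_lambda50",
                                       ignore_index=True)
    l50 = lambda50(reference_N, dim)
    grid = np.logspace(np.log10(0.1), np.log10(1000.0), 40)
    fr = np.array([fraction_sdc_better(reference_N, float(l), dim)
                   for l in grid])
    rows = []
    for lev in levels:
        if lev <= 0.0:
            sel = grid[fr <= 0.0]
            lam = sel.max() if sel.size else np.nan
        elif lev >= 1.0:
            sel = grid[fr >= 1.0]
            lam = sel.min() if sel.size else np.nan
        else:
            above = np.flatnonzero(fr >= lev)
            if above.size and above[0] > 0:
                i = above[0]
                # log-linear interpolation between bracketing grid points
                f0, f1 = fr[i - 1], fr[i]
                w = (lev - f0) / (f1 - f0) if f1 > f0 else 0.0
                lam = np.exp(np.log(grid[i - 1])
                             + w * (np.log(grid[i]) - np.log(grid[i - 1])))
            else:
                lam = np.nan
        rows.append({"level": lev, "lambda_hat": lam,
                     "lambda_hat_over_lambda50": lam / l50})
    contours = pd.DataFrame(rows)
    meta = pd.DataFrame([{**summary, "reference_N": reference_N,
                          "lambda50_reference": l50}])
    return {"records": rec_df, "contours": contours, "summary": meta}


def figure_data(kind: str, *, records: Optional[Iterable[MorphogenRecord]] = None,
                plot_path: Optional[str | Path] = None, **kwargs):
    """Dispatch to one of the figure dataset builders.

    kind = "fig3a" (DT precision vs phi), "fig3b" (rho crossover curves) or
    "fig4b" (morphogen classification; requires ``records``).  If
    ``plot_path`` is given, a rendering is also written there.
    """
    if kind == "fig3a":
        data = dt_precision_curves(**kwargs)
    elif kind == "fig3b":
        data = rho_crossover_curves(**kwargs)
    elif kind == "fig4b":
        if records is None:
            raise ValueError("fig4b needs morphogen records")
        data = classification_dataset(records, **kwargs)
    else:
        raise ValueError(f"unknown figure kind {kind!r}")
    if plot_path is not None:
        _render(kind, data, Path(plot_path))
    return data


def _render(kind: str, data, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if kind == "fig3a":
        for lam, grp in data.groupby("lambda_hat"):
            ax.loglog(grp["phi"], grp["p_squared"], label=f"$\\hat\\lambda$={lam:g}")
        ax.set_xlabel(r"shape parameter $\phi$")
        ax.set_ylabel(r"$P_{DT}^2$ (per unit $\beta T$)")
        ax.legend(fontsize=8)
    elif kind == "fig3b":
        for dim, grp in data.groupby("dim"):
            ax.loglog(grp["lambda_hat"], grp["rho"], label=f"{dim}D")
        ax.axhline(1.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel(r"profile lengthscale $\lambda/a$")
        ax.set_ylabel(r"$\rho_j = P_{DT}^2 / P_{SDC}^2$")
        ax.legend(fontsize=8)
    else:
        rec = data["records"]
        colors = {"DT": "tab:red", "SDC": "tab:blue", "multiple": "0.7"}
        for _, r in rec.iterrows():
            ax.scatter(r["lambda_hat_over_lambda50"], 1.0,
                       color=colors[r["evidence_class"]], edgecolor="k",
                       zorder=3)
            ax.annotate(r["name"], (r["lambda_hat_over_lambda50"], 1.0),
                        textcoords="offset points", xytext=(0, 8),
                        rotation=60, fontsize=7)
        for _, c in data["contours"].iterrows():
            if np.isfinite(c["lambda_hat_over_lambda50"]):
                ax.axvline(c["lambda_hat_over_lambda50"], color="k",
                           ls=":" if c["level"] not in (0.5,) else "-",
                           lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel(r"$\hat\lambda / \hat\lambda_{50}$")
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
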