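"""Figure helpers: survival/hazard curves, RLS contour maps, ring charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import ContourGrid, tally_segregation_defects
from .survival import HazardCurve, SurvivalCurve, SurvivalFit


def survival_plot(curve: SurvivalCurve, fit: SurvivalFit | None, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(curve.generations, curve.survival, where="post", color="k",
            label=f"KM estimate (n={curve.n_total})")
    if fit is not None:
        g = np.linspace(0, curve.generations.max(), 200)
        ax.plot(g, fit.model.survival(g), "r-",
                label=f"{fit.model.kind} fit (RLS={fit.rls:.1f})")
    ax.axhline(0.5, ls="--", color="b", lw=0.8)
    ax.set_xlabel("generation")
    ax.set_ylabel("fraction surviving, S(g)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def hazard_plot(empirical: HazardCurve, fit: SurvivalFit | None, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(empirical.generations, empirical.hazard, "ko", ms=3,
            label="empirical (deaths / at-risk)")
    if fit is not None:
        g = np.linspace(0, empirical.generations.max(), 200)
        ax.plot(g, fit.model.hazard(g), "r-", label=f"{fit.model.kind} fit")
    ax.set_xlabel("generation")
    ax.set_ylabel("hazard per generation")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def contour_plot(grid: ContourGrid, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(grid.beta_values, grid.alpha_values, grid.rls_matrix,
                     levels=15, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="RLS (generations)")
    if grid.strain_points:
        for label, alpha, beta in grid.strain_points:
            ax.plot(beta, alpha, "r*", ms=10)
            ax.annotate(label, (beta, alpha), textcoords="offset points",
                        xytext=(4, 4), color="w", fontsize=8)
    ax.set_xlabel("beta (age-dependent rate)")
    ax.set_ylabel("alpha (age-independent hazard)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ring_chart(table, path) -> None:
    """Nested pie: overall (inner) vs terminal (outer) defect classes."""
    died = table[(table["status"] == "died")
                 & (table["defect_class"] != "none")]
    if len(died) == 0:
        return
    import pandas as pd

    events = pd.DataFrame({"population": "terminal",
                           "defect_class": died["defect_class"]})
    # terminal-only table: the inner ring repeats it so the chart renders
    events = pd.concat([events,
                        events.assign(population="all")], ignore_index=True)
    overall, terminal, _ = tally_segregation_defects(events)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    classes = list(overall.counts)
    cmap = plt.get_cmap("tab10")
    colors = [cmap(i) for i in range(len(classes))]
    ax.pie([overall.counts[c] for c in classes], radius=0.7, colors=colors,
           wedgeprops=dict(width=0.3, edgecolor="w"))
    ax.pie([terminal.counts[c] for c in classes], radius=1.0, colors=colors,
           labels=classes, wedgeprops=dict(width=0.3, edgecolor="w"))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
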