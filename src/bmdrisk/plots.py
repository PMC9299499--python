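"""Static plot output: fitted curves, BMDL-BMDU interval ladders, MOE zones."""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .models import DoseResponseDataset, predict_response


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_fit(
    dataset: DoseResponseDataset,
    fits: dict,
    path: str | Path,
    ces: float | None = None,
) -> None:
    """Observed responses and fitted curves per family, log-log axes."""
    plt = _mpl()
    fig, axes = plt.subplots(1, len(fits), figsize=(5 * len(fits), 4), squeeze=False)
    df = dataset.to_frame()
    positive = df[df["dose"] > 0]
    x_lo = positive["dose"].min() / 3 if len(positive) else 0.1
    x_hi = df["dose"].max() * 1.5
    grid = np.geomspace(x_lo, x_hi, 200)
    for ax, (family, fit) in zip(axes[0], fits.items()):
        for level in dataset.levels:
            sub = df[df["covariate_level"] == level]
            ycol = "response" if "response" in sub.columns else "mean"
            ax.scatter(sub["dose"].clip(lower=x_lo), sub[ycol], s=12, label=level, alpha=0.7)
            ax.plot(grid, predict_response(fit.params, level, grid), lw=1.5)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(f"dose ({dataset.units})")
        ax.set_ylabel(dataset.endpoint)
        ax.set_title(family)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bmd_intervals(estimates, path: str | Path) -> None:
    """BMDL-BMDU interval ladder per family and level (log dose axis)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(4, len(list(estimates)))))
    ests = list(estimates)
    labels = []
    for i, e in enumerate(ests):
        hi = e.bmdu if math.isfinite(e.bmdu) else e.bmdl * 1e3
        ax.plot([e.bmdl, hi], [i, i], lw=3)
        ax.plot([e.bmd], [i], "k|", ms=10)
        labels.append(f"{e.family}/{e.covariate_level}")
    ax.set_yticks(range(len(ests)), labels)
    ax.set_xscale("log")
    ax.set_xlabel("dose (mg/kg)")
    ax.set_title(f"BMDL{ests[0].ces * 100:g}-BMDU{ests[0].ces * 100:g} intervals")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_moe_zones(
    pod_hed: float,
    exposure_min: float,
    exposure_max: float,
    path: str | Path,
    lower: float = 3.0,
    upper: float = 10.0,
) -> None:
    """Linear zone diagram: exposure range against the PoD/10 and PoD/3 cut lines."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 2.2))
    top = max(exposure_max, pod_hed) * 1.2
    ax.axvspan(0, pod_hed / upper, color="tab:green", alpha=0.35)
    ax.axvspan(pod_hed / upper, pod_hed / lower, color="gold", alpha=0.45)
    ax.axvspan(pod_hed / lower, top, color="tab:red", alpha=0.30)
    ax.plot([exposure_min, exposure_max], [0.5, 0.5], "k-", lw=4)
    ax.annotate("exposure range", (exposure_min, 0.62), fontsize=9)
    ax.axvline(pod_hed, color="k", ls="--", lw=1)
    ax.annotate(f"PoD {pod_hed:g}", (pod_hed, 0.8), fontsize=9)
    ax.set_xlim(0, top)
    ax.set_yticks([])
    ax.set_xlabel("mg/m$^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
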