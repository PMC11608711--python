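"""Figures: tornado diagram, acceptability curves, survival overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import DigitizedCurve
from .config import RunConfig
from .fitting import SurvivalFit, survival_at
from .reconstruct import KMCurve


def tornado_plot(
    tornado: pd.DataFrame, comparison: str, path: str | Path, top: int = 12
) -> None:
    """Horizontal tornado bars for one comparison, widest at the top."""
    sub = tornado[tornado["comparison"] == comparison]
    sub = sub.sort_values("spread", ascending=False).head(top).iloc[::-1]
    base = tornado.attrs.get("base_icers", {}).get(comparison)
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(sub) + 1.5))
    y = np.arange(len(sub))
    lo = np.minimum(sub["icer_low"], sub["icer_high"])
    hi = np.maximum(sub["icer_low"], sub["icer_high"])
    ax.barh(y, hi - lo, left=lo, color="#4878b0", alpha=0.85)
    if base is not None:
        ax.axvline(base, color="k", lw=1, ls="--", label="base case")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_yticks(y, sub["parameter"], fontsize=8)
    ax.set_xlabel(f"ICER {comparison} vs reference ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(ceac_table: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for arm in [c for c in ceac_table.columns if c != "wtp"]:
        ax.plot(ceac_table["wtp"], ceac_table[arm], label=arm)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def survival_overlay(
    curve: DigitizedCurve,
    km: KMCurve,
    fits: list[SurvivalFit],
    config: RunConfig,
    path: str | Path,
    max_years: float | None = None,
) -> None:
    """Digitized coordinates, KM refit, and fitted models on one axis."""
    horizon = max_years or config.horizon_years
    t = np.linspace(0, horizon, 400)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.step(np.r_[0, km.step_times], np.r_[1, km.step_survival],
            where="post", color="k", lw=1.2, label="KM (reconstructed)")
    ax.plot(curve.times, curve.survival, ".", ms=3, color="gray",
            label="digitized")
    for f in fits:
        ax.plot(t, survival_at(f, t), lw=1, alpha=0.8, label=f.label)
    ax.set_xlabel("Years")
    ax.set_ylabel("Survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{curve.arm} {curve.endpoint}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
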