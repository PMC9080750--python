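"""Report figures: pause-by-outcome and per-bat attack accumulation.

Colours come from a colourblind-safe palette.  The accumulation figure's
colour scale is anchored at the reference pause lengths 114 / 153 / 200 ms
(failed / dropped / captured) so panels from different runs are comparable.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["fig_pause_by_outcome", "fig_attack_accumulation", "make_figures"]

REFERENCE_PAUSES_MS = {"failed": 114, "dropped": 153, "captured": 200}
_PALETTE = {"captured": "#0072B2", "dropped": "#E69F00", "failed": "#CC79A7"}


def fig_pause_by_outcome(attacks, means=None):
    """Box plots of measured pauses per outcome, model means/CIs overlaid.

    ``attacks`` needs ``outcome`` and ``pause_ms`` columns; ``means`` is the
    estimated-means table (level, mean, ci_low, ci_high) if a model was fit.
    Returns the Figure, or None (with a warning) if no outcome labels exist.
    """
    attacks = pd.DataFrame(attacks)
    data = attacks.dropna(subset=["pause_ms"])
    data = data[data["outcome"].isin(_PALETTE)]
    if data.empty:
        warnings.warn("no labelled attacks: skipping the pause-by-outcome figure")
        return None
    levels = [o for o in ("captured", "dropped", "failed") if (data["outcome"] == o).any()]
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = [data.loc[data["outcome"] == o, "pause_ms"].astype(float) for o in levels]
    box = ax.boxplot(groups, tick_labels=levels, patch_artist=True, widths=0.55)
    for patch, lev in zip(box["boxes"], levels):
        patch.set_facecolor(_PALETTE[lev])
        patch.set_alpha(0.45)
    if means is not None:
        means = pd.DataFrame(means).set_index("level")
        for i, lev in enumerate(levels, start=1):
            if lev in means.index:
                row = means.loc[lev]
                ax.errorbar(
                    i, row["mean"],
                    yerr=[[row["mean"] - row["ci_low"]], [row["ci_high"] - row["mean"]]],
                    fmt="o", color="black", capsize=4, zorder=5,
                )
    ax.set_xlabel("attack outcome")
    ax.set_ylabel("post-buzz pause (ms)")
    fig.tight_layout()
    return fig


def fig_attack_accumulation(attacks):
    """Per-bat cumulative attack count over the bout, pause colour-coded.

    Attacks are ordered in time (attack_idx, falling back to table order);
    each bat's trace is a monotone staircase; marker colour encodes the
    measured pause on a scale anchored at the 114/153/200 ms references.
    Returns the Figure, or None if the table is empty.
    """
    attacks = pd.DataFrame(attacks)
    if attacks.empty:
        warnings.warn("empty attack table: skipping the accumulation figure")
        return None
    attacks = attacks.copy()
    if "attack_idx" not in attacks:
        attacks["attack_idx"] = np.arange(len(attacks))
    order_col = "attack_idx"
    fig, ax = plt.subplots(figsize=(6, 4))
    refs = sorted(REFERENCE_PAUSES_MS.values())
    norm = plt.Normalize(vmin=refs[0] - 40, vmax=refs[-1] + 40)
    cmap = plt.get_cmap("viridis")
    for bat, sub in attacks.groupby("bat_id"):
        sub = sub.sort_values(order_col)
        x = sub[order_col].to_numpy(float)
        y = np.arange(1, len(sub) + 1)
        ax.step(x, y, where="post", lw=1.0, alpha=0.6, label=str(bat))
        pauses = pd.to_numeric(sub["pause_ms"], errors="coerce").to_numpy(float)
        ax.scatter(x, y, c=cmap(norm(pauses)), edgecolor="k", zorder=5, s=30)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    cbar = fig.colorbar(sm, ax=ax, label="post-buzz pause (ms)")
    for name, ref in REFERENCE_PAUSES_MS.items():
        cbar.ax.axhline(ref, color="w", lw=1.2)
        cbar.ax.text(1.5, ref, f" {name} ({ref})", va="center", fontsize=7,
                     transform=cbar.ax.get_yaxis_transform())
    ax.set_xlabel("attack order")
    ax.set_ylabel("cumulative attacks per bat")
    if attacks["bat_id"].nunique() <= 8:
        ax.legend(fontsize=7, title="bat")
    fig.tight_layout()
    return fig


def make_figures(attacks, means=None, out_dir=None, formats=("png", "svg")):
    """Build both report figures; optionally write them under ``out_dir``.

    Returns {name: Figure}; a figure that cannot be drawn (e.g. no outcome
    labels) is skipped with a warning, the other still produced.
    """
    figs = {}
    f1 = fig_pause_by_outcome(attacks, means=means)
    if f1 is not None:
        figs["pause_by_outcome"] = f1
    f2 = fig_attack_accumulation(attacks)
    if f2 is not None:
        figs["attack_accumulation"] = f2
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fig in figs.items():
            for fmt in formats:
                fig.savefig(out / f"{name}.{fmt}", dpi=150)
    return figs
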