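"""Minimal figures: PCA biplot and observed-vs-predicted Ho scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def pca_biplot(pca, table, path: str | Path) -> None:
    """Scores on the first two components with variable loading arrows."""
    fig, ax = plt.subplots(figsize=(6, 5))
    scores = pca.scores
    ins = table.meta["insularity"].to_numpy()
    for group, color in (("mainland", "tab:blue"), ("island", "tab:red")):
        sel = ins == group
        if sel.any():
            ax.scatter(scores[sel, 0], scores[sel, 1], s=18, alpha=0.7,
                       color=color, label=group)
    scale = 0.8 * np.abs(scores[:, :2]).max() if len(scores) else 1.0
    for var, row in pca.loadings.iloc[:, :2].iterrows():
        ax.annotate(var, xy=(0, 0), xytext=(row.iloc[0] * scale, row.iloc[1] * scale),
                    arrowprops=dict(arrowstyle="<-", color="gray", lw=0.8),
                    fontsize=7, color="gray")
    ax.set_xlabel(f"PC1 ({pca.explained[0]:.1%})")
    ax.set_ylabel(f"PC2 ({pca.explained[1]:.1%})")
    ax.legend(frameon=False, fontsize=8)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def obs_vs_pred(observed, predicted, r2, p, path: str | Path) -> None:
    """Jackknife predicted vs observed Ho with the least-squares line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(predicted, observed, s=18, alpha=0.7)
    if np.isfinite(r2) and np.ptp(predicted) > 0:
        coeffs = np.polyfit(predicted, observed, 1)
        xs = np.linspace(min(predicted), max(predicted), 10)
        ax.plot(xs, np.polyval(coeffs, xs), color="tab:red", lw=1)
        ax.set_title(f"R² = {r2:.3f}, p = {p:.2g}", fontsize=9)
    ax.set_xlabel("predicted Ho (jackknife)")
    ax.set_ylabel("observed Ho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
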