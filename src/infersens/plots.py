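"""Diagnostic figures: feature-contribution maps and Bland-Altman plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import BlandAltman
from .importance import ContributionSet, goodness_of_visualization


def contribution_plot(cs: ContributionSet, feature: str, feature_values, path,
                      normative_band: float = 2.0):
    """Scatter of a feature's contribution (dB) vs its z-score value.

    The y-axis is inverted so that sensitivity loss plots downwards; dashed
    lines mark the normal range (+- ``normative_band`` normative SD).  The
    panel title carries the goodness-of-visualization R^2.
    """
    x = np.asarray(feature_values, dtype=float)
    c = cs.contributions[feature].to_numpy()
    r2 = goodness_of_visualization(c, x)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.scatter(x, c, s=6, alpha=0.25, linewidths=0)
    for b in (-normative_band, normative_band):
        ax.axvline(b, ls="--", c="grey", lw=0.8)
    ax.invert_yaxis()
    ax.set_xlabel(f"{feature} (normative SD)")
    ax.set_ylabel("feature contribution (dB)")
    ax.set_title(f"{feature}  (R$^2$ = {r2:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return r2


def bland_altman_plot(pairs, ba: BlandAltman, path):
    """Difference-vs-mean plot with mean difference, 95% limits of agreement
    and their confidence intervals."""
    v1 = pairs.value1.to_numpy(dtype=float)
    v2 = pairs.value2.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    ax.scatter((v1 + v2) / 2, v1 - v2, s=6, alpha=0.25, linewidths=0)
    ax.axhline(ba.mean_diff, color="red")
    for lo in (ba.loa_low, ba.loa_high):
        ax.axhline(lo, color="red", ls="--")
    for ci in (ba.mean_diff_ci, ba.loa_low_ci, ba.loa_high_ci):
        for v in ci:
            ax.axhline(v, color="red", ls=":", lw=0.6, alpha=0.6)
    ax.set_xlabel("mean of pair (dB)")
    ax.set_ylabel("difference (dB)")
    ax.set_title(f"Bland-Altman ({ba.mode})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
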