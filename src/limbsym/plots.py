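"""Plotting helpers for symmetry-score tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_scores(scores: pd.DataFrame, metric: str = "combined", ax=None):
    """Strip plot of one score column by group, mean ± SEM overlaid.

    Windows cut from the same sample share an x-offset within their group,
    making within-limb clustering visible.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * scores["group"].nunique() + 1, 3.2))
    groups = list(dict.fromkeys(scores["group"]))
    for gi, g in enumerate(groups):
        sub = scores[scores["group"] == g]
        sample_ids = list(dict.fromkeys(sub["sample_id"]))
        offsets = np.linspace(-0.25, 0.25, max(len(sample_ids), 2))
        for sid, off in zip(sample_ids, offsets):
            y = sub.loc[sub["sample_id"] == sid, metric].dropna()
            ax.plot(np.full(len(y), gi + off), y, "o", ms=4, alpha=0.7)
        vals = sub[metric].dropna().to_numpy()
        if len(vals):
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            ax.errorbar(gi, vals.mean(), yerr=sem, fmt="_", color="k",
                        capsize=6, ms=18, lw=1.5)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(f"symmetry score ({metric})")
    ax.set_ylim(-0.02, 1.05)
    return ax
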