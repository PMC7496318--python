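"""Figure helpers for the study's characteristic plots.

Each function takes the pipeline's own objects and returns a matplotlib
Axes, so figures compose into larger layouts.
"""

from __future__ import annotations

import numpy as np

from .simulate import SEGMENTS


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_species_positions(summary, ax=None):
    """Mean relative position per species and segment with 95% CIs."""
    ax = _ax(ax)
    per = summary.per_segment
    species = list(summary.per_species.index)
    cmap_vals = np.linspace(0, 1, 8)
    import matplotlib.cm as cm

    for yi, sp in enumerate(species):
        sub = per[per.species == sp]
        for seg, c in zip(SEGMENTS, cmap_vals):
            row = sub[sub.segment == seg]
            if row.empty:
                continue
            r = row.iloc[0]
            ax.plot([r.ci95_low, r.ci95_high], [yi, yi], color=cm.viridis(c), lw=4, alpha=0.6)
            ax.plot([r.mean_p, r.mean_p], [yi - 0.3, yi + 0.3], color="k", lw=1)
    ax.set_yticks(range(len(species)), species, fontsize=8)
    ax.set_xlabel("relative segment position (fraction of larval length)")
    return ax


def plot_deviation_grid(summary, ax=None, scale=2000.0):
    """Direction/magnitude of each species' shift from the across-species mean.

    Circle area is proportional to the magnitude; colour encodes the
    direction (anterior vs posterior).
    """
    ax = _ax(ax)
    per = summary.per_segment
    species = list(summary.per_species.index)
    for yi, sp in enumerate(species):
        for xi, seg in enumerate(SEGMENTS):
            row = per[(per.species == sp) & (per.segment == seg)]
            if row.empty:
                continue
            r = row.iloc[0]
            ax.scatter(xi, yi, s=max(scale * r.magnitude, 1.0),
                       color="#e6c229" if r.direction == "anterior" else "#1f77b4", alpha=0.8)
    ax.set_xticks(range(8), SEGMENTS)
    ax.set_yticks(range(len(species)), species, fontsize=8)
    return ax


def plot_correlation_decay(profile, ax=None):
    """Within-species correlation versus inter-segment distance, A8 split out."""
    ax = _ax(ax)
    from .stats import correlation_decay_summary

    summ = correlation_decay_summary(profile)
    for a8, color, label in ((False, "k", "without A8"), (True, "r", "with A8")):
        sub = summ[summ.involves_a8 == a8].sort_values("separation")
        if sub.empty:
            continue
        ax.errorbar(sub.separation, sub.mean_r,
                    yerr=[sub.mean_r - sub.ci95_low, sub.ci95_high - sub.mean_r],
                    color=color, marker="o", capsize=3, label=label)
    ax.set_xlabel("segments apart")
    ax.set_ylabel("mean Pearson r")
    ax.legend()
    return ax


def plot_rate_posteriors(results, ax=None):
    """Per-segment posterior of the evolutionary rate (boxplot)."""
    ax = _ax(ax)
    s2 = results.sigma2_frame()
    ax.boxplot([s2[c] for c in s2.columns], tick_labels=list(s2.columns), whis=(2.5, 97.5), showfliers=False)
    ax.set_ylabel("evolutionary rate of relative position ($\\sigma^2$ per unit time)")
    return ax


def plot_branch_change_distribution(change_summary, ax=None, bins=60):
    """Pooled posterior distribution of normalised per-branch change."""
    ax = _ax(ax)
    ax.hist(change_summary.pooled, bins=bins, density=True, color="#555")
    ax.set_xlabel("|change in relative position| per unit time")
    ax.set_ylabel("density")
    return ax
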