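"""Optional diagnostic plots (matplotlib imported lazily).

These are illustrations of the numeric outputs, not part of the data
contract: the CSV/JSON files are authoritative.
"""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def resilience_plane(states, thresholds, path) -> None:
    """Trajectory in the (H, <s>) plane with the resilience frontier."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    h = [s.H for s in states]
    s_mean = [s.mean_s for s in states]
    lim_h = max(max(h, default=1), 2 * thresholds.h_crit) * 1.1
    lim_s = max(max(s_mean, default=1), 2 * thresholds.s_crit) * 1.1
    hh = np.linspace(1e-6, lim_h, 200)
    ax.fill_between(hh, 0, np.maximum(thresholds.beta_crit - hh, 0), color="#d73027", alpha=0.4)
    ax.axvline(thresholds.h_crit, color="grey", ls="--", lw=0.8)
    ax.axhline(thresholds.s_crit, color="grey", ls="--", lw=0.8)
    ax.plot(h, s_mean, "o-", color="#1a5276", ms=4)
    for state in states:
        ax.annotate(str(state.timestamp), (state.H, state.mean_s), fontsize=7)
    ax.set_xlabel("heterogeneity H")
    ax.set_ylabel("network density <s>")
    ax.set_xlim(0, lim_h)
    ax.set_ylim(0, lim_s)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def greenband_plot(statuses, model, path) -> None:
    """Catch vs production with the fitted band (log-log axes)."""
    from .greenband import band_bounds

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    frame = statuses[statuses["P"] > 0]
    p_grid = np.logspace(
        np.log10(frame["P"].min()) - 0.5, np.log10(frame["P"].max()) + 0.5, 200
    )
    upper, lower = band_bounds(p_grid, model)
    ax.fill_between(p_grid, lower, upper, color="#1a9850", alpha=0.3, label="green band")
    colours = {"above": "#d73027", "within": "#1a9850", "below": "#4575b4"}
    for status, colour in colours.items():
        sel = frame[frame["status"] == status]
        ax.plot(sel["P"], sel["Y"].clip(lower=1e-12), "o", ms=4, color=colour, label=status)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("production P (t km$^{-2}$ yr$^{-1}$)")
    ax.set_ylabel("catch Y (t km$^{-2}$ yr$^{-1}$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def eti_timeseries_plot(results, config, path) -> None:
    """ETI through time, coloured by qualitative rank."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colour_of = {label: colour for _, label, colour in config.rank_bands}
    x = range(len(results))
    ax.plot(x, [r.score for r in results], "-", color="grey", lw=0.8, zorder=1)
    ax.scatter(
        list(x),
        [r.score for r in results],
        c=[colour_of.get(r.rank_label, "black") for r in results],
        s=30,
        zorder=2,
    )
    ax.set_xticks(list(x))
    ax.set_xticklabels([str(r.timestamp) for r in results], fontsize=7)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("snapshot")
    ax.set_ylabel("ETI")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
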