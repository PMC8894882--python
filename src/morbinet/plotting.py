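"""Optional figure output (matplotlib); CSV tables remain canonical.

Import is deferred so the package works headless without matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_degree_profile", "plot_efficiency_series", "plot_graphlet_fractions"]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_degree_profile(profile: pd.DataFrame, path) -> Path:
    """Bar panel of group mean degrees with 95% CI whiskers."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    err = [profile["mean_degree"] - profile["ci_low"],
           profile["ci_high"] - profile["mean_degree"]]
    ax.bar(profile["group"].astype(str), profile["mean_degree"], yerr=err,
           capsize=3, color="#4878b0")
    ax.set_ylabel("mean degree")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_efficiency_series(series: pd.DataFrame, path,
                           subset: str = "all") -> Path:
    """Efficiency vs window midpoint with the null ribbon and the
    empirical/null ratio as an inset-style second axis."""
    plt = _pyplot()
    col = f"E_{subset}"
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(series["midpoint"], series[col], "o-", color="#c44e52",
            label="empirical")
    mean = series[f"{col}_null_mean"]
    sd = series[f"{col}_null_sd"]
    ax.plot(series["midpoint"], mean, "s-", color="#4878b0", label="null")
    ax.fill_between(series["midpoint"], mean - 1.96 * sd, mean + 1.96 * sd,
                    color="#4878b0", alpha=0.25)
    ax.set_xlabel("window midpoint (years to index diagnosis)")
    ax.set_ylabel(f"average efficiency ({subset})")
    ax.legend()
    ax2 = ax.twinx()
    ax2.plot(series["midpoint"], series[f"{col}_ratio"], ":", color="gray")
    ax2.axhline(1.0, color="gray", lw=0.5)
    ax2.set_ylabel("empirical / null", color="gray")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_graphlet_fractions(counts: pd.DataFrame, path) -> Path:
    """Stacked percentage bars of the 2-edge graphlet classes per scope."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    bottom = None
    for cls, color in (("frac_D1", "#dd8452"), ("frac_D2", "#55a868"),
                       ("frac_D3", "#4878b0")):
        vals = 100 * counts[cls]
        ax.bar(counts["scope"], vals, bottom=bottom, label=cls[5:], color=color)
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("% of 2-edge temporal graphlets")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
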