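"""Basic plots: expression heatmap and stratified Kaplan-Meier curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import survival as surv


def expression_heatmap(values: pd.DataFrame, path, title: str = "") -> None:
    """Plain matrix heatmap (features x samples), no dendrogram decoration."""
    fig, ax = plt.subplots(figsize=(8, max(2, 0.2 * len(values))))
    im = ax.imshow(values.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(values)), labels=values.index, fontsize=6)
    ax.set_xticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(data: pd.DataFrame, groups: pd.Series, path, horizon: float = 3.0) -> None:
    """Kaplan-Meier curves per group with the log-rank p in the title."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for gid, members in groups.groupby(groups).groups.items():
        km = surv.kaplan_meier(data.loc[members])
        ax.step(km["time"], km["survival"], where="post", label=str(gid))
    chi2, p = surv.log_rank_test(data, groups)
    ax.set_xlim(0, horizon)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("years")
    ax.set_ylabel("overall survival")
    ax.set_title(f"log-rank p = {p:.3g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
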