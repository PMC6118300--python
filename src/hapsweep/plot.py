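"""Simple per-stage summary figures."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .scan import NullDistribution


def plot_null_distribution(
    null: NullDistribution,
    observed: Optional[float] = None,
    path=None,
    statistic: str = "value",
    log_x: bool = False,
):
    """Histogram of a null distribution with the observed value marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(null.values, bins=40, color="#4878a8", alpha=0.85,
            label=f"null (n={null.n_matched})")
    if observed is not None:
        ax.axvline(observed, color="#c03030", linestyle="--",
                   label=f"observed = {observed:.3g}")
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(statistic)
    ax.set_ylabel("count")
    title = null.source
    if null.matching is not None:
        title += f", matched [{null.matching.lo}, {null.matching.hi}]"
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_ld_profile(positions, r2_values, deletion_pos=None, path=None):
    """Scatter of deletion-SNV r-squared along the region."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.scatter(positions, r2_values, s=8, color="#333333")
    if deletion_pos is not None:
        ax.axvline(deletion_pos, color="#c03030", linestyle=":",
                   label="deletion")
        ax.legend(fontsize=8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$r^2$ with deletion")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
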