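"""Diagnostics for judging fitted weights and choosing a rank threshold.

Two tabular views back the standard graphical presentations: a
comparative histogram of combined scores for all genes versus the core
genes (a good weight vector pushes the core mass into the high-score
bins), and a dual-axis threshold curve of score and cumulative core-gene
count against rank, from which the user reads off a prioritization
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .prioritize import RankedTable

__all__ = [
    "ScoreDistribution",
    "score_distribution",
    "threshold_curve",
    "plot_score_distribution",
    "plot_threshold_curve",
]


@dataclass(frozen=True)
class ScoreDistribution:
    """Histogram of combined scores over [0, 1] for all vs core genes."""

    bin_edges: np.ndarray
    all_counts: np.ndarray
    core_counts: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "all_count": self.all_counts,
                "core_count": self.core_counts,
            }
        )


def score_distribution(table: RankedTable, n_bins: int = 20) -> ScoreDistribution:
    """Equal-width score histogram over [0, 1]; last bin right-inclusive."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scores = table.frame["score"].to_numpy()
    core = table.frame["is_core"].to_numpy(dtype=bool)
    all_counts, edges = np.histogram(scores, bins=n_bins, range=(0.0, 1.0))
    core_counts, _ = np.histogram(scores[core], bins=n_bins, range=(0.0, 1.0))
    return ScoreDistribution(edges, all_counts, core_counts)


def threshold_curve(table: RankedTable):
    """Per-rank (rank, score, cumulative_core_count) table.

    Cumulative core count is taken along the displayed ranking order and
    ends at the total number of core genes.
    """
    import pandas as pd

    if len(table.frame) == 0:
        raise ValueError("ranked table is empty")
    core = table.frame["is_core"].to_numpy(dtype=bool)
    if not core.any():
        warnings.warn("no core genes in table: cumulative count is identically 0", UserWarning)
    return pd.DataFrame(
        {
            "rank": table.frame["rank"].to_numpy(),
            "score": table.frame["score"].to_numpy(),
            "cumulative_core_count": np.cumsum(core),
        }
    )


def plot_score_distribution(dist: ScoreDistribution, path) -> None:
    """Overlayed all-genes / core-genes score histogram (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
    width = np.diff(dist.bin_edges)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, dist.all_counts, width=width, label="all genes", color="#9ecae1")
    ax.bar(centers, dist.core_counts, width=width, label="core genes", color="#de2d26", alpha=0.8)
    ax.set_xlabel("combined score")
    ax.set_ylabel("gene count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_threshold_curve(curve, path) -> None:
    """Dual-axis rank curve: score (left) and cumulative core count (right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["rank"], curve["score"], color="#3182bd", label="combined score")
    ax.set_xlabel("rank")
    ax.set_ylabel("combined score")
    ax2 = ax.twinx()
    ax2.plot(
        curve["rank"], curve["cumulative_core_count"], color="#de2d26", label="core genes"
    )
    ax2.set_ylabel("cumulative core genes")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
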