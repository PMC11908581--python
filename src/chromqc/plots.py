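"""Plot helpers: cluster scatter in PC space and observed-vs-predicted."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

#: PNG metadata that would embed a timestamp is suppressed so reruns of the
#: same configuration produce byte-identical files.
_PNG_META = {"metadata": {"Software": None}}


def scatter_clusters(results, ax=None):
    """PC1-vs-PC2 scatter coloured by cluster label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    scores = results.reduced.scores
    labels = results.cluster.labels
    for c in sorted(set(int(v) for v in labels)):
        sel = labels == c
        ax.scatter(scores[sel, 0], scores[sel, 1], s=12, label=f"cluster {c}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"k={results.k}, mean silhouette={results.mean_silhouette:.2f}")
    ax.legend()
    return ax


def plot_clusters(results, path):
    ax = scatter_clusters(results)
    ax.figure.savefig(path, dpi=120, **_PNG_META)
    plt.close(ax.figure)


def plot_observed_vs_predicted(y_obs, y_pred, path, title=""):
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y_obs, y_pred, s=12)
    lo = min(min(y_obs), min(y_pred))
    hi = max(max(y_obs), max(y_pred))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("observed tR (min)")
    ax.set_ylabel("predicted tR (min)")
    ax.set_title(title)
    fig.savefig(path, dpi=120, **_PNG_META)
    plt.close(fig)
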