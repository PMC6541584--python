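"""Sample-level summaries: PCA, hierarchical clustering, volcano table, plots.

PCA runs on the full filtered, log-transformed matrix (samples as
observations, transcripts centred as features). Hierarchical clustering is
intended for the significant-transcript submatrix, with distance
1 - Pearson correlation between sample profiles and average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("telodiff")


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x 2
    variance_explained: np.ndarray  # length 2, non-increasing, in [0, 1]
    group_labels: list[str]


@dataclass
class ClusteringResult:
    merges: np.ndarray  # scipy linkage matrix (n-1) x 4
    leaf_order: list[str]
    two_cluster_labels: dict[str, int]
    group_labels: dict[str, str]


def pca_samples(m: ExpressionMatrix) -> EmbeddingResult:
    """Top-2 principal components of the samples.

    Transcript (feature) means are removed; component signs are fixed by
    making each component's largest-magnitude loading positive, so the
    embedding is deterministic.
    """
    if len(m.sample_ids) < 3:
        raise ValidationError("PCA requires at least 3 samples")
    if len(m.transcript_ids) < 2:
        raise ValidationError("PCA requires at least 2 transcripts")
    X = m.values.to_numpy().T  # samples x transcripts
    Xc = X - X.mean(axis=0)
    n_comp = min(2, len(m.sample_ids) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    with np.errstate(invalid="ignore", divide="ignore"):
        coords = pca.fit_transform(Xc)
    for j in range(n_comp):
        load = pca.components_[j]
        i_max = int(np.argmax(np.abs(load)))
        if load[i_max] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    if n_comp < 2:  # degenerate two-sample edge, pad a zero axis
        coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
        var = np.array([pca.explained_variance_ratio_[0], 0.0])
    else:
        var = pca.explained_variance_ratio_[:2].copy()
    total_var = Xc.var(axis=0).sum()
    if total_var == 0:
        coords = np.zeros_like(coords)
        var = np.zeros(2)
    return EmbeddingResult(
        sample_ids=list(m.sample_ids),
        coordinates=coords,
        variance_explained=var,
        group_labels=[m.group_of[s] for s in m.sample_ids],
    )


def hcluster_samples(m: ExpressionMatrix) -> ClusteringResult:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    A sample with a zero-variance profile has undefined correlation and is a
    hard error naming the sample.
    """
    if len(m.sample_ids) < 2:
        raise ValidationError("clustering requires at least 2 samples")
    X = m.values.to_numpy().T  # samples x transcripts
    sds = X.std(axis=1)
    for s, sd in zip(m.sample_ids, sds):
        if sd == 0:
            raise ValidationError(
                f"sample {s!r} has a zero-variance profile; correlation undefined"
            )
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce exact symmetry
    condensed = dist[np.triu_indices(len(m.sample_ids), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(Z)
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return ClusteringResult(
        merges=Z,
        leaf_order=[m.sample_ids[i] for i in leaves],
        two_cluster_labels=dict(zip(m.sample_ids, (int(c) for c in cut))),
        group_labels=dict(m.group_of),
    )


def cut_purity(c: ClusteringResult) -> float:
    """Fraction of samples on the majority-group side of the two-cluster cut
    (1.0 = the cut separates the groups perfectly)."""
    correct = 0
    for cluster in (1, 2):
        members = [s for s, c2 in c.two_cluster_labels.items() if c2 == cluster]
        if not members:
            continue
        groups = [c.group_labels[s] for s in members]
        correct += max(groups.count("case"), groups.count("control"))
    return correct / len(c.two_cluster_labels)


def volcano_table(de_table: pd.DataFrame) -> pd.DataFrame:
    """(log2 ratio, -log10 q, class) per transcript, sorted by q.

    Class is down/up for significant transcripts (strict q < alpha decided
    upstream via the ``significant`` column) and ``ns`` otherwise.
    """
    if de_table.empty:
        return pd.DataFrame(columns=["log2_ratio", "neg_log10_q", "class"])
    out = pd.DataFrame(index=de_table.index)
    out["log2_ratio"] = de_table["log2_ratio"]
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(de_table["q_value"])
    sig = de_table["significant"].to_numpy(dtype=bool)
    down = de_table["log2_ratio"].to_numpy() < 0
    out["class"] = np.where(sig, np.where(down, "down", "up"), "ns")
    return out.loc[de_table["q_value"].sort_values(kind="stable").index]


# ---------------------------------------------------------------------------
# Plots (optional outputs; all take an explicit path)
# ---------------------------------------------------------------------------


def _get_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_volcano(volcano: pd.DataFrame, path) -> None:
    plt = _get_axes()
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"down": "tab:red", "up": "tab:green", "ns": "black"}
    for cls, sub in volcano.groupby("class"):
        ax.scatter(sub["log2_ratio"], sub["neg_log10_q"], s=4,
                   c=colors.get(cls, "grey"), label=cls, alpha=0.6)
    ax.set_xlabel("log2 fold change (case vs control)")
    ax.set_ylabel("-log10 q")
    ax.legend(frameon=False, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(emb: EmbeddingResult, path) -> None:
    plt = _get_axes()
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, color in (("case", "tab:orange"), ("control", "tab:blue")):
        idx = [i for i, g in enumerate(emb.group_labels) if g == label]
        ax.scatter(emb.coordinates[idx, 0], emb.coordinates[idx, 1],
                   c=color, label=label)
    ax.set_xlabel(f"PC1 ({100 * emb.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * emb.variance_explained[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(c: ClusteringResult, path) -> None:
    plt = _get_axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(
        c.merges, labels=list(c.two_cluster_labels), ax=ax, color_threshold=None
    )
    ax.set_ylabel("1 - Pearson r (average linkage)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density_envelope(env, path) -> None:
    """Observed density line over the shaded null band for one chromosome."""
    plt = _get_axes()
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.fill_between(env.grid / 1e6, env.lower, env.upper,
                    color="lightgrey", label="null 95% envelope")
    ax.plot(env.grid / 1e6, env.observed, color="tab:orange", label="observed")
    ax.set_xlabel(f"{env.chrom} position (Mb)")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
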