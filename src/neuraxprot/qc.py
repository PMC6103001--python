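"""Replicate-level quality diagnostics.

Builds a protein x sample intensity matrix from per-replicate protein means,
computes pairwise Pearson correlations (pairwise-complete), and performs
unsupervised hierarchical clustering (Euclidean distance, average/UPGMA
linkage) on log2-transformed, row-z-scored intensities — the standard
Perseus-style reproducibility workflow.  Row clusters are cut at a fixed
distance threshold (default 3.4) for visualization of co-expressed protein
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "IntensityMatrix",
    "build_matrix",
    "log2_zscore",
    "pairwise_pearson",
    "cluster_samples",
    "ClusterResult",
]


@dataclass
class IntensityMatrix:
    """Proteins x samples matrix with an explicit transform-state flag.

    ``data`` holds one row per protein and one column per sample
    ("tissue/condition/replicate" labels); missing cells are NaN.  ``state``
    is one of {"linear", "log2", "log2_zscored"}; transforms refuse to run
    twice.  ``constant_rows`` lists proteins whose non-missing values were
    constant at z-scoring time (their z-rows are all zeros by convention).
    """

    data: pd.DataFrame
    state: str = "linear"
    constant_rows: list[str] = field(default_factory=list)
    dropped_rows: list[str] = field(default_factory=list)


def sample_label(tissue: str, condition: str, replicate: int) -> str:
    return f"{tissue}/{condition}/{replicate}"


def build_matrix(
    replicate_intensities: pd.DataFrame,
    samples: list[tuple[str, str, int]] | None = None,
) -> IntensityMatrix:
    """Pivot per-replicate protein intensities into a proteins x samples matrix.

    ``samples`` selects and orders (tissue, condition, replicate) columns;
    by default every sample present in the input is used.  Proteins missing
    in a sample carry NaN.
    """
    df = replicate_intensities
    if samples is None:
        samples = sorted(
            {
                (t, c, int(r))
                for t, c, r in zip(df["tissue"], df["condition"], df["replicate"])
            }
        )
    if not samples:
        raise ValueError("empty sample selection")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample in selection")
    labels = [sample_label(*s) for s in samples]
    key = list(zip(df["tissue"], df["condition"], df["replicate"]))
    sub = df.loc[[k in set(samples) for k in key]].copy()
    sub["sample"] = [
        sample_label(t, c, int(r))
        for t, c, r in zip(sub["tissue"], sub["condition"], sub["replicate"])
    ]
    wide = sub.pivot_table(
        index="protein_id", columns="sample", values="mean_intensity",
        aggfunc="first", observed=True,
    )
    wide = wide.reindex(columns=labels)
    return IntensityMatrix(data=wide, state="linear")


def log2_zscore(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform and z-score each protein row over its non-missing cells.

    Sample sd (n-1) is used.  Rows with a single non-missing value are
    dropped (sd undefined) and listed in ``dropped_rows``; constant rows
    z-score to all zeros and are listed in ``constant_rows`` so the row
    universe stays stable between correlation and clustering.
    """
    if matrix.state != "linear":
        raise ValueError(f"matrix already transformed (state={matrix.state!r})")
    logged = np.log2(matrix.data)
    n_obs = logged.notna().sum(axis=1)
    dropped = logged.index[n_obs < 2].tolist()
    logged = logged.drop(index=dropped)
    means = logged.mean(axis=1, skipna=True)
    sds = logged.std(axis=1, ddof=1, skipna=True)
    constant = sds.index[sds == 0.0].tolist()
    safe_sd = sds.replace(0.0, 1.0)
    z = logged.sub(means, axis=0).div(safe_sd, axis=0)
    return IntensityMatrix(
        data=z, state="log2_zscored", constant_rows=constant, dropped_rows=dropped
    )


def pairwise_pearson(matrix: IntensityMatrix) -> pd.DataFrame:
    """Pearson r for every sample pair over rows non-missing in both.

    Pairwise-complete: each pair uses its own shared-row set.  Cells backed
    by fewer than two shared rows are NaN with a warning.  The diagonal is 1.
    """
    corr = matrix.data.corr(method="pearson", min_periods=2)
    counts = matrix.data.notna().astype(int)
    shared = counts.T @ counts
    thin = (shared < 2) & ~np.eye(len(corr), dtype=bool)
    if thin.to_numpy().any():
        warnings.warn(
            "some sample pairs share fewer than two complete rows; "
            "their correlations are undefined",
            stacklevel=2,
        )
        corr = corr.mask(thin)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusterResult:
    """Linkage matrices plus flat row clusters cut at a fixed distance."""

    sample_linkage: np.ndarray
    sample_labels: list[str]
    protein_linkage: np.ndarray | None
    protein_labels: list[str]
    protein_clusters: pd.Series  # protein_id -> flat cluster id


def _linkage(data: np.ndarray) -> np.ndarray:
    return hierarchy.linkage(pdist(data, metric="euclidean"), method="average")


def cluster_samples(
    matrix: IntensityMatrix,
    cut_distance: float = 3.4,
) -> ClusterResult:
    """UPGMA clustering of samples (columns) and proteins (rows).

    Requires a z-scored matrix; rows with any missing value are excluded
    (complete-case), matching the behaviour of standard heatmap tools.  Rows
    and columns are ordered lexicographically by label before linkage so the
    result is deterministic and invariant to input permutation.  Flat row
    clusters are cut at ``cut_distance`` (the 3.4 default mirrors the
    visualization threshold of the study design).
    """
    if matrix.state != "log2_zscored":
        raise ValueError("cluster_samples expects a log2_zscored matrix")
    complete = matrix.data.dropna(axis=0, how="any")
    complete = complete.sort_index(axis=0).sort_index(axis=1)
    if complete.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    sample_linkage = _linkage(complete.to_numpy().T)
    if complete.shape[0] >= 2:
        protein_linkage = _linkage(complete.to_numpy())
        flat = hierarchy.fcluster(
            protein_linkage, t=cut_distance, criterion="distance"
        )
        protein_clusters = pd.Series(
            flat, index=complete.index, name="cluster"
        )
    else:
        protein_linkage = None
        protein_clusters = pd.Series(
            np.ones(len(complete), dtype=int), index=complete.index, name="cluster"
        )
    return ClusterResult(
        sample_linkage=sample_linkage,
        sample_labels=list(complete.columns),
        protein_linkage=protein_linkage,
        protein_labels=list(complete.index),
        protein_clusters=protein_clusters,
    )


def plot_density(matrix: IntensityMatrix, path) -> None:
    """Kernel-density view of each sample's log2 intensity distribution.

    Gaussian kernel with Silverman bandwidth; optional (requires matplotlib).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    data = np.log2(matrix.data) if matrix.state == "linear" else matrix.data
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in data.columns:
        values = data[col].dropna().to_numpy()
        if len(values) < 2:
            continue
        kde = gaussian_kde(values, bw_method="silverman")
        grid = np.linspace(values.min(), values.max(), 256)
        ax.plot(grid, kde(grid), label=col, lw=1)
    ax.set_xlabel("log2 intensity")
    ax.set_ylabel("density")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
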