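"""Sample-level multivariate views: PCA score plots and hierarchical
clustering with Newick dendrogram export.

Rows are metabolites, columns are samples of one compartment. Before PCA
every metabolite row is autoscaled (zero mean, unit variance across
samples; zero-variance rows dropped). ND cells cannot be autoscaled, so the
matrix builder substitutes half the minimum observed value of that
metabolite — the usual left-censoring stand-in for below-detection peaks.

Defaults (Euclidean distance, Ward linkage, row autoscaling) are the common
metabolomics choices; both are flags and exported artifacts record the
settings used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core import MODES, StudyBundle

ND_POLICIES = ("half_min", "drop")


def build_sample_matrix(
    bundle: StudyBundle, compartment: str, nd_policy: str = "half_min"
) -> pd.DataFrame:
    """Metabolite x sample matrix for one compartment, ND resolved.

    ``half_min`` replaces ND with half the minimum observed value of that
    metabolite; ``drop`` removes any row containing ND. All-ND rows are
    always dropped.
    """
    if nd_policy not in ND_POLICIES:
        raise ValueError(f"unknown nd_policy {nd_policy!r}")
    frame = bundle.compartment_frame(compartment)
    values = frame.drop(columns=["metabolite", "mode"]).astype(float)
    values = values.loc[values.notna().any(axis=1)]
    if nd_policy == "drop":
        values = values.loc[values.notna().all(axis=1)]
    else:
        half_min = values.min(axis=1) / 2
        values = values.apply(lambda col: col.fillna(half_min))
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    return values


def _autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=1, ddof=1)
    kept = matrix.loc[sd > 0]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)


def pca_scores(matrix: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the samples.

    Rows are autoscaled, then the samples (columns) are decomposed. Returns
    ``(scores, explained)`` where ``scores`` is samples x k and
    ``explained`` the non-increasing explained-variance fractions. Scores
    are reproducible up to per-component sign.
    """
    scaled = _autoscale(matrix)
    n_samples = scaled.shape[1]
    if k > min(scaled.shape[0], n_samples - 1):
        raise ValueError(f"k={k} exceeds the rank bound of the matrix")
    x = scaled.to_numpy().T  # samples x features
    model = PCA(n_components=k)
    scores = model.fit_transform(x)
    frame = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, model.explained_variance_ratio_


def hca_tree(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "ward",
    autoscale: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of the samples.

    ``distance`` is ``euclidean`` or ``correlation`` (1 - Pearson between
    sample profiles); ``linkage`` is ``ward``, ``average`` or ``complete``.
    Returns the scipy linkage matrix and the leaf labels (sample columns).
    Merge heights are non-decreasing for these linkage/distance choices.
    """
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    data = _autoscale(matrix) if autoscale else matrix
    x = data.to_numpy().T
    if np.isnan(x).any():
        raise ValueError("NaN in matrix after ND policy application")
    dists = pdist(x, metric=distance)
    z = hierarchy.linkage(dists, method=linkage)
    return z, list(matrix.columns)


def to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Export a linkage matrix as a rooted Newick string.

    Branch lengths are merge-height differences, so leaf-to-root path
    lengths equal the root merge height.
    """
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.10g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    left = walk(tree.get_left(), tree.dist)
    right = walk(tree.get_right(), tree.dist)
    return f"({left},{right});"


def clades(z: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Leaf sets of every internal node — a column-order-invariant tree
    fingerprint used for isomorphism checks."""
    tree = hierarchy.to_tree(z)
    out: set[frozenset] = set()

    def walk(node) -> frozenset:
        if node.is_leaf():
            return frozenset([labels[node.id]])
        leaves = walk(node.get_left()) | walk(node.get_right())
        out.add(leaves)
        return leaves

    walk(tree)
    return out
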