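"""Model scope comparison: what each model covers, and how models group.

Each model is reduced to a binary vector over a shared feature set —
the union of gene (ORF) identifiers, or the union of first-listed ChEBI
metabolite identifiers — giving an incidence matrix (models x
features).  Pairwise distances between the binary vectors feed
agglomerative hierarchical clustering (dendrogram, exportable as
Newick) and classical multidimensional scaling (2-D scatter
coordinates).

Metabolite comparison is necessarily less comprehensive than gene
comparison: only metabolites carrying ChEBI annotation participate, and
a metabolite annotated with several ChEBI identifiers contributes its
FIRST identifier only.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .model import MetabolicModel

__all__ = [
    "gene_incidence",
    "metabolite_incidence",
    "pairwise_distance",
    "hierarchical_cluster",
    "cut_clusters",
    "linkage_to_newick",
    "classical_mds",
]

logger = logging.getLogger(__name__)

_METRICS = {"euclidean", "hamming", "jaccard"}
_LINKAGES = {"average", "single", "complete"}


def gene_incidence(models: list[MetabolicModel]) -> pd.DataFrame:
    """Binary incidence matrix over ORFs: rows = models, columns = the
    sorted union of gene ids; 1 where the model includes the gene.

    Transpose for a row-aligned comparative gene table (genes as rows).
    """
    if len(models) < 2:
        raise ValueError("gene incidence comparison requires >= 2 models")
    features = sorted(set().union(*(m.genes for m in models)))
    data = [[1 if g in m.genes else 0 for g in features] for m in models]
    return pd.DataFrame(data, index=[m.model_id for m in models], columns=features)


def metabolite_incidence(models: list[MetabolicModel]) -> pd.DataFrame:
    """Binary incidence matrix over ChEBI ids (first identifier per
    metabolite); metabolites without ChEBI annotation are excluded."""
    per_model: list[set[str]] = []
    for m in models:
        ids = {
            met.chebi_ids[0]
            for met in m.metabolites.values()
            if met.chebi_ids and not met.is_boundary
        }
        if not ids:
            warnings.warn(
                f"model {m.model_id!r} has no ChEBI-annotated metabolites; "
                "its row is all zeros",
                stacklevel=2,
            )
        per_model.append(ids)
    features = sorted(set().union(*per_model)) if per_model else []
    data = [[1 if f in ids else 0 for f in features] for ids in per_model]
    return pd.DataFrame(data, index=[m.model_id for m in models], columns=features)


def pairwise_distance(
    incidence: pd.DataFrame, metric: str = "euclidean"
) -> pd.DataFrame:
    """Symmetric model-by-model distance matrix over incidence rows."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    values = incidence.to_numpy(dtype=float)
    d = squareform(pdist(values, metric=metric))
    return pd.DataFrame(d, index=incidence.index, columns=incidence.index)


def hierarchical_cluster(
    distances: pd.DataFrame, linkage: str = "average"
) -> np.ndarray:
    """Agglomerative clustering of a distance matrix.

    Returns the SciPy linkage matrix; merge heights are non-decreasing.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    condensed = squareform(distances.to_numpy(dtype=float), checks=True)
    return hierarchy.linkage(condensed, method=linkage)


def cut_clusters(
    linkage_matrix: np.ndarray, labels: list[str], k: int
) -> dict[str, int]:
    """Partition into ``k`` groups by cutting the dendrogram."""
    assignment = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assignment)))


def linkage_to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def classical_mds(distances: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared-distance matrix, eigendecomposes the Gram
    matrix, and returns coordinates ordered by decreasing eigenvalue.
    Dimensions whose eigenvalues are non-positive carry no Euclidean
    structure; if fewer than ``k`` positive eigenvalues exist the output
    is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = distances.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    positive = eigvals > max(1e-12, 1e-9 * abs(eigvals[0]))
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_pos} "
            f"dimension(s) instead of {k}",
            stacklevel=2,
        )
    dims = min(k, max(n_pos, 1))
    coords = eigvecs[:, :dims] * np.sqrt(np.maximum(eigvals[:dims], 0.0))
    return pd.DataFrame(
        coords,
        index=distances.index,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
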