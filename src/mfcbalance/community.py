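"""Anodic-community diversity from taxon-by-sample count tables.

Rarefaction to an even sampling depth, Shannon alpha diversity,
Bray-Curtis dissimilarity and average-linkage (UPGMA) hierarchical
clustering — the standard downstream of an amplicon count table once ASVs
have been called and assigned.  Upstream read processing is out of scope.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import braycurtis as _braycurtis, squareform


class CommunityMatrix:
    """Non-negative integer counts, taxa (rows) by samples (columns)."""

    def __init__(self, counts, taxa: list[str], samples: list[str]):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        if counts.shape != (len(taxa), len(samples)):
            raise ValueError("counts shape must match taxon and sample labels")
        if len(set(taxa)) != len(taxa) or len(set(samples)) != len(samples):
            raise ValueError("duplicate taxon or sample labels")
        self.counts = counts.astype(np.int64)
        self.taxa = list(taxa)
        self.samples = list(samples)

    @property
    def depths(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def sample_counts(self, name: str) -> np.ndarray:
        return self.counts[:, self.samples.index(name)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CommunityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)


def rarefy(matrix: CommunityMatrix, depth: int | None = None,
           seed: int = 0) -> CommunityMatrix:
    """Subsample every sample to an even depth, without replacement.

    ``depth`` defaults to the minimum sample depth (single draw, no
    averaging over repeated rarefactions).  Samples shallower than
    ``depth`` are dropped with a warning.  Deterministic given ``seed``.
    """
    if depth is None:
        depth = int(matrix.depths.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep_cols, out = [], []
    for j, name in enumerate(matrix.samples):
        col = matrix.counts[:, j]
        total = int(col.sum())
        if total < depth:
            warnings.warn(f"sample {name!r} (depth {total}) below rarefaction "
                          f"depth {depth}; dropped", stacklevel=2)
            continue
        if total == depth:
            out.append(col.copy())
        else:
            out.append(rng.multivariate_hypergeometric(col, depth))
        keep_cols.append(name)
    if not keep_cols:
        raise ValueError("no sample reaches the requested depth")
    return CommunityMatrix(np.column_stack(out), matrix.taxa, keep_cols)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (natural log) of one sample."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon index is undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log(p)))


def shannon_table(matrix: CommunityMatrix, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon index; ``base`` rescales from natural log."""
    scale = 1.0 if base is None else 1.0 / np.log(base)
    return pd.DataFrame({
        "sample": matrix.samples,
        "shannon": [shannon(matrix.counts[:, j]) * scale
                    for j in range(len(matrix.samples))],
    })


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum a + sum b), in [0,1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and the same length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    return float(_braycurtis(a, b))


def bray_curtis_matrix(matrix: CommunityMatrix) -> pd.DataFrame:
    n = len(matrix.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(matrix.counts[:, i], matrix.counts[:, j])
    return pd.DataFrame(d, index=matrix.samples, columns=matrix.samples)


def hierarchical_cluster(dist: pd.DataFrame | np.ndarray,
                         labels: list[str] | None = None) -> "ClusterTree":
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix."""
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.columns.astype(str))
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"S{i}" for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if d.shape[0] == 1:
        return ClusterTree(None, labels)
    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")
    return ClusterTree(linkage, labels)


class ClusterTree:
    """A UPGMA dendrogram, serializable to Newick."""

    def __init__(self, linkage: np.ndarray | None, labels: list[str]):
        self.linkage = linkage
        self.labels = labels

    @property
    def merge_heights(self) -> np.ndarray:
        if self.linkage is None:
            return np.array([])
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Ultrametric Newick: node height is half the merge distance, so
        the leaf-to-leaf path length equals the cophenetic dissimilarity."""
        if self.linkage is None:
            return f"{self.labels[0]}:0.0;"
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            kids = ",".join(fmt(c, height) for c in (node.left, node.right))
            return f"({kids}):{length:.6g}"

        h = root.dist / 2.0
        kids = ",".join(fmt(c, h) for c in (root.left, root.right))
        return f"({kids});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")
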