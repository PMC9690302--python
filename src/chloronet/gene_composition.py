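"""Cross-sample gene presence/absence comparison.

Chloroplast gene content varies between populations (notably tRNA
presence/absence); this module builds a binary presence matrix over
normalized gene symbols, extracts genes unique to a focal sample subset,
and clusters samples by Jaccard distance of their presence profiles.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .genome_features import GenomeRecord

__all__ = [
    "build_presence_matrix",
    "unique_genes",
    "jaccard_cluster",
    "discriminating_genes",
    "ClusterResult",
]


def build_presence_matrix(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Boolean samples x genes matrix; a cell is True iff the gene is
    annotated at least once in that sample (IR duplicates collapse)."""
    if not records:
        raise ValueError("no genome records given")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample IDs among records")
    genes = sorted(set().union(*(r.gene_names() for r in records)))
    data = np.zeros((len(records), len(genes)), dtype=bool)
    index = {g: j for j, g in enumerate(genes)}
    for i, rec in enumerate(records):
        for name in rec.gene_names():
            data[i, index[name]] = True
    return pd.DataFrame(data, index=ids, columns=genes)


def unique_genes(matrix: pd.DataFrame, focal_samples: Iterable[str]) -> set[str]:
    """Genes present in every focal sample and absent from every other sample."""
    focal = list(dict.fromkeys(focal_samples))
    if not focal:
        raise ValueError("focal sample set is empty")
    missing = [s for s in focal if s not in matrix.index]
    if missing:
        raise ValueError(f"focal samples not in matrix: {missing}")
    rest = [s for s in matrix.index if s not in focal]
    if not rest:
        raise ValueError("focal set equals the full sample set")
    in_all_focal = matrix.loc[focal].all(axis=0)
    in_no_other = ~matrix.loc[rest].any(axis=0)
    return set(matrix.columns[in_all_focal & in_no_other])


@dataclass
class ClusterResult:
    """Average-linkage Jaccard clustering of presence profiles."""

    samples: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    flat_clusters: dict[str, int]  # 2-cluster cut (all 1s when profiles identical)
    distance_matrix: pd.DataFrame
    method: str = "average-linkage on Jaccard distance"

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            return f"({fmt(node.left)}:{node.dist/2:.6g},{fmt(node.right)}:{node.dist/2:.6g})"

        return fmt(tree) + ";"


def jaccard_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster samples on Jaccard distance of presence rows.

    The flat clustering is the 2-cluster cut of the average-linkage tree;
    identical rows everywhere collapse to a single cluster.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two samples to cluster")
    rows = matrix.to_numpy(dtype=bool)
    dist = pdist(rows, metric="jaccard")
    link = hierarchy.linkage(dist, method="average")
    if np.allclose(dist, 0):
        labels = np.ones(len(matrix), dtype=int)
    else:
        labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    dm = pd.DataFrame(squareform(dist), index=matrix.index, columns=matrix.index)
    return ClusterResult(
        samples=list(matrix.index),
        linkage=link,
        flat_clusters=dict(zip(matrix.index, (int(x) for x in labels))),
        distance_matrix=dm,
    )


def discriminating_genes(matrix: pd.DataFrame, clusters: dict[str, int]) -> pd.DataFrame:
    """Genes whose presence separates the flat clusters: present in every
    sample of one cluster and absent from every sample of the other.

    Surfaces single-gene differences between otherwise-similar samples
    (psbM-style splits among hinterland populations).
    """
    groups: dict[int, list[str]] = {}
    for s, c in clusters.items():
        groups.setdefault(c, []).append(s)
    if len(groups) < 2:
        return pd.DataFrame(columns=["gene", "present_in_cluster"])
    out = []
    ids = sorted(groups)
    for gene in matrix.columns:
        col = matrix[gene]
        for cid in ids:
            inside = col.loc[groups[cid]]
            outside = col.drop(groups[cid])
            if inside.all() and not outside.any():
                out.append({"gene": gene, "present_in_cluster": cid})
    return pd.DataFrame(out, columns=["gene", "present_in_cluster"])
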