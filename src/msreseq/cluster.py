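"""Hierarchical clustering of CpG sites with bootstrap branch support.

Sites are clustered by average linkage on correlation dissimilarity
(1 - Pearson) of their per-sample profiles; branch support is the ordinary
bootstrap probability: the fraction of column-resampled trees containing
the identical leaf bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

Bipartition = FrozenSet[str]


@dataclass
class ClusterTree:
    linkage_matrix: np.ndarray  # scipy linkage (n-1) x 4
    leaf_ids: List[str]
    supports: Dict[Bipartition, float] = field(default_factory=dict)  # percent
    n_boot: int = 0
    seed: Optional[int] = None

    def bipartitions(self) -> List[Bipartition]:
        return _clades(self.linkage_matrix, self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with BP (percent) as internal node labels."""
        root = to_tree(self.linkage_matrix)

        def render(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            clade = frozenset(
                self.leaf_ids[i] for i in node.pre_order(lambda n: n.id)
            )
            label = ""
            if clade in self.supports:
                label = f"{self.supports[clade]:.1f}"
            return f"({left},{right}){label}:{length:.6g}"

        return render(root, root.dist) + ";"


def _correlation_distances(values: np.ndarray) -> np.ndarray:
    d = pdist(values, metric="correlation")
    # rows that lose all variance under resampling yield NaN; treat as
    # uncorrelated rather than aborting the replicate
    return np.nan_to_num(d, nan=1.0)


def _clades(z: np.ndarray, leaf_ids: Sequence[str]) -> List[Bipartition]:
    n = len(leaf_ids)
    members: List[FrozenSet[str]] = [frozenset([lid]) for lid in leaf_ids]
    clades: List[Bipartition] = []
    for row in z:
        merged = members[int(row[0])] | members[int(row[1])]
        members.append(merged)
        clades.append(merged)
    return clades


def correlation_linkage_tree(profiles: pd.DataFrame) -> ClusterTree:
    """Average-linkage tree on 1 - Pearson correlation of site rows.

    ``profiles``: rows are sites (index = site_id), columns are samples.
    Zero-variance rows are rejected (their correlation is undefined).
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 3:
        raise ValueError("need at least 2 sites and 3 samples")
    values = profiles.to_numpy(dtype=float)
    variances = values.var(axis=1)
    if np.any(variances == 0):
        bad = list(profiles.index[variances == 0])
        raise ValueError(f"zero-variance site profiles: {bad}")
    z = linkage(pdist(values, metric="correlation"), method="average")
    return ClusterTree(linkage_matrix=z, leaf_ids=list(profiles.index))


def bootstrap_branch_support(profiles: pd.DataFrame, n_boot: int = 1000,
                             seed: int = 0) -> ClusterTree:
    """Tree plus bootstrap probabilities per internal branch.

    Samples (columns) are resampled with replacement ``n_boot`` times; BP of
    a branch is the percentage of replicate trees containing the identical
    leaf bipartition.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is low; supports will be noisy", n_boot)
    tree = correlation_linkage_tree(profiles)
    target = {clade: 0 for clade in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    values = profiles.to_numpy(dtype=float)
    n_samples = values.shape[1]
    leaf_ids = tree.leaf_ids
    for _ in range(n_boot):
        cols = rng.integers(0, n_samples, size=n_samples)
        z = linkage(_correlation_distances(values[:, cols]), method="average")
        for clade in _clades(z, leaf_ids):
            if clade in target:
                target[clade] += 1
    tree.supports = {c: 100.0 * k / n_boot for c, k in target.items()}
    tree.n_boot = n_boot
    tree.seed = seed
    return tree


def bipartition_table(tree: ClusterTree) -> pd.DataFrame:
    """Flat TSV-ready table of branches and their supports."""
    rows = []
    for clade in tree.bipartitions():
        rows.append(
            {
                "n_leaves": len(clade),
                "support_pct": tree.supports.get(clade, float("nan")),
                "members": ",".join(sorted(clade)),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["n_leaves", "members"], kind="stable"
    ).reset_index(drop=True)
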