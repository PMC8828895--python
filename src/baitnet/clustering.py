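"""Bait-by-prey and prey-prey correlation clustering.

Two complementary views of a distilled interactome:

* hierarchical clustering of the bait-by-prey average-spectral-count
  matrix (either axis), revealing baits with similar interactomes;
* prey-prey Pearson correlation of prey profiles across baits, followed
  by hierarchical clustering, revealing groups of preys that co-occur
  across baits — candidate complexes or shared molecular contexts. Each
  flat cluster is attributed to "driving baits", ranked by how many
  cluster members appear in the bait's interactome.

Clustering is deterministic: scipy's agglomerative linkage with a fixed
distance metric, and flat clusters labeled A, B, C... in dendrogram leaf
order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .types import PreyCluster, ValidationError


@dataclass
class BaitPreyMatrix:
    """Dense bait x prey matrix of average spectral counts.

    Zero where the pair is not a high-confidence interaction; only
    filtered interactions are non-zero.
    """

    baits: list[str]
    preys: list[str]
    values: np.ndarray  # shape (n_baits, n_preys)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.baits), len(self.preys)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.baits)} baits x {len(self.preys)} preys"
            )
        if (self.values < 0).any():
            raise ValidationError("spectral counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.baits, columns=self.preys)


def build_bait_prey_matrix(*tables: pd.DataFrame) -> BaitPreyMatrix:
    """Assemble the matrix from one or more distilled interaction tables.

    If a (bait, prey) pair occurs in several tables (e.g. both methods),
    the maximum average count is used.
    """
    cells: dict[tuple[str, str], float] = {}
    for table in tables:
        for row in table.itertuples(index=False):
            key = (row.bait, row.prey)
            cells[key] = max(cells.get(key, 0.0), float(row.avg_spec))
    baits = sorted({b for b, _ in cells})
    preys = sorted({p for _, p in cells})
    values = np.zeros((len(baits), len(preys)))
    b_idx = {b: i for i, b in enumerate(baits)}
    p_idx = {p: j for j, p in enumerate(preys)}
    for (b, p), v in cells.items():
        values[b_idx[b], p_idx[p]] = v
    return BaitPreyMatrix(baits=baits, preys=preys, values=values)


@dataclass
class ClusterTree:
    """An agglomerative clustering result for one axis of the matrix."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def hierarchical_cluster(
    matrix: BaitPreyMatrix,
    axis: str = "prey",
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of baits or preys.

    metric: ``euclidean`` on the count profiles, or ``pearson`` for
    1 - Pearson correlation distance. linkage: ``average`` or ``complete``.
    Deterministic for fixed input; permuting input rows does not change
    the tree topology.
    """
    if axis not in ("bait", "prey"):
        raise ValidationError(f"axis must be 'bait' or 'prey', got {axis!r}")
    data = matrix.values if axis == "bait" else matrix.values.T
    labels = matrix.baits if axis == "bait" else matrix.preys
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 items on the clustered axis")
    if metric == "euclidean":
        dist = pdist(data, metric="euclidean")
    elif metric == "pearson":
        dist = pdist(data, metric="correlation")
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    if linkage not in ("average", "complete", "single", "ward"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterTree(labels=list(labels), linkage=Z, leaf_order=order)


def prey_correlation_matrix(
    matrix: BaitPreyMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Prey x prey Pearson correlation of profiles across baits.

    Requires >= 2 baits. Preys with constant profiles (usually all-equal
    counts across baits) have undefined correlation; they are excluded and
    returned separately. The result is symmetric with a unit diagonal.
    """
    if len(matrix.baits) < 2:
        raise ValidationError("need >= 2 baits to correlate prey profiles")
    profiles = matrix.values.T  # preys x baits
    keep = np.ptp(profiles, axis=1) > 0
    excluded = [p for p, k in zip(matrix.preys, keep) if not k]
    kept_preys = [p for p, k in zip(matrix.preys, keep) if k]
    corr = np.corrcoef(profiles[keep])
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=kept_preys, columns=kept_preys)
    return frame, excluded


def _letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA ... (spreadsheet-style labels)."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def extract_clusters(tree: ClusterTree, k: int | None = None,
                     height: float | None = None) -> list[PreyCluster]:
    """Cut the dendrogram into a flat partition labeled in leaf order.

    Exactly one of ``k`` (number of clusters) or ``height`` (distance
    threshold) must be given. Cluster letters follow the dendrogram leaf
    order: the cluster containing the leftmost leaf is A, and so on.
    """
    if (k is None) == (height is None):
        raise ValidationError("specify exactly one of k or height")
    if k is not None:
        assignments = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    else:
        assignments = hierarchy.fcluster(tree.linkage, t=height,
                                         criterion="distance")
    # map scipy's arbitrary cluster ids to letters by first leaf appearance
    letter_of: dict[int, str] = {}
    for leaf in tree.leaf_order:
        cid = assignments[leaf]
        if cid not in letter_of:
            letter_of[cid] = _letters(len(letter_of))
    clusters: dict[str, list[str]] = {}
    for leaf in tree.leaf_order:
        clusters.setdefault(letter_of[assignments[leaf]], []).append(
            tree.labels[leaf])
    return [PreyCluster(cluster_id=cid, members=members)
            for cid, members in clusters.items()]


def driving_baits(
    cluster: PreyCluster,
    *tables: pd.DataFrame,
    include_zero: bool = False,
) -> list[tuple[str, int]]:
    """Rank baits by how many cluster members appear in their interactome.

    Sorted by descending count, ties broken alphabetically. Baits with no
    cluster members are omitted unless ``include_zero``.
    """
    members = set(cluster.members)
    prey_of: dict[str, set[str]] = {}
    for table in tables:
        for bait, group in table.groupby("bait"):
            prey_of.setdefault(bait, set()).update(group["prey"])
    counts = {bait: len(preys & members) for bait, preys in prey_of.items()}
    if not include_zero:
        counts = {b: c for b, c in counts.items() if c > 0}
    return sorted(counts.items(), key=lambda bc: (-bc[1], bc[0]))


def cluster_report(clusters: Sequence[PreyCluster],
                   *tables: pd.DataFrame) -> pd.DataFrame:
    """Flat TSV-ready cluster table with ranked driving baits attached."""
    rows = []
    for cl in clusters:
        drivers = driving_baits(cl, *tables)
        driver_str = ";".join(f"{b}:{n}" for b, n in drivers)
        for prey in cl.members:
            rows.append((cl.cluster_id, prey, len(cl.members), driver_str))
    return pd.DataFrame(rows, columns=["cluster", "prey", "cluster_size",
                                       "driving_baits"])
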