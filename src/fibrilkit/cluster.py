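"""Single-linkage clustering of trajectory frames at an RMSD cutoff.

This is the receptor-selection stage: frames from the tail of a simulation are
grouped by pairwise RMSD, and the centroid of the most populated cluster is
handed to ensemble docking as the receptor conformation.

Two frames belong to one cluster when they are connected by a path of frame
pairs whose RMSD is strictly below the cutoff — the semantics of the classic
GROMACS linkage clustering.  The centroid of a cluster is its member with the
minimum mean RMSD to all other members (ties broken by the lowest frame
index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import RMSDMatrix

__all__ = ["ClusterResult", "linkage_cluster", "cluster_centroid"]


@dataclass(frozen=True)
class ClusterResult:
    """Frame partition with the docking-receptor centroid.

    ``labels[k]`` is the cluster id of the k-th frame of the matrix; cluster
    ids are assigned by decreasing cluster size (ties by lowest member frame
    index), so cluster 0 is always the most populated.  ``centroid_index``
    is a frame index (in the matrix's own frame numbering) belonging to
    cluster 0.
    """

    labels: np.ndarray
    sizes: np.ndarray
    centroid_index: int

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("cluster sizes must sum to the frame count")
        if self.labels[self.centroid_index_local] != 0:
            raise ValueError("centroid must belong to the largest cluster")

    @property
    def centroid_index_local(self) -> int:
        # centroid_index is stored in matrix-local numbering
        return int(self.centroid_index)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def linkage_cluster(rmsd_matrix: RMSDMatrix, cutoff: float) -> ClusterResult:
    """Partition frames into single-linkage clusters at a strict RMSD cutoff.

    Parameters
    ----------
    rmsd_matrix
        All-vs-all frame RMSD matrix in nm.
    cutoff
        Linkage threshold in nm; a pair links its frames iff
        ``rmsd < cutoff`` (strictly).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    v = rmsd_matrix.values
    n = v.shape[0]
    adj = (v < cutoff) & ~np.eye(n, dtype=bool)
    _, comp = connected_components(csr_matrix(adj), directed=False)

    comp_ids = np.unique(comp)
    members = {c: np.flatnonzero(comp == c) for c in comp_ids}
    # order clusters by decreasing size; ties by lowest member frame index
    order = sorted(comp_ids, key=lambda c: (-len(members[c]), members[c].min()))
    relabel = {c: k for k, c in enumerate(order)}
    labels = np.array([relabel[c] for c in comp], dtype=int)
    sizes = np.array([len(members[c]) for c in order], dtype=int)
    centroid = cluster_centroid(rmsd_matrix, np.flatnonzero(labels == 0))
    return ClusterResult(labels=labels, sizes=sizes, centroid_index=centroid)


def cluster_centroid(rmsd_matrix: RMSDMatrix, member_indices: np.ndarray) -> int:
    """The member with minimum mean RMSD to the other members.

    A singleton cluster's centroid is its single member; exact ties go to
    the lowest frame index (argmin's first-hit rule on sorted members).
    """
    members = np.sort(np.asarray(member_indices, dtype=int))
    if members.size == 0:
        raise ValueError("empty member set has no centroid")
    if members.size == 1:
        return int(members[0])
    sub = rmsd_matrix.values[np.ix_(members, members)]
    mean_rmsd = sub.sum(axis=1) / (members.size - 1)
    return int(members[np.argmin(mean_rmsd)])
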