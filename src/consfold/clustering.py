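"""Iterative density clustering of conformation ensembles.

Density of a model is its count of RMSD-neighbors within a threshold;
the iteration alternates density computation and removal of low-density
outliers until stable, then groups survivors by single linkage at the
same threshold.  Clusters are ranked by size and represented by their
maximum-density member (the centroid).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from consfold.structcore import Ensemble, Model, kabsch_superimpose

OUTLIER = -1


@dataclass
class ClusterResult:
    """Assignments, densities, ranked clusters and their centroids.

    ``assignments[i]`` is the rank of model i's cluster (0 = largest) or
    -1 for outliers removed during iteration.  ``clusters`` lists member
    indices per rank; ``centroids`` one member index per rank.
    """

    assignments: np.ndarray
    densities: np.ndarray
    clusters: list[list[int]]
    centroids: list[int]
    rmsd_threshold: float
    iterations: int
    ensemble: Ensemble | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def write(self, path: str | Path) -> None:
        lines = [f"# rmsd_threshold\t{self.rmsd_threshold!r}",
                 f"# iterations\t{self.iterations}",
                 f"# sizes\t{','.join(str(len(c)) for c in self.clusters)}",
                 f"# centroids\t{','.join(str(c) for c in self.centroids)}",
                 "model\tcluster\tdensity"]
        for i, (a, d) in enumerate(zip(self.assignments, self.densities)):
            lines.append(f"{i}\t{int(a)}\t{int(d)}")
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_rmsd_matrix(ensemble: Ensemble) -> np.ndarray:
    """Symmetric matrix of pairwise CA Kabsch RMSDs (zero diagonal)."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 models")
    cas = [m.ca_coords() for m in ensemble]
    n = len(cas)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superimpose(cas[i], cas[j])
            mat[i, j] = mat[j, i] = r
    return mat


def iterative_density_cluster(ensemble: Ensemble, rmsd_threshold: float = 2.0,
                              min_density: int = 2, max_iter: int = 50,
                              rmsd_matrix: np.ndarray | None = None
                              ) -> ClusterResult:
    """Cycle density computation and outlier removal, then cluster.

    density(i) = number of surviving j != i with rmsd(i, j) <= threshold.
    Models with density < min_density are removed each iteration until no
    removal occurs (or max_iter).  Survivors are grouped by single linkage
    at the threshold; clusters rank by size, ties by lower mean
    intra-cluster RMSD, then lowest member index.  The centroid is the
    member of maximal density (ties: lowest mean RMSD to the cluster,
    then lowest index).  If everything is removed, an explicit empty
    result is returned.
    """
    n = len(ensemble)
    mat = pairwise_rmsd_matrix(ensemble) if rmsd_matrix is None else rmsd_matrix
    neighbor = (mat <= rmsd_threshold) & ~np.eye(n, dtype=bool)

    alive = np.ones(n, dtype=bool)
    iterations = 0
    while iterations < max_iter:
        dens = (neighbor & alive[None, :]).sum(axis=1)
        dens[~alive] = 0
        low = alive & (dens < min_density)
        iterations += 1
        if not low.any():
            break
        alive &= ~low

    densities = (neighbor & alive[None, :]).sum(axis=1)
    densities[~alive] = 0
    assignments = np.full(n, OUTLIER, dtype=int)
    if not alive.any():
        return ClusterResult(assignments, densities, [], [],
                             rmsd_threshold, iterations, ensemble)

    idx = np.nonzero(alive)[0]
    sub = neighbor[np.ix_(idx, idx)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    raw_clusters: list[list[int]] = [
        [int(idx[k]) for k in np.nonzero(labels == c)[0]] for c in range(n_comp)
    ]

    def mean_intra(members: list[int]) -> float:
        if len(members) < 2:
            return 0.0
        m = np.ix_(members, members)
        return float(mat[m].sum() / (len(members) * (len(members) - 1)))

    raw_clusters.sort(key=lambda c: (-len(c), mean_intra(c), min(c)))

    centroids: list[int] = []
    for rank, members in enumerate(raw_clusters):
        for i in members:
            assignments[i] = rank
        members_arr = np.array(members)

        def centroid_key(i: int):
            others = members_arr[members_arr != i]
            mean_r = float(mat[i, others].mean()) if len(others) else 0.0
            return (-densities[i], mean_r, i)

        centroids.append(min(members, key=centroid_key))

    return ClusterResult(assignments, densities, raw_clusters, centroids,
                         rmsd_threshold, iterations, ensemble)


def select_top(result: ClusterResult, k: int = 5) -> list[Model]:
    """Centroid models of the k largest clusters, in rank order."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if result.ensemble is None:
        raise ValueError("result carries no ensemble")
    return [result.ensemble[c] for c in result.centroids[:k]]
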