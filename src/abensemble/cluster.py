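"""Agglomerative clustering of model ensembles by loop RMSD.

This is the ensemble-reduction step: a large generative ensemble of heavy
chain models (typically 100) is clustered on the framework-aligned H3 loop
backbone RMSD and replaced by the cluster centers (typically 20), giving a
small, structurally diverse set suitable for ensemble docking.

The clustering is plain bottom-up agglomeration from singletons: at each
step the pair of clusters at minimal inter-cluster distance under the chosen
linkage (single = min, complete = max, average = unweighted mean of pairwise
member distances) is merged, until K clusters remain.  Ties on the merge
distance are broken deterministically by the smallest pair of minimum member
indices, so identical inputs always give identical partitions.  The center
of a cluster is its medoid: the member minimizing the summed distance to all
other members of that cluster, ties going to the member earliest in ensemble
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import RegionDefinition, loop_rmsd, pairwise_loop_distances
from .structure import BACKBONE_ATOMS, Ensemble, Structure

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "LINKAGES",
    "agglomerative_cluster",
    "cluster_centers",
    "reduce_ensemble",
    "sweep_reduction",
]

logger = logging.getLogger(__name__)

LINKAGES = ("single", "average", "complete")

SYMMETRY_TOL = 1e-6


@dataclass
class DistanceMatrix:
    """Labelled symmetric non-negative distance matrix (angstrom)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if np.any(np.abs(np.diag(self.values)) > SYMMETRY_TOL):
            raise ValidationError("non-zero diagonal")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("matrix is not symmetric within 1e-6")
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path, sep="\t")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))


@dataclass
class ClusterAssignment:
    """Partition of ensemble members into K clusters plus one medoid each."""

    n_clusters: int
    membership: dict[str, int]
    centers: dict[int, str]
    linkage: str

    def __post_init__(self) -> None:
        if self.linkage not in LINKAGES:
            raise ValidationError(f"linkage must be one of {LINKAGES}, got {self.linkage!r}")
        clusters = set(self.membership.values())
        if clusters != set(range(self.n_clusters)):
            raise ValidationError("cluster indices must be exactly 0..K-1, each non-empty")
        for ci, lab in self.centers.items():
            if self.membership.get(lab) != ci:
                raise ValidationError(f"center {lab!r} does not belong to cluster {ci}")

    def members_of(self, cluster: int) -> list[str]:
        return [lab for lab, ci in self.membership.items() if ci == cluster]

    def sizes(self) -> list[int]:
        return [len(self.members_of(c)) for c in range(self.n_clusters)]


def _linkage_update(linkage: str, d_im: float, d_jm: float, ni: int, nj: int) -> float:
    if linkage == "single":
        return min(d_im, d_jm)
    if linkage == "complete":
        return max(d_im, d_jm)
    # unweighted mean of all pairwise member distances (UPGMA)
    return (ni * d_im + nj * d_jm) / (ni + nj)


def _agglomerate(values: np.ndarray, k: int, linkage: str) -> list[list[int]]:
    """Merge singletons bottom-up until k clusters remain.

    Clusters are kept sorted by their minimum member index; the merge
    candidate search scans the upper triangle in row-major order, so distance
    ties resolve to the smallest (i, j) pair of minimum member labels.
    """
    n = len(values)
    clusters: list[list[int]] = [[i] for i in range(n)]
    D = values.astype(float).copy()
    while len(clusters) > k:
        m = len(clusters)
        work = D[:m, :m].copy()
        work[np.tril_indices(m)] = np.inf
        flat = int(np.argmin(work))
        i, j = divmod(flat, m)
        ni, nj = len(clusters[i]), len(clusters[j])
        for col in range(m):
            if col in (i, j):
                continue
            D[i, col] = D[col, i] = _linkage_update(linkage, D[i, col], D[j, col], ni, nj)
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        keep = [c for c in range(m) if c != j]
        D = D[np.ix_(keep, keep)]
    return clusters


def agglomerative_cluster(dist: DistanceMatrix, k: int, linkage: str = "complete") -> ClusterAssignment:
    """Cluster a distance matrix into exactly ``k`` clusters.

    Deterministic for identical inputs.  Cluster indices are ordered by
    descending size, ties by the smallest member index, so downstream
    ensemble outputs are stable.
    """
    n = len(dist)
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    clusters = _agglomerate(dist.values, k, linkage)
    order = sorted(range(len(clusters)), key=lambda c: (-len(clusters[c]), clusters[c][0]))
    membership = {
        dist.labels[m]: rank for rank, c in enumerate(order) for m in clusters[c]
    }
    assignment = ClusterAssignment(
        n_clusters=k, membership=membership, centers={}, linkage=linkage
    )
    assignment.centers = cluster_centers(dist, assignment)
    return assignment


def cluster_centers(dist: DistanceMatrix, assignment: ClusterAssignment) -> dict[int, str]:
    """Medoid of each cluster: minimal summed distance to cluster co-members.

    Ties are broken by ensemble order (position in ``dist.labels``);
    singleton clusters return their only member.
    """
    index = {lab: i for i, lab in enumerate(dist.labels)}
    centers: dict[int, str] = {}
    for ci in range(assignment.n_clusters):
        members = [lab for lab in dist.labels if assignment.membership.get(lab) == ci]
        if not members:
            raise ValidationError(f"cluster {ci} is empty")
        idx = [index[lab] for lab in members]
        sums = dist.values[np.ix_(idx, idx)].sum(axis=1)
        centers[ci] = members[int(np.argmin(sums))]
    return centers


def reduce_ensemble(
    ensemble: Ensemble,
    regions: RegionDefinition,
    loop: str = "H3",
    k: int = 20,
    linkage: str = "complete",
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    return_assignment: bool = False,
):
    """Reduce an ensemble to the ``k`` cluster-center structures.

    Composes :func:`pairwise_loop_distances`, :func:`agglomerative_cluster`
    and medoid extraction.  The returned ensemble holds the center structures
    in cluster-index order (largest cluster first).
    """
    if len(ensemble) < k:
        raise ValueError(f"ensemble of {len(ensemble)} members cannot yield {k} clusters")
    dist = pairwise_loop_distances(ensemble, regions, loop, atom_set)
    assignment = agglomerative_cluster(dist, k=k, linkage=linkage)
    logger.info(
        "reduced %d models to %d clusters (%s linkage); sizes %s",
        len(ensemble), k, linkage, assignment.sizes(),
    )
    index = {lab: i for i, lab in enumerate(ensemble.labels)}
    reduced = ensemble.subset([index[assignment.centers[c]] for c in range(k)])
    if return_assignment:
        return reduced, assignment
    return reduced


def sweep_reduction(
    ensemble: Ensemble,
    regions: RegionDefinition,
    loop: str,
    n_values: Sequence[int],
    k_values: Sequence[int],
    linkages: Sequence[str],
    reference: Structure,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
) -> pd.DataFrame:
    """Best-center loop RMSD versus reference over an (n, k, linkage) grid.

    For each combination the first ``n`` ensemble members (ensemble order)
    are reduced to ``k`` centers and the minimum loop RMSD over the centers
    against ``reference`` is reported, together with the pre-clustering
    minimum over the same ``n`` members (``all_min_rmsd``).  Combinations
    with ``k > n`` are skipped.
    """
    if max(n_values) > len(ensemble):
        raise ValueError(f"max n {max(n_values)} exceeds ensemble size {len(ensemble)}")
    rows = []
    for n in n_values:
        head = ensemble.subset(range(n))
        member_rmsds = [loop_rmsd(m, reference, regions, loop, atom_set) for m in head.members]
        all_min = float(min(member_rmsds))
        dist = pairwise_loop_distances(head, regions, loop, atom_set)
        for link in linkages:
            for k in k_values:
                if k > n:
                    continue
                assignment = agglomerative_cluster(dist, k=k, linkage=link)
                centers = [assignment.centers[c] for c in range(k)]
                idx = {lab: i for i, lab in enumerate(head.labels)}
                best = float(min(member_rmsds[idx[c]] for c in centers))
                rows.append(
                    {"n": n, "k": k, "linkage": link, "best_center_rmsd": best, "all_min_rmsd": all_min}
                )
    return pd.DataFrame(rows, columns=["n", "k", "linkage", "best_center_rmsd", "all_min_rmsd"])
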