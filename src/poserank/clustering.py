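"""Center-of-mass leader clustering of docked pose ensembles.

Each pose is reduced to its center of mass (COM).  Poses are visited in
ascending energy order (ties broken by pose index) and greedily assigned:
a pose joins the earliest-created cluster whose *representative* COM lies
within the cluster radius (default 4 Å), otherwise it founds a new cluster
with itself as representative.  Because seeding is energy-ordered, every
representative is automatically the lowest-energy member of its cluster.
Distances are Euclidean on the COM; the representative anchor is fixed (no
running-centroid update), so the partition is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pose_io import LigandPose, PoseEnsemble

log = logging.getLogger("poserank")


@dataclass(frozen=True)
class ClusteringParams:
    """Clustering knobs: cutoff radius (Å) and COM weighting."""

    radius: float = 4.0
    mass_weighted: bool = True
    #: only energy_ascending is supported; field kept for forward compatibility
    seed_order: str = "energy_ascending"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.seed_order != "energy_ascending":
            raise ValueError(f"unsupported seed_order: {self.seed_order!r}")


@dataclass(eq=False)
class PoseCluster:
    """A disjoint group of poses with its lowest-energy representative.

    ``n`` is the cluster population entering the entropy correction;
    ``e_min`` is the representative's (minimum) energy.
    """

    member_indices: frozenset[int]
    representative_index: int
    com_representative: np.ndarray
    n: int
    e_min: float
    e_mean: float
    #: member energies keyed by pose_index, for summaries (spread etc.)
    member_energies: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.com_representative = np.asarray(self.com_representative, dtype=float)
        if self.representative_index not in self.member_indices:
            raise ValueError("representative must be a member")
        if self.n != len(self.member_indices) or self.n < 1:
            raise ValueError("n must equal the member count and be >= 1")


def center_of_mass(pose: LigandPose, mass_weighted: bool = True) -> np.ndarray:
    """COM of a pose: mass-weighted mean of atom coordinates (or plain centroid)."""
    coords = pose.coords
    if not mass_weighted:
        return coords.mean(axis=0)
    w = pose.masses
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def _visit_order(ensemble: PoseEnsemble) -> list[LigandPose]:
    return sorted(ensemble.poses, key=lambda p: (p.energy, p.pose_index))


def cluster_poses(ensemble: PoseEnsemble, params: ClusteringParams | None = None) -> list[PoseCluster]:
    """Partition an ensemble into COM leader clusters.

    Returns clusters sorted by ``e_min`` ascending.  The partition is disjoint
    and exhaustive, and every member COM lies within ``params.radius`` of its
    cluster representative's COM.
    """
    params = params or ClusteringParams()
    if not ensemble.poses:
        raise ValueError("empty ensemble")

    coms = {p.pose_index: center_of_mass(p, params.mass_weighted) for p in ensemble.poses}
    reps: list[LigandPose] = []            # cluster representatives, creation order
    members: list[list[LigandPose]] = []
    rep_coms: list[np.ndarray] = []

    for pose in _visit_order(ensemble):
        com = coms[pose.pose_index]
        assigned = False
        for k, rep_com in enumerate(rep_coms):
            if np.linalg.norm(com - rep_com) <= params.radius:
                members[k].append(pose)
                assigned = True
                break
        if not assigned:
            reps.append(pose)
            members.append([pose])
            rep_coms.append(com)

    clusters = [
        PoseCluster(
            member_indices=frozenset(p.pose_index for p in group),
            representative_index=rep.pose_index,
            com_representative=rep_com,
            n=len(group),
            e_min=rep.energy,
            e_mean=float(np.mean([p.energy for p in group])),
            member_energies={p.pose_index: p.energy for p in group},
        )
        for rep, rep_com, group in zip(reps, rep_coms, members)
    ]
    clusters.sort(key=lambda c: (c.e_min, c.representative_index))
    return clusters


def partition_check(
    clusters: list[PoseCluster],
    ensemble: PoseEnsemble,
    params: ClusteringParams | None = None,
) -> bool:
    """Validate a clustering: disjoint, exhaustive, min-energy representatives,
    every member COM within radius of its representative COM.

    Returns False (with a logged reason) instead of raising.
    """
    params = params or ClusteringParams()
    energies = {p.pose_index: p.energy for p in ensemble.poses}
    coms = {p.pose_index: center_of_mass(p, params.mass_weighted) for p in ensemble.poses}

    covered: set[int] = set()
    for c in clusters:
        if covered & c.member_indices:
            log.warning("partition_check: clusters overlap on %s", covered & c.member_indices)
            return False
        covered |= c.member_indices
        e_min = min(energies[i] for i in c.member_indices)
        if energies[c.representative_index] != e_min or c.e_min != e_min:
            log.warning("partition_check: representative of cluster %s is not min-energy",
                        c.representative_index)
            return False
        rep_com = coms[c.representative_index]
        for i in c.member_indices:
            if np.linalg.norm(coms[i] - rep_com) > params.radius:
                log.warning("partition_check: pose %d outside radius of rep %d",
                            i, c.representative_index)
                return False
    if covered != set(energies):
        log.warning("partition_check: poses not covered: %s", set(energies) - covered)
        return False
    return True
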