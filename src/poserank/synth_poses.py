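"""Seeded generators of synthetic pose ensembles and toy receptors.

The ensemble generator plants a known cluster structure: cluster k gets
``cluster_sizes[k]`` poses whose COMs are ``center_k`` plus a displacement
drawn uniformly in a ball of radius ``scatter_max`` (rejection-sampled, hard
truncation).  In guarantee mode — centers pairwise separated by at least
2·radius + 0.5 Å and scatter_max ≤ radius/2 — leader clustering at that
radius provably recovers the planted partition: any two COMs in one cluster
are within 2·scatter_max ≤ radius of each other, and any two COMs in
different clusters are more than 2·radius − 2·scatter_max ≥ radius apart.

All randomness comes from one ``numpy.random.Generator`` derived from the
spec's seed; the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pose_io import AtomRecord, LigandPose, PoseEnsemble, ReceptorStructure

_BACKBONE_OFFSETS = {
    # rough backbone geometry relative to CA, Å
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
}


@dataclass
class SynthSpec:
    """Recipe for a planted-cluster synthetic ensemble.

    ``target_radius`` is the clustering radius the ensemble is built for;
    auto-placed centers respect the guarantee separation 2·radius + 0.5 Å.
    """

    cluster_sizes: list[int]
    cluster_centers: list[tuple[float, float, float]] | None = None
    target_radius: float = 4.0
    scatter_max: float = 2.0
    energy_base: list[float] | None = None
    energy_jitter_sd: float = 0.3
    atoms_per_pose: int = 8
    seed: int = 0
    ligand_id: str = "synthetic"
    #: enforce separation >= 2·radius + 0.5 and scatter <= radius/2
    guarantee_recovery: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def __post_init__(self) -> None:
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be non-empty with all sizes >= 1")
        if self.atoms_per_pose < 1:
            raise ValueError("atoms_per_pose must be >= 1")
        if self.scatter_max < 0:
            raise ValueError("scatter_max must be non-negative")
        if self.guarantee_recovery and self.scatter_max > self.target_radius / 2:
            raise ValueError(
                "guarantee mode requires scatter_max <= target_radius / 2 "
                f"({self.scatter_max} > {self.target_radius / 2})"
            )
        if self.energy_base is not None and len(self.energy_base) != self.n_clusters:
            raise ValueError("energy_base must have one entry per cluster")
        if self.cluster_centers is not None:
            if len(self.cluster_centers) != self.n_clusters:
                raise ValueError("cluster_centers must have one entry per cluster")
            if self.guarantee_recovery:
                min_sep = 2 * self.target_radius + 0.5
                centers = np.asarray(self.cluster_centers, dtype=float)
                for i in range(len(centers)):
                    for j in range(i + 1, len(centers)):
                        if np.linalg.norm(centers[i] - centers[j]) < min_sep:
                            raise ValueError(
                                f"centers {i} and {j} closer than guarantee "
                                f"separation {min_sep:.2f} Å"
                            )


def _auto_centers(n: int, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    # box sized so the expected packing is loose; grown on failure
    side = max(min_sep * 2.0, min_sep * np.ceil(n ** (1 / 3)) * 2.0)
    for _ in range(8):
        centers: list[np.ndarray] = []
        for _ in range(n * 200):
            cand = rng.uniform(-side / 2, side / 2, size=3)
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
                if len(centers) == n:
                    return np.array(centers)
        side *= 1.6
    raise ValueError(f"cannot place {n} centers with separation {min_sep:.2f} Å")


def _ball_sample(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Uniform point in the closed ball of the given radius (rejection)."""
    if radius == 0:
        return np.zeros(3)
    while True:
        v = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(v) <= radius:
            return v


def simulate_ensemble(spec: SynthSpec) -> tuple[PoseEnsemble, list[int]]:
    """Generate a planted-cluster ensemble and its ground-truth labels.

    Returns ``(ensemble, labels)`` where ``labels[i]`` is the planted cluster
    of pose ``i`` (0-based, file order).  Atom coordinates are a rigid
    all-carbon template shifted so the realized COM equals the target COM.
    """
    rng = np.random.default_rng(spec.seed)
    min_sep = 2 * spec.target_radius + 0.5
    if spec.cluster_centers is not None:
        centers = np.asarray(spec.cluster_centers, dtype=float)
    else:
        centers = _auto_centers(spec.n_clusters, min_sep, rng)

    e_base = spec.energy_base if spec.energy_base is not None else [
        -9.0 + 0.5 * k for k in range(spec.n_clusters)
    ]

    # rigid template, COM at the origin (all carbon -> equal weights)
    template = rng.uniform(-1.5, 1.5, size=(spec.atoms_per_pose, 3))
    template -= template.mean(axis=0)

    poses: list[LigandPose] = []
    labels: list[int] = []
    pose_index = 0
    for k, size in enumerate(spec.cluster_sizes):
        for _ in range(size):
            pose_index += 1
            com = centers[k] + _ball_sample(rng, spec.scatter_max)
            energy = float(e_base[k] + spec.energy_jitter_sd * rng.standard_normal())
            atoms = [
                AtomRecord(name=f"C{i + 1}", element="C", coord=template[i] + com)
                for i in range(spec.atoms_per_pose)
            ]
            poses.append(LigandPose(pose_index, atoms, energy, source_label=spec.ligand_id))
            labels.append(k)
    return PoseEnsemble(spec.ligand_id, poses), labels


def make_toy_receptor(
    residues: list[tuple[str, int, tuple[float, float, float]]],
    chain_id: str = "A",
    structure_id: str = "toy",
) -> tuple[ReceptorStructure, str]:
    """Build a minimal receptor: N/CA/C/O backbone per residue, CA as given.

    ``residues`` is a list of (three_letter_code, residue_number, ca_coord).
    Returns the structure and its serialization as valid PDB text.
    """
    numbers = [num for _, num, _ in residues]
    if len(set(numbers)) != len(numbers):
        raise ValueError("duplicate residue number in one chain")

    atoms: list[AtomRecord] = []
    pdb_lines: list[str] = []
    serial = 0
    for resname, resnum, ca in residues:
        ca = np.asarray(ca, dtype=float)
        for atom_name in ("N", "CA", "C", "O"):
            serial += 1
            coord = ca + _BACKBONE_OFFSETS[atom_name]
            element = atom_name[0]
            atoms.append(
                AtomRecord(
                    name=atom_name,
                    element=element,
                    coord=coord,
                    residue_name=resname,
                    residue_number=resnum,
                    chain_id=chain_id,
                )
            )
            # PDB fixed columns: name in 13-16 (leading space for 1-char
            # elements), altLoc 17, resName 18-20, chain 22, resSeq 23-26
            pdb_lines.append(
                f"ATOM  {serial:>5}  {atom_name:<3} {resname:>3} {chain_id}"
                f"{resnum:>4}    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"  1.00  0.00          {element:>2}"
            )
    pdb_lines.append("END")
    return ReceptorStructure(atoms=atoms, structure_id=structure_id), "\n".join(pdb_lines) + "\n"
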