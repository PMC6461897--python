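"""Shared fixtures: PDBQT text builders, toy receptors, and an independent
naive leader-clustering oracle used to cross-check the implementation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from poserank import AtomRecord, LigandPose, PoseEnsemble


# ---------------------------------------------------------------------------
# PDBQT fixture builders
# ---------------------------------------------------------------------------

def pdbqt_atom_line(serial: int, name: str, x: float, y: float, z: float,
                    ad_type: str = "C") -> str:
    """A fixed-column PDBQT ATOM line (atom type in cols 78-79)."""
    return (
        f"ATOM  {serial:>5}  {name:<3} LIG A   1    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  0.00  0.00    +0.000 {ad_type:<2}"
    )


def make_pdbqt(models: list[tuple[float, list[tuple[str, float, float, float]]]]) -> str:
    """Vina-style multi-MODEL text: [(energy, [(atom_name, x, y, z), ...]), ...]."""
    lines = []
    for i, (energy, atoms) in enumerate(models, start=1):
        lines.append(f"MODEL {i}")
        lines.append(f"REMARK VINA RESULT:    {energy:8.3f}      0.000      0.000")
        lines.append("ROOT")
        for serial, (name, x, y, z) in enumerate(atoms, start=1):
            lines.append(pdbqt_atom_line(serial, name, x, y, z))
        lines.append("ENDROOT")
        lines.append("TORSDOF 0")
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_model_pdbqt(tmp_path):
    """Three poses with energies −7.9 / −7.5 / −6.0, two atoms each."""
    text = make_pdbqt(
        [
            (-7.9, [("C1", 0.0, 0.0, 0.0), ("O1", 1.0, 0.0, 0.0)]),
            (-7.5, [("C1", 5.0, 0.0, 0.0), ("O1", 6.0, 0.0, 0.0)]),
            (-6.0, [("C1", 20.0, 0.0, 0.0), ("O1", 21.0, 0.0, 0.0)]),
        ]
    )
    path = tmp_path / "lig.pdbqt"
    path.write_text(text)
    return path


# ---------------------------------------------------------------------------
# pose/ensemble builders
# ---------------------------------------------------------------------------

def single_atom_pose(pose_index: int, com: tuple[float, float, float],
                     energy: float, element: str = "C") -> LigandPose:
    """A 1-atom pose whose COM is exactly the atom coordinate."""
    return LigandPose(pose_index, [AtomRecord("C1", element, com)], energy)


def point_ensemble(coms: list[tuple[float, float, float]], energies: list[float],
                   ligand_id: str = "toy") -> PoseEnsemble:
    poses = [single_atom_pose(i + 1, com, e)
             for i, (com, e) in enumerate(zip(coms, energies))]
    return PoseEnsemble(ligand_id, poses)


def random_point_ensemble(rng: np.random.Generator, n_max: int = 12,
                          box: float = 8.0) -> PoseEnsemble:
    n = int(rng.integers(1, n_max + 1))
    coms = [tuple(rng.uniform(-box, box, size=3)) for _ in range(n)]
    energies = list(np.round(rng.uniform(-10.0, -2.0, size=n), 3))
    return point_ensemble(coms, energies)


# ---------------------------------------------------------------------------
# independent leader-clustering oracle (plain loops, no package imports)
# ---------------------------------------------------------------------------

def naive_leader(items: list[tuple[int, tuple[float, float, float], float]],
                 radius: float) -> list[tuple[int, frozenset[int]]]:
    """Step-by-step leader rule on (pose_index, com, energy) triples.

    Visit in ascending (energy, pose_index); join the earliest cluster whose
    leader is within radius, else found a new one.  Returns
    [(leader_index, member_set), ...] sorted by leader energy then index.
    """
    order = sorted(items, key=lambda t: (t[2], t[0]))
    clusters: list[dict] = []
    for idx, com, energy in order:
        placed = False
        for cl in clusters:
            lx, ly, lz = cl["com"]
            d = math.sqrt((com[0] - lx) ** 2 + (com[1] - ly) ** 2 + (com[2] - lz) ** 2)
            if d <= radius:
                cl["members"].add(idx)
                placed = True
                break
        if not placed:
            clusters.append({"leader": idx, "com": com, "energy": energy,
                             "members": {idx}})
    clusters.sort(key=lambda c: (c["energy"], c["leader"]))
    return [(c["leader"], frozenset(c["members"])) for c in clusters]


@pytest.fixture
def oracle():
    return naive_leader
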