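"""Readers and writers for docked-pose ensembles, receptors and reports.

Formats handled:

* multi-MODEL PDBQT ligand output (AutoDock Vina style, one ``REMARK VINA
  RESULT`` energy line per MODEL block),
* a plain TSV pose-table dialect used for synthetic/toy ensembles,
* receptor PDB files (via :mod:`gemmi`),
* rescoring reports as TSV or JSON.

Coordinates are Å, right-handed, stored exactly as read — no recentering.
Energies are kcal/mol with the docking sign convention (more negative =
more favorable) preserved verbatim.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger("poserank")

# ---------------------------------------------------------------------------
# element masses
# ---------------------------------------------------------------------------

#: Standard atomic weights (Da), abridged.  Docking files rarely contain
#: anything outside this set; unknown elements fall back to carbon (logged),
#: because PDBQT atom typing is nonstandard and must not abort a run.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "SI": 28.085, "P": 30.974,
    "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938,
    "FE": 55.845, "ZN": 65.38, "BR": 79.904, "I": 126.904,
}

#: AutoDock atom types that are not plain element symbols.
_AD_TYPE_TO_ELEMENT = {
    "A": "C",            # aromatic carbon
    "NA": "N", "NS": "N",
    "OA": "O", "OS": "O",
    "SA": "S",
    "HD": "H", "HS": "H",
}


def element_mass(element: str) -> float:
    """Mass in Da for an element symbol; unknown symbols get carbon's mass."""
    m = ATOMIC_MASSES.get(element.strip().upper())
    if m is None:
        log.warning("unknown element %r: using carbon mass", element)
        return ATOMIC_MASSES["C"]
    return m


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AtomRecord:
    """One atom: name, element, coordinate (Å) and mass (Da).

    Receptor atoms additionally carry residue/chain metadata; ligand atoms
    leave those fields as ``None``.
    """

    name: str
    element: str
    coord: np.ndarray
    mass: float | None = None
    residue_name: str | None = None
    residue_number: int | None = None
    chain_id: str | None = None
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite components")
        if self.mass is None:
            self.mass = element_mass(self.element)
        if self.mass <= 0:
            raise ValueError(f"atom {self.name!r}: mass must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtomRecord):
            return NotImplemented
        return (
            self.name == other.name
            and self.element == other.element
            and np.array_equal(self.coord, other.coord)
            and self.mass == other.mass
        )


@dataclass(eq=False)
class LigandPose:
    """One docked conformation: atoms plus a scalar binding energy (kcal/mol)."""

    pose_index: int
    atoms: list[AtomRecord]
    energy: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.pose_index < 1:
            raise ValueError("pose_index must be >= 1")
        if not self.atoms:
            raise ValueError(f"pose {self.pose_index}: no atoms")
        if not np.isfinite(self.energy):
            raise ValueError(f"pose {self.pose_index}: energy must be finite")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.coord for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LigandPose):
            return NotImplemented
        return (
            self.pose_index == other.pose_index
            and self.energy == other.energy
            and self.atoms == other.atoms
        )


@dataclass(eq=False)
class PoseEnsemble:
    """All poses of one ligand from one docking campaign."""

    ligand_id: str
    poses: list[LigandPose]
    #: set True to permit poses with differing atom counts / name sequences
    allow_heterogeneous: bool = False

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError(f"ensemble {self.ligand_id!r}: no poses")
        idx = [p.pose_index for p in self.poses]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError(
                f"ensemble {self.ligand_id!r}: pose_index must be unique and increasing"
            )
        if not self.allow_heterogeneous:
            ref = [a.name for a in self.poses[0].atoms]
            for p in self.poses[1:]:
                names = [a.name for a in p.atoms]
                if names != ref:
                    raise ValueError(
                        f"ensemble {self.ligand_id!r}: pose {p.pose_index} atom "
                        "names differ from pose 1 (set allow_heterogeneous to override)"
                    )

    def __len__(self) -> int:
        return len(self.poses)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseEnsemble):
            return NotImplemented
        return self.ligand_id == other.ligand_id and self.poses == other.poses


@dataclass
class ReceptorStructure:
    """Receptor atoms with chain/residue metadata, in file order."""

    atoms: list[AtomRecord]
    structure_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str | None, int | None]] = set()
        prev: tuple[str | None, int | None] | None = None
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if key != prev:
                if key in seen:
                    raise ValueError(f"residue group {key} not contiguous in file order")
                seen.add(key)
                prev = key


class ParseError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# PDBQT multi-pose parsing
# ---------------------------------------------------------------------------

_VINA_RESULT_RE = re.compile(r"^REMARK\s+VINA\s+RESULT", re.IGNORECASE)
_NUMBER_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _pdbqt_element(line: str) -> str:
    """Element from a PDBQT ATOM/HETATM line (AutoDock type in cols 78-79)."""
    ad_type = line[77:79].strip() if len(line) > 77 else ""
    if ad_type in _AD_TYPE_TO_ELEMENT:
        return _AD_TYPE_TO_ELEMENT[ad_type]
    if ad_type.upper() in ATOMIC_MASSES:
        return ad_type.capitalize() if len(ad_type) > 1 else ad_type.upper()
    # fall back to the first alphabetic character of the atom name
    name = line[12:16].strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed coordinate field: {line.rstrip()!r}") from exc
    return AtomRecord(
        name=line[12:16].strip(),
        element=_pdbqt_element(line),
        coord=(x, y, z),
        is_hetatm=line.startswith("HETATM"),
    )


def read_pdbqt_poses(path: str | Path, ligand_id: str) -> PoseEnsemble:
    """Parse a Vina-style multi-MODEL PDBQT file into a :class:`PoseEnsemble`.

    Each MODEL/ENDMDL block becomes one pose, in file order; the pose energy
    is the first numeric token on the block's ``REMARK VINA RESULT`` line.
    A file with no MODEL blocks is accepted as a single pose if (and only if)
    it carries an energy REMARK.
    """
    path = Path(path)
    text = path.read_text()
    blocks: list[tuple[int, list[tuple[int, str]]]] = []  # (model_no, lines)
    current: list[tuple[int, str]] | None = None
    preamble: list[tuple[int, str]] = []
    model_no = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            model_no += 1
            current = []
            blocks.append((model_no, current))
        elif rec == "ENDMDL":
            current = None
        elif current is not None:
            current.append((lineno, line))
        else:
            preamble.append((lineno, line))

    if not blocks:
        blocks = [(1, preamble)]

    poses: list[LigandPose] = []
    for model_no, lines in blocks:
        energy: float | None = None
        atoms: list[AtomRecord] = []
        for lineno, line in lines:
            if _VINA_RESULT_RE.match(line):
                m = _NUMBER_RE.search(line[line.upper().index("RESULT") + 6:])
                if not m:
                    raise ParseError(f"MODEL {model_no}: energy REMARK has no numeric field")
                energy = float(m.group())
            elif line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_line(line, lineno))
        if energy is None:
            raise ParseError(f"MODEL {model_no}: missing VINA RESULT energy REMARK")
        if not atoms:
            raise ParseError(f"MODEL {model_no}: no atoms")
        poses.append(LigandPose(model_no, atoms, energy, source_label=ligand_id))
    return PoseEnsemble(ligand_id, poses)


# ---------------------------------------------------------------------------
# pose-table dialect (TSV)
# ---------------------------------------------------------------------------

POSE_TABLE_COLUMNS = ("ligand_id", "pose_id", "energy", "atom_name", "element", "x", "y", "z")


def write_pose_table(ensemble: PoseEnsemble, path: str | Path) -> None:
    """Write an ensemble as TSV, one row per atom, full float precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# poserank pose table\n")
        fh.write("\t".join(POSE_TABLE_COLUMNS) + "\n")
        for pose in ensemble.poses:
            for atom in pose.atoms:
                fh.write(
                    "\t".join(
                        [
                            ensemble.ligand_id,
                            str(pose.pose_index),
                            repr(pose.energy),
                            atom.name,
                            atom.element,
                            repr(float(atom.coord[0])),
                            repr(float(atom.coord[1])),
                            repr(float(atom.coord[2])),
                        ]
                    )
                    + "\n"
                )


def read_pose_table(path: str | Path) -> PoseEnsemble:
    """Read the TSV pose dialect written by :func:`write_pose_table`."""
    path = Path(path)
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = set(POSE_TABLE_COLUMNS) - set(header)
            if missing:
                raise ParseError(f"pose table missing columns: {sorted(missing)}")
            continue
        if len(fields) != len(header):
            raise ParseError(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
        rows.append(dict(zip(header, fields)))
    if header is None or not rows:
        raise ParseError("no poses in pose table")

    ligand_ids = {r["ligand_id"] for r in rows}
    if len(ligand_ids) != 1:
        raise ParseError(f"pose table mixes ligand ids: {sorted(ligand_ids)}")
    ligand_id = ligand_ids.pop()

    by_pose: dict[int, list[dict[str, str]]] = {}
    for r in rows:
        by_pose.setdefault(int(r["pose_id"]), []).append(r)

    poses: list[LigandPose] = []
    for pose_id in sorted(by_pose):
        group = by_pose[pose_id]
        energies = {float(r["energy"]) for r in group}
        if len(energies) != 1:
            raise ParseError(f"pose {pose_id}: conflicting energies {sorted(energies)}")
        atoms = [
            AtomRecord(
                name=r["atom_name"],
                element=r["element"],
                coord=(float(r["x"]), float(r["y"]), float(r["z"])),
            )
            for r in group
        ]
        poses.append(LigandPose(pose_id, atoms, energies.pop(), source_label=ligand_id))
    return PoseEnsemble(ligand_id, poses)


# ---------------------------------------------------------------------------
# receptor PDB
# ---------------------------------------------------------------------------

def read_receptor_pdb(path: str | Path) -> ReceptorStructure:
    """Read a receptor PDB.

    ATOM records are retained with chain/residue metadata; HETATM records are
    retained but flagged.  For alternate locations only the first conformer is
    kept (dropped copies are logged).
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: not parseable as PDB: {exc}") from exc
    n_before = sum(len(res) for model in st for chain in model for res in chain)
    st.remove_alternative_conformations()
    n_after = sum(len(res) for model in st for chain in model for res in chain)
    if n_after < n_before:
        log.info("%s: dropped %d alternate-location atoms", path.name, n_before - n_after)

    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise ParseError(f"{path}: no ATOM records")
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=atom.element.name,
                        coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        is_hetatm=res.het_flag == "H",
                    )
                )
    if not any(not a.is_hetatm for a in atoms):
        raise ParseError(f"{path}: no ATOM records")
    return ReceptorStructure(atoms=atoms, structure_id=st.name or path.stem)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "ligand_id", "cluster_rank", "n_poses", "representative_pose",
    "e_min", "e_mean", "delta_g", "com_x", "com_y", "com_z",
)


def _report_rows(report) -> list[dict]:
    rows = []
    for ligand_id, clusters in report.entries:
        for rank, sc in enumerate(clusters, start=1):
            rows.append(
                {
                    "ligand_id": ligand_id,
                    "cluster_rank": rank,
                    "n_poses": sc.n,
                    "representative_pose": sc.representative_index,
                    "e_min": round(sc.e_min, 4),
                    "e_mean": round(sc.e_mean, 4),
                    "delta_g": round(sc.delta_g, 4),
                    "com_x": round(float(sc.com_representative[0]), 4),
                    "com_y": round(float(sc.com_representative[1]), 4),
                    "com_z": round(float(sc.com_representative[2]), 4),
                }
            )
    return rows


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Serialize a rescoring report as TSV or JSON (4-decimal fixed precision)."""
    if not report.entries:
        raise ValueError("empty report")
    path = Path(path)
    rows = _report_rows(report)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for row in rows:
                fh.write(
                    "\t".join(
                        f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c])
                        for c in REPORT_COLUMNS
                    )
                    + "\n"
                )
    elif format == "json":
        payload = {"parameters": report.parameters, "clusters": rows}
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report_json(path: str | Path) -> dict:
    """Read back a JSON report (round-trip counterpart of :func:`write_report`)."""
    with Path(path).open() as fh:
        return json.load(fh)
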