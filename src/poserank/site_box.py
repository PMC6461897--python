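"""Cα-anchored cubic site boxes and COM membership tests.

A binding site is specified as a list of residues (e.g. the myristic-acid
contact residues of HNF4α: V178, S181, Q185, R226, L236, G237, M252, S256,
I259, Q345, I346).  Each residue contributes one axis-aligned cube centered
on its Cα atom, with a default edge of 15 Å.  A pose is "in the site" when
its center of mass lies inside the union of the cubes (closed boundary).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .clustering import center_of_mass
from .pose_io import LigandPose, ReceptorStructure

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class ResidueSpec:
    """A residue named by one-letter code + number, e.g. S181 (optionally A:S181)."""

    one_letter_code: str
    residue_number: int
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.one_letter_code not in ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid code {self.one_letter_code!r}")
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")

    def __str__(self) -> str:
        base = f"{self.one_letter_code}{self.residue_number}"
        return f"{self.chain_id}:{base}" if self.chain_id else base


_SPEC_RE = re.compile(r"^(?:([A-Za-z0-9]):)?([A-Z])(\d+)$")


def parse_residue_spec(text: str) -> ResidueSpec:
    """Parse 'V178' or 'A:V178' into a ResidueSpec."""
    m = _SPEC_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse residue spec {text!r} (expected e.g. V178 or A:V178)")
    chain, code, num = m.groups()
    return ResidueSpec(code, int(num), chain)


@dataclass(frozen=True)
class SiteBox:
    """Axis-aligned cube: center (a Cα coordinate, Å) and edge length (Å).

    Membership is the closed cube [center − edge/2, center + edge/2] per axis.
    """

    center: tuple[float, float, float]
    edge: float = 15.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("box edge must be positive")
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("box center must be a finite 3-vector")

    def contains(self, point: np.ndarray) -> bool:
        c = np.asarray(self.center, dtype=float)
        return bool(np.all(np.abs(np.asarray(point, dtype=float) - c) <= self.edge / 2.0))


def get_ca(receptor: ReceptorStructure, spec: ResidueSpec) -> np.ndarray:
    """Cα coordinate of the residue matching ``spec``.

    Verifies the residue's 3-letter name translates to the spec's one-letter
    code; errors on absence, identity mismatch, ambiguous chain, or missing CA.
    """
    groups: dict[tuple[str | None, int], list] = {}
    for a in receptor.atoms:
        if a.residue_number == spec.residue_number and not a.is_hetatm:
            if spec.chain_id is None or a.chain_id == spec.chain_id:
                groups.setdefault((a.chain_id, a.residue_number), []).append(a)
    if not groups:
        raise KeyError(f"residue not found: {spec}")
    if len(groups) > 1:
        chains = sorted(k[0] or "?" for k in groups)
        raise KeyError(f"residue {spec} is ambiguous across chains {chains}; give a chain id")
    atoms = next(iter(groups.values()))
    resname = atoms[0].residue_name or ""
    one = THREE_TO_ONE.get(resname.upper())
    if one != spec.one_letter_code:
        raise ValueError(
            f"identity mismatch for {spec}: structure has {resname} "
            f"{spec.residue_number}, spec says {ONE_TO_THREE[spec.one_letter_code]}"
        )
    for a in atoms:
        if a.name == "CA":
            return np.array(a.coord, dtype=float)
    raise ValueError(f"residue {spec} has no CA atom")


def build_site_boxes(
    receptor: ReceptorStructure, specs: list[ResidueSpec], edge: float = 15.0
) -> list[SiteBox]:
    """One Cα-centered cube per spec, in input order (default edge 15 Å)."""
    if edge <= 0:
        raise ValueError("box edge must be positive")
    boxes = []
    for spec in specs:
        try:
            ca = get_ca(receptor, spec)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"site box for {spec}: {exc}") from exc
        boxes.append(SiteBox(center=tuple(float(v) for v in ca), edge=edge, label=str(spec)))
    return boxes


def pose_in_site(pose: LigandPose, boxes: list[SiteBox], mass_weighted: bool = True) -> bool:
    """True iff the pose COM lies in the union of the boxes (closed cubes)."""
    if not boxes:
        raise ValueError("pose_in_site requires at least one box")
    com = center_of_mass(pose, mass_weighted)
    return any(box.contains(com) for box in boxes)
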