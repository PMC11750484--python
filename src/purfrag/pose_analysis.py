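"""Near-attack-configuration (NAC) classification of docked poses.

A serine hydrolase cleaves an ester or urethane bond by nucleophilic attack
of the catalytic serine oxygen on the carbonyl carbon, while the incipient
oxyanion is stabilised by two backbone N-H donors (the oxyanion hole).  A
docked pose is *productive* when its geometry is compatible with this
mechanism: the serine side-chain oxygen lies close to the carbonyl carbon
of the nearest cleavable bond, and both oxyanion-hole probe atoms lie close
to that bond's carbonyl oxygen.  Rigid-receptor docking is imprecise, so
the distance threshold defaults to a permissive 4.5 Angstrom, applied
inclusively to all three distances.

The ligand's chemistry (which bonds are cleavable) is taken from its
generated 2D structure, matched to the pose coordinates by heavy-atom
order; docking file formats do not preserve bond orders, so re-perceiving
bonds from coordinates would be less reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from rdkit import Chem

from .io_formats import LigandPose

__all__ = [
    "ReceptorStructure",
    "ActiveSiteSpec",
    "CleavableBond",
    "PoseClassification",
    "find_cleavable_bonds",
    "classify_pose",
    "summarize",
    "load_receptor",
]

DEFAULT_THRESHOLD = 4.5

_URETHANE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])[OX2][#6]")
_ESTER = Chem.MolFromSmarts("[#6;!$([#6]=[!#6])][CX3](=[OX1])[OX2][#6]")


class SiteResolutionError(KeyError):
    """An active-site atom could not be found in the receptor."""


@dataclass
class ReceptorStructure:
    """Receptor atoms indexed by (chain, residue number, atom name)."""

    name: str
    _atoms: dict[tuple[str, int, str], np.ndarray]

    def atom_coord(self, chain: str, resnum: int, atom_name: str) -> np.ndarray:
        key = (chain, resnum, atom_name)
        if key not in self._atoms:
            raise SiteResolutionError(
                f"atom {atom_name} of residue {chain}:{resnum} not found in receptor {self.name}"
            )
        return self._atoms[key]

    def has_atom(self, chain: str, resnum: int, atom_name: str) -> bool:
        return (chain, resnum, atom_name) in self._atoms


def load_receptor(path, name: str | None = None) -> ReceptorStructure:
    """Read a PDB receptor into an atom lookup table (first model only).

    ``path`` may be a filename or an open text handle.
    """
    parser = PDBParser(QUIET=True)
    if hasattr(path, "read"):
        structure = parser.get_structure(name or "receptor", path)
    else:
        structure = parser.get_structure(name or Path(path).stem, str(path))
    atoms: dict[tuple[str, int, str], np.ndarray] = {}
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            resnum = residue.id[1]
            for atom in residue:
                atoms[(chain.id, resnum, atom.get_name())] = np.asarray(atom.get_coord(), dtype=float)
    return ReceptorStructure(name or Path(path).stem, atoms)


@dataclass(frozen=True)
class ActiveSiteSpec:
    """Catalytic serine + oxyanion-hole residues of one receptor.

    ``serine`` is (chain, residue number); ``serine_o`` names the
    side-chain oxygen (OG for serine).  ``oxyanion_residues`` are exactly
    two (chain, residue number) locators whose backbone amide probes the
    carbonyl oxygen.  ``probe_atoms`` selects the probe: the backbone amide
    hydrogen (``backbone_H``) on protonated receptors, or the backbone
    nitrogen (``backbone_N``) otherwise.
    """

    serine: tuple[str, int]
    oxyanion_residues: tuple[tuple[str, int], tuple[str, int]]
    serine_o: str = "OG"
    probe_atoms: Literal["backbone_H", "backbone_N"] = "backbone_H"

    def resolve(self, receptor: ReceptorStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (serine O, probe1, probe2) coordinates, validating presence."""
        ser = receptor.atom_coord(*self.serine, self.serine_o)
        probe_name = "H" if self.probe_atoms == "backbone_H" else "N"
        probes = []
        for chain, resnum in self.oxyanion_residues:
            probes.append(receptor.atom_coord(chain, resnum, probe_name))
        return ser, probes[0], probes[1]


@dataclass(frozen=True)
class CleavableBond:
    """A hydrolysable urethane or ester bond, located by its carbonyl atoms."""

    kind: Literal["urethane", "ester"]
    carbonyl_c: int
    carbonyl_o: int


@dataclass
class PoseClassification:
    """NAC distances and verdict for one docked pose."""

    ligand_id: str
    pose_index: int
    bond: CleavableBond | None
    d_ser: float
    d_oxy1: float
    d_oxy2: float
    productive: bool
    no_bond: bool = False


def find_cleavable_bonds(ligand: Chem.Mol) -> list[CleavableBond]:
    """Locate every urethane (N-C(=O)-O-C) and ester (C-C(=O)-O-C) bond.

    The ester pattern requires a carbon substituent on the carbonyl carbon,
    so urethane linkages are never double-reported as esters.  Bonds are
    returned sorted by carbonyl-carbon index, each motif once.
    """
    bonds: dict[int, CleavableBond] = {}
    for match in ligand.GetSubstructMatches(_URETHANE):
        _, c, o, _, _ = match
        bonds.setdefault(c, CleavableBond("urethane", c, o))
    for match in ligand.GetSubstructMatches(_ESTER):
        _, c, o, _, _ = match
        bonds.setdefault(c, CleavableBond("ester", c, o))
    return [bonds[c] for c in sorted(bonds)]


def _map_pose_atoms(ligand: Chem.Mol, pose: LigandPose) -> dict[int, int]:
    """Map ligand heavy-atom indices to pose atom indices by element order.

    Requires the pose's heavy atoms to appear in the same order as the
    ligand graph's (the convention of every writer in this package and of
    tools that preserve input atom order).
    """
    lig_heavy = [a.GetIdx() for a in ligand.GetAtoms() if a.GetSymbol() != "H"]
    pose_heavy = pose.heavy_indices()
    if len(lig_heavy) != len(pose_heavy):
        raise ValueError(
            f"pose {pose.ligand_id}/{pose.pose_index}: heavy-atom count "
            f"{len(pose_heavy)} does not match ligand graph ({len(lig_heavy)})"
        )
    for li, pi in zip(lig_heavy, pose_heavy):
        if ligand.GetAtomWithIdx(li).GetSymbol() != pose.elements[pi]:
            raise ValueError(
                f"pose {pose.ligand_id}/{pose.pose_index}: element mismatch at "
                f"atom {pi} ({pose.elements[pi]} vs {ligand.GetAtomWithIdx(li).GetSymbol()})"
            )
    return dict(zip(lig_heavy, pose_heavy))


def classify_pose(
    pose: LigandPose,
    ligand: Chem.Mol,
    receptor: ReceptorStructure,
    site: ActiveSiteSpec,
    threshold: float = DEFAULT_THRESHOLD,
) -> PoseClassification:
    """Classify one docked pose as productive or non-productive.

    The cleavable bond is chosen as the one whose carbonyl carbon is
    nearest the catalytic serine oxygen; the pose is productive iff that
    distance *and* both probe-to-carbonyl-oxygen distances are all within
    ``threshold`` (inclusive).  A ligand without cleavable bonds is
    classified non-productive with the ``no_bond`` flag set.
    """
    ser_o, probe1, probe2 = site.resolve(receptor)
    bonds = find_cleavable_bonds(ligand)
    if not bonds:
        return PoseClassification(
            pose.ligand_id, pose.pose_index, None,
            math.inf, math.inf, math.inf, False, no_bond=True,
        )
    atom_map = _map_pose_atoms(ligand, pose)
    best: tuple[float, CleavableBond] | None = None
    for bond in bonds:
        d = float(np.linalg.norm(pose.coords[atom_map[bond.carbonyl_c]] - ser_o))
        if best is None or d < best[0]:
            best = (d, bond)
    d_ser, chosen = best
    o_coord = pose.coords[atom_map[chosen.carbonyl_o]]
    d_oxy1 = float(np.linalg.norm(o_coord - probe1))
    d_oxy2 = float(np.linalg.norm(o_coord - probe2))
    productive = max(d_ser, d_oxy1, d_oxy2) <= threshold
    return PoseClassification(
        pose.ligand_id, pose.pose_index, chosen, d_ser, d_oxy1, d_oxy2, productive
    )


def classifications_table(classifications: Sequence[PoseClassification]) -> pd.DataFrame:
    """Flatten classifications into the per-pose CSV layout."""
    return pd.DataFrame(
        [
            {
                "ligand": c.ligand_id,
                "pose": c.pose_index,
                "bond_kind": c.bond.kind if c.bond else "none",
                "d_ser": c.d_ser,
                "d_oxy1": c.d_oxy1,
                "d_oxy2": c.d_oxy2,
                "productive": c.productive,
            }
            for c in classifications
        ],
        columns=["ligand", "pose", "bond_kind", "d_ser", "d_oxy1", "d_oxy2", "productive"],
    )


def summarize(
    classifications: Sequence[PoseClassification],
    metadata: pd.DataFrame,
) -> dict:
    """Aggregate pose classifications for one enzyme.

    ``metadata`` must map ligand ids to at least ``isocyanate_class`` and
    ``has_ester`` columns (index or ``id`` column = ligand id).  Returns
    the overall productive percentage, the per-isocyanate-class productive
    percentages, the urethane share among productive poses of dual-bond
    (ester-containing) ligands, and the raw serine-carbonyl distances for
    histogramming.
    """
    if "id" in metadata.columns:
        metadata = metadata.set_index("id")
    ids = {c.ligand_id for c in classifications}
    missing = sorted(ids - set(metadata.index))
    if missing:
        raise KeyError(f"ligand ids missing from metadata: {missing}")

    n = len(classifications)
    n_prod = sum(c.productive for c in classifications)
    by_class: dict[str, list[PoseClassification]] = {}
    for c in classifications:
        by_class.setdefault(str(metadata.loc[c.ligand_id, "isocyanate_class"]), []).append(c)

    dual = [
        c
        for c in classifications
        if c.productive and bool(metadata.loc[c.ligand_id, "has_ester"])
    ]
    urethane_chosen = sum(1 for c in dual if c.bond and c.bond.kind == "urethane")

    return {
        "n_poses": n,
        "percent_productive": 100.0 * n_prod / n if n else float("nan"),
        "percent_productive_by_class": {
            cls: 100.0 * sum(c.productive for c in group) / len(group)
            for cls, group in sorted(by_class.items())
        },
        "percent_urethane_among_dual_productive": (
            100.0 * urethane_chosen / len(dual) if dual else float("nan")
        ),
        "d_ser_values": [c.d_ser for c in classifications if not c.no_bond],
    }
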