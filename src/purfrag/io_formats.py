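"""Structure-file readers and writers.

Writers cover MOL (V2000), SDF, MOL2 (TRIPOS, with a compact SYBYL atom
typer) and SMILES lists; MOL/SDF go through RDKit's native serialisers.
Readers cover MOL, SDF, MOL2 and multi-MODEL PDBQT.  PDBQT parsing is
deliberately coordinate-and-element only: docked poses contribute geometry,
while bond orders come from the generated oligomer the pose belongs to
(docking output formats do not store them reliably).

All coordinates are Angstrom; no transforms are applied on read or write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .enumerate import Oligomer

__all__ = [
    "LigandPose",
    "write_structures",
    "read_poses",
    "read_mol2",
    "mol_to_mol2_block",
]

SUPPORTED_FORMATS = ("mol", "mol2", "sdf", "smi")


class FormatError(ValueError):
    """Malformed structure file or unsupported format tag."""


@dataclass
class LigandPose:
    """One docked (or synthetic) ligand pose: elements + coordinates."""

    ligand_id: str
    pose_index: int
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom

    def heavy_indices(self) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el != "H"]


# --- MOL2 writing -----------------------------------------------------------

def _sybyl_atom_type(atom: Chem.Atom) -> str:
    """Minimal SYBYL typing sufficient for the elements this tool emits."""
    sym = atom.GetSymbol()
    if sym == "C":
        if atom.GetIsAromatic():
            return "C.ar"
        hyb = atom.GetHybridization()
        return {
            Chem.HybridizationType.SP: "C.1",
            Chem.HybridizationType.SP2: "C.2",
        }.get(hyb, "C.3")
    if sym == "N":
        if atom.GetIsAromatic():
            return "N.ar"
        if any(
            nbr.GetSymbol() == "C"
            and any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(nbr).GetSymbol() == "O"
                for b in nbr.GetBonds()
            )
            for nbr in atom.GetNeighbors()
        ):
            return "N.am"
        hyb = atom.GetHybridization()
        return {
            Chem.HybridizationType.SP: "N.1",
            Chem.HybridizationType.SP2: "N.2",
        }.get(hyb, "N.3")
    if sym == "O":
        return "O.2" if atom.GetHybridization() == Chem.HybridizationType.SP2 else "O.3"
    if sym == "H":
        return "H"
    if sym == "S":
        return "S.3"
    return sym


_MOL2_BOND = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "ar",
}


def mol_to_mol2_block(mol: Chem.Mol, name: str = "", conf_id: int = 0) -> str:
    """Serialise one conformer of a molecule as a TRIPOS MOL2 block."""
    if mol.GetNumConformers() == 0:
        raise FormatError(f"molecule {name!r} has no 3D coordinates to write")
    conf = mol.GetConformer(conf_id)
    lines = [
        "@<TRIPOS>MOLECULE",
        name or "UNNAMED",
        f"{mol.GetNumAtoms():>5} {mol.GetNumBonds():>5}     1     0     0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        lines.append(
            f"{atom.GetIdx() + 1:>7} {atom.GetSymbol() + str(atom.GetIdx() + 1):<8}"
            f"{pos.x:>10.4f}{pos.y:>10.4f}{pos.z:>10.4f} "
            f"{_sybyl_atom_type(atom):<8}     1  LIG1        0.0000"
        )
    lines.append("@<TRIPOS>BOND")
    for i, bond in enumerate(mol.GetBonds(), 1):
        lines.append(
            f"{i:>6}{bond.GetBeginAtomIdx() + 1:>6}{bond.GetEndAtomIdx() + 1:>6} "
            f"{_MOL2_BOND.get(bond.GetBondType(), '1'):>4}"
        )
    return "\n".join(lines) + "\n"


# --- MOL2 reading -----------------------------------------------------------

def _parse_mol2_block(lines: list[str], source: str) -> Chem.Mol:
    section = None
    natoms = nbonds = None
    atoms: list[tuple[str, float, float, float]] = []
    bonds: list[tuple[int, int, str]] = []
    counts_line = None
    body: list[str] = []
    for raw in lines:
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            body = []
            continue
        if section == "MOLECULE":
            body.append(line)
            if len(body) == 2:
                counts_line = line
                parts = line.split()
                natoms, nbonds = int(parts[0]), int(parts[1])
        elif section == "ATOM" and line.strip():
            parts = line.split()
            sybyl = parts[5]
            element = sybyl.split(".")[0]
            element = element[0].upper() + element[1:].lower()
            atoms.append((element, float(parts[2]), float(parts[3]), float(parts[4])))
        elif section == "BOND" and line.strip():
            parts = line.split()
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1, parts[3]))
    if natoms is None or len(atoms) != natoms:
        raise FormatError(
            f"{source}: MOL2 atom count mismatch (header {natoms}, found {len(atoms)})"
        )
    rw = Chem.RWMol()
    conf = Chem.Conformer(natoms)
    for i, (element, x, y, z) in enumerate(atoms):
        rw.AddAtom(Chem.Atom(element))
        conf.SetAtomPosition(i, (x, y, z))
    bond_types = {
        "1": Chem.BondType.SINGLE,
        "2": Chem.BondType.DOUBLE,
        "3": Chem.BondType.TRIPLE,
        "am": Chem.BondType.SINGLE,
        "ar": Chem.BondType.AROMATIC,
    }
    for a, b, kind in bonds:
        rw.AddBond(a, b, bond_types.get(kind, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    except Exception:
        pass  # geometry-only consumers tolerate odd valence states
    return mol


def read_mol2(path: str | os.PathLike) -> list[Chem.Mol]:
    """Read every @<TRIPOS>MOLECULE block of a MOL2 file."""
    text = Path(path).read_text()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>MOLECULE"):
            current = []
            blocks.append(current)
        if current is not None:
            current.append(line)
    if not blocks:
        raise FormatError(f"{path}: no @<TRIPOS>MOLECULE block found")
    return [_parse_mol2_block(b, str(path)) for b in blocks]


# --- PDBQT reading ----------------------------------------------------------

_PDBQT_ELEMENTS = {
    "A": "C",  # aromatic carbon
    "C": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "HD": "H", "HS": "H", "H": "H",
    "S": "S", "SA": "S", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
}


def read_pdbqt_poses(path: str | os.PathLike, ligand_id: str | None = None) -> list[LigandPose]:
    """Parse a (multi-MODEL) AutoDock PDBQT file into poses.

    Only coordinates and elements are extracted; the AutoDock atom type in
    the final column determines the element.  A file without MODEL records
    is treated as a single pose.
    """
    lid = ligand_id or Path(path).stem
    poses: list[LigandPose] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    in_model = False

    def flush(index: int):
        nonlocal elements, coords
        if elements:
            poses.append(LigandPose(lid, index, elements, np.asarray(coords)))
        elements, coords = [], []

    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
            elif rec == "ENDMDL":
                flush(len(poses) + 1)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    adtype = line[77:79].strip() or line[12:16].strip()[0]
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"{path}:{lineno}: malformed atom record") from exc
                element = _PDBQT_ELEMENTS.get(adtype.upper())
                if element is None:
                    element = adtype[0].upper()
                elements.append(element)
                coords.append((x, y, z))
    flush(len(poses) + 1)
    if not poses:
        raise FormatError(f"{path}: no atom records found")
    return poses


def read_poses(path: str | os.PathLike, ligand_id: str | None = None) -> list[LigandPose]:
    """Read docked poses from a MOL2, SDF or PDBQT file (by extension)."""
    path = Path(path)
    lid = ligand_id or path.stem
    ext = path.suffix.lower()
    if ext == ".pdbqt":
        return read_pdbqt_poses(path, lid)
    if ext == ".mol2":
        mols = read_mol2(path)
    elif ext in (".sdf", ".mol"):
        mols = [
            m
            for m in Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
            if m is not None
        ]
        if not mols:
            raise FormatError(f"{path}: no molecule records found")
    else:
        raise FormatError(f"unsupported pose format {ext!r} for {path}")
    poses = []
    for i, mol in enumerate(mols, 1):
        conf = mol.GetConformer(0)
        poses.append(
            LigandPose(
                lid,
                i,
                [a.GetSymbol() for a in mol.GetAtoms()],
                conf.GetPositions(),
            )
        )
    return poses


# --- library output ---------------------------------------------------------

def _ensure_3d(mol: Chem.Mol, seed: int = 0xC0FFEE) -> Chem.Mol:
    if mol.GetNumConformers():
        return mol
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2**31)
    if AllChem.EmbedMolecule(molh, params) != 0:
        # distance-geometry occasionally fails on long chains; random-coordinate
        # initialisation is the standard fallback and stays seed-deterministic
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            raise FormatError(f"3D embedding failed for {Chem.MolToSmiles(mol)}")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
    return molh


def write_structures(
    oligomers: Sequence[Oligomer],
    out_dir: str | os.PathLike,
    formats: Iterable[str] = ("mol", "mol2"),
    seed: int = 0xC0FFEE,
) -> list[str]:
    """Write one structure file per oligomer per format; return the manifest.

    MOL files use the V2000 connection table; MOL2 files carry TRIPOS atom
    typing.  Molecules without 3D coordinates are embedded and
    force-field-optimised first (deterministic per seed).  Files are named
    ``<oligomer id>.<ext>``.
    """
    formats = list(formats)
    for fmt in formats:
        if fmt not in SUPPORTED_FORMATS:
            raise FormatError(
                f"unsupported format {fmt!r}; expected subset of {SUPPORTED_FORMATS}"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    need_3d = any(f in ("mol", "mol2", "sdf") for f in formats)
    for olig in oligomers:
        mol3d = _ensure_3d(olig.molecule, seed=seed) if need_3d else olig.molecule
        for fmt in formats:
            path = out_dir / f"{olig.id}.{fmt}"
            if fmt == "mol":
                Chem.MolToMolFile(mol3d, str(path))
            elif fmt == "sdf":
                with Chem.SDWriter(str(path)) as writer:
                    writer.write(mol3d)
            elif fmt == "mol2":
                path.write_text(mol_to_mol2_block(mol3d, name=olig.id))
            elif fmt == "smi":
                path.write_text(f"{olig.smiles}\t{olig.id}\n")
            manifest.append(str(path))
    return manifest


def write_conformers(
    conformer_set, out_dir: str | os.PathLike, fmt: str = "sdf"
) -> list[str]:
    """Write a ConformerSet as one SDF (all records) or numbered MOL2 files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = conformer_set.parent_id or "conformers"
    if fmt == "sdf":
        path = out_dir / f"{name}.sdf"
        with Chem.SDWriter(str(path)) as writer:
            for i in range(len(conformer_set)):
                writer.write(conformer_set.mol, confId=i)
        return [str(path)]
    if fmt == "mol2":
        paths = []
        for i in range(len(conformer_set)):
            path = out_dir / f"{name}_conf{i + 1:02d}.mol2"
            path.write_text(
                mol_to_mol2_block(conformer_set.mol, name=f"{name}_conf{i + 1:02d}", conf_id=i)
            )
            paths.append(str(path))
        return paths
    raise FormatError(f"unsupported conformer format {fmt!r}")
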