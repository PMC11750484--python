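"""Deterministic synthetic fixtures: minimal receptors, poses and monomer sets.

Everything here is synthetic scaffolding for testing the analysis path
without any external structure download.  The receptors are *not*
physically realistic proteins: they are three-residue stubs (a catalytic
serine plus two oxyanion-hole residues) whose probe atoms are placed at
exactly the requested distances from a real, 3D-embedded ligand.  They use
standard PDB residue and atom naming and are round-tripped through the
real PDB parser, so tests exercise the same code path as genuine
structures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_core import Monomer, parse_monomer
from .io_formats import LigandPose, mol_to_mol2_block
from .pose_analysis import (
    ActiveSiteSpec,
    ReceptorStructure,
    find_cleavable_bonds,
    load_receptor,
)

__all__ = ["SyntheticSite", "make_site_fixture", "make_monomer_set"]

#: one-urethane ligand used by the synthetic site (methyl N-methylcarbamate)
SITE_LIGAND_SMILES = "CNC(=O)OC"
_EMBED_SEED = 2024


@dataclass
class SyntheticSite:
    """A synthetic receptor/pose pair realising requested NAC distances."""

    receptor: ReceptorStructure
    pose: LigandPose
    ligand: Chem.Mol
    site: ActiveSiteSpec
    pdb_text: str
    requested: tuple[float, float, float]

    def pose_mol2(self) -> str:
        return mol_to_mol2_block(self.ligand, name=self.pose.ligand_id)


def _pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz: np.ndarray,
    element: str,
) -> str:
    pad_name = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {pad_name}{'':1}{resname:>3} {chain}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def make_site_fixture(
    d_ser: float,
    d_oxy1: float,
    d_oxy2: float,
    probe: str = "backbone_H",
    ligand_smiles: str = SITE_LIGAND_SMILES,
    ligand_id: str = "fixture_ligand",
) -> SyntheticSite:
    """Build a minimal receptor + one-urethane ligand pose with exact distances.

    The ligand is embedded in 3D; the serine OG is placed ``d_ser`` from
    the carbonyl carbon of its (single) cleavable bond, and the two
    oxyanion backbone probes ``d_oxy1``/``d_oxy2`` from the carbonyl
    oxygen, each along a different fixed axis.  Realised distances match
    the request to machine precision.  Backbone N atoms sit 1.01 Angstrom
    beyond each amide H, so switching the probe mode genuinely changes the
    measured distances.
    """
    for label, d in (("d_ser", d_ser), ("d_oxy1", d_oxy1), ("d_oxy2", d_oxy2)):
        if d < 0:
            raise ValueError(f"{label} must be non-negative, got {d}")

    mol = Chem.AddHs(Chem.MolFromSmiles(ligand_smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for fixture ligand {ligand_smiles}")
    AllChem.MMFFOptimizeMolecule(mol)
    bonds = find_cleavable_bonds(mol)
    if len(bonds) != 1:
        raise ValueError(
            f"fixture ligand {ligand_smiles} must contain exactly one cleavable bond"
        )
    conf = mol.GetConformer(0)
    # snap to PDB coordinate precision (3 decimals) so that receptor atoms
    # placed at ligand_atom + d * unit_axis realise d exactly after the
    # PDB round-trip (for d given to <= 3 decimals)
    coords = np.round(conf.GetPositions(), 3)
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, coords[i])
    c_xyz = coords[bonds[0].carbonyl_c]
    o_xyz = coords[bonds[0].carbonyl_o]

    u_ser = np.array([1.0, 0.0, 0.0])
    u_oxy1 = np.array([0.0, 1.0, 0.0])
    u_oxy2 = np.array([0.0, 0.0, 1.0])
    og = c_xyz + d_ser * u_ser
    h1 = o_xyz + d_oxy1 * u_oxy1
    h2 = o_xyz + d_oxy2 * u_oxy2
    n1 = o_xyz + (d_oxy1 + 1.01) * u_oxy1
    n2 = o_xyz + (d_oxy2 + 1.01) * u_oxy2

    far = c_xyz + np.array([20.0, 20.0, 20.0])  # inert backbone filler
    lines = ["HEADER    SYNTHETIC NAC FIXTURE"]
    serial = 0
    for name, resname, resnum, xyz, element in [
        ("N", "TYR", 60, n1, "N"),
        ("H", "TYR", 60, h1, "H"),
        ("CA", "TYR", 60, far + [0, 0, 1], "C"),
        ("C", "TYR", 60, far + [0, 0, 2], "C"),
        ("O", "TYR", 60, far + [0, 0, 3], "O"),
        ("N", "SER", 130, far + [1, 0, 0], "N"),
        ("CA", "SER", 130, far + [1, 0, 1], "C"),
        ("CB", "SER", 130, og + [0.0, 1.2, 0.0], "C"),
        ("OG", "SER", 130, og, "O"),
        ("C", "SER", 130, far + [1, 0, 2], "C"),
        ("O", "SER", 130, far + [1, 0, 3], "O"),
        ("N", "MET", 131, n2, "N"),
        ("H", "MET", 131, h2, "H"),
        ("CA", "MET", 131, far + [2, 0, 1], "C"),
        ("C", "MET", 131, far + [2, 0, 2], "C"),
        ("O", "MET", 131, far + [2, 0, 3], "O"),
    ]:
        serial += 1
        lines.append(_pdb_atom_line(serial, name, resname, "A", resnum, np.asarray(xyz), element))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    receptor = load_receptor(io.StringIO(pdb_text), name="synthetic_site")
    site = ActiveSiteSpec(
        serine=("A", 130),
        oxyanion_residues=(("A", 60), ("A", 131)),
        probe_atoms=probe,
    )
    pose = LigandPose(
        ligand_id=ligand_id,
        pose_index=1,
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
    )
    return SyntheticSite(
        receptor=receptor,
        pose=pose,
        ligand=mol,
        site=site,
        pdb_text=pdb_text,
        requested=(d_ser, d_oxy1, d_oxy2),
    )


def make_monomer_set(
    n_iso: int,
    n_iso_di: int,
    n_ol: int,
    n_ol_di: int,
    seed: int = 0,
) -> tuple[list[Monomer], list[Monomer]]:
    """Generate random aliphatic monomer sets with an exact functionality split.

    Monomers are straight-chain: monoisocyanates ``O=C=N(C)k``,
    diisocyanates ``O=C=N(C)kN=C=O``, alcohols ``O(C)k`` and diols
    ``OC(C)kCO``-style chains, with distinct chain lengths drawn without
    replacement from the seeded RNG, so each call is reproducible and free
    of duplicates.
    """
    for label, val in (
        ("n_iso", n_iso), ("n_iso_di", n_iso_di), ("n_ol", n_ol), ("n_ol_di", n_ol_di)
    ):
        if val < 0:
            raise ValueError(f"{label} must be non-negative, got {val}")
    if n_iso_di > n_iso or n_ol_di > n_ol:
        raise ValueError("difunctional counts cannot exceed totals")
    rng = np.random.default_rng(seed)

    def chain_lengths(n: int) -> list[int]:
        return sorted(int(k) for k in rng.choice(np.arange(1, max(30, 2 * n + 2)), size=n, replace=False))

    isos: list[Monomer] = []
    for i, k in enumerate(chain_lengths(n_iso - n_iso_di)):
        isos.append(parse_monomer("O=C=N" + "C" * k, "isocyanate", f"iso_mono_{i + 1}"))
    for i, k in enumerate(chain_lengths(n_iso_di)):
        isos.append(parse_monomer("O=C=N" + "C" * k + "N=C=O", "isocyanate", f"iso_di_{i + 1}"))
    ols: list[Monomer] = []
    for i, k in enumerate(chain_lengths(n_ol - n_ol_di)):
        ols.append(parse_monomer("O" + "C" * k, "alcohol", f"ol_mono_{i + 1}"))
    for i, k in enumerate(chain_lengths(n_ol_di)):
        ols.append(parse_monomer("OC" + "C" * k + "O", "alcohol", f"ol_di_{i + 1}"))
    return isos, ols
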