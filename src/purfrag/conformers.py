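"""Systematic conformer generation with diversity and energy filtering.

The generator drives every rotatable bond on a fixed torsion grid
(120-degree steps for ordinary single bonds, 180-degree steps for
conjugated/amide-like bonds), evaluates each state with the MMFF94 force
field, and greedily selects up to ``max_n`` low-energy conformers that are
mutually distinct by at least ``rmsd_cutoff`` on heavy atoms and lie within
``energy_window`` of the best state found.

Flexible oligomers explode combinatorially, so two guards keep the search
tractable: molecules with more than ``rotor_limit`` rotatable bonds fall
back to a single embedded, force-field-optimised conformer, and grids
larger than ``max_states`` are subsampled deterministically from the seeded
RNG.  Rigid molecules always yield exactly one conformer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign, rdMolTransforms

__all__ = ["ConformerSet", "generate_conformers", "EmbeddingError"]

DEFAULT_SEED = 0xC0FFEE

_ROTATABLE = Chem.MolFromSmarts(
    "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"
)
# bonds held at 2-fold torsion grids: amide/carbamate C-N and conjugated links
_AMIDE_LIKE = Chem.MolFromSmarts("[CX3](=[OX1])-[NX3]")


class EmbeddingError(RuntimeError):
    """3D embedding failed for a molecule."""


@dataclass
class ConformerSet:
    """Diverse 3D conformers of one parent molecule.

    ``mol`` carries the conformers as RDKit conformer records (with explicit
    hydrogens); ``energies`` are MMFF94 energies in kcal/mol, sorted
    ascending and aligned with conformer order.
    """

    parent_id: str
    mol: Chem.Mol
    energies: list[float]

    def __len__(self) -> int:
        return self.mol.GetNumConformers()

    def coordinates(self, i: int) -> np.ndarray:
        return self.mol.GetConformer(i).GetPositions()


def _torsion_atoms(mol: Chem.Mol, begin: int, end: int) -> tuple[int, int, int, int]:
    """Pick a deterministic a-b-c-d quartet around rotatable bond b-c."""
    b_nbrs = sorted(
        a.GetIdx()
        for a in mol.GetAtomWithIdx(begin).GetNeighbors()
        if a.GetIdx() != end
    )
    e_nbrs = sorted(
        a.GetIdx()
        for a in mol.GetAtomWithIdx(end).GetNeighbors()
        if a.GetIdx() != begin
    )
    return b_nbrs[0], begin, end, e_nbrs[0]


def _grid_for_bond(mol: Chem.Mol, begin: int, end: int) -> tuple[float, ...]:
    for match in mol.GetSubstructMatches(_AMIDE_LIKE):
        if {begin, end} == {match[0], match[2]}:
            return (0.0, 180.0)
    a, b = mol.GetAtomWithIdx(begin), mol.GetAtomWithIdx(end)
    if a.GetIsAromatic() or b.GetIsAromatic():
        return (0.0, 180.0)
    return (0.0, 120.0, 240.0)


def _heavy_rmsd(mol_noh: Chem.Mol, i: int, j: int) -> float:
    return rdMolAlign.GetBestRMS(mol_noh, mol_noh, prbId=i, refId=j, maxMatches=10000)


def generate_conformers(
    mol: Chem.Mol,
    max_n: int = 20,
    rmsd_cutoff: float = 0.5,
    energy_window: float = 50.0,
    rotor_limit: int = 8,
    max_states: int = 2000,
    seed: int = DEFAULT_SEED,
    parent_id: str = "",
) -> ConformerSet:
    """Generate up to ``max_n`` diverse conformers for one molecule.

    Parameters
    ----------
    mol:
        Molecule to embed (hydrogens are added internally).
    max_n:
        Maximum conformers to return (default 20).
    rmsd_cutoff:
        Minimum pairwise heavy-atom RMSD between returned conformers, in
        Angstrom (default 0.5).
    energy_window:
        Keep only states within this many kcal/mol of the best energy
        (default 50).
    rotor_limit:
        Above this many rotatable bonds the systematic search is skipped
        and a single embedded + optimised conformer is returned.
    max_states:
        Cap on torsion-grid states evaluated; larger grids are subsampled
        deterministically.
    seed:
        Seed for embedding and grid subsampling; fixed default so repeat
        runs are bit-identical.

    Raises
    ------
    EmbeddingError
        If RDKit cannot produce 3D coordinates for the molecule.
    """
    name = parent_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
    if mol.GetNumAtoms() == 0:
        raise EmbeddingError(f"cannot embed empty molecule {name!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2**31)
    try:
        ok = AllChem.EmbedMolecule(molh, params)
        if ok != 0:
            params.useRandomCoords = True
            ok = AllChem.EmbedMolecule(molh, params)
    except ValueError as exc:
        raise EmbeddingError(
            f"3D embedding failed for molecule {name or Chem.MolToSmiles(mol)!r}"
        ) from exc
    if ok != 0:
        raise EmbeddingError(f"3D embedding failed for molecule {name or Chem.MolToSmiles(mol)!r}")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=500)

    rot_bonds = [
        (b, e)
        for b, e in molh.GetSubstructMatches(_ROTATABLE)
        if molh.GetBondBetweenAtoms(b, e).GetBondType() == Chem.BondType.SINGLE
    ]
    # substructure matches report both directions; keep one per bond
    rot_bonds = sorted({tuple(sorted(p)) for p in rot_bonds})

    if not rot_bonds or len(rot_bonds) > rotor_limit:
        props = AllChem.MMFFGetMoleculeProperties(molh)
        ff = AllChem.MMFFGetMoleculeForceField(molh, props) if props else None
        energy = ff.CalcEnergy() if ff else 0.0
        return ConformerSet(parent_id=name, mol=molh, energies=[energy])

    quartets = [_torsion_atoms(molh, b, e) for b, e in rot_bonds]
    grids = [_grid_for_bond(molh, b, e) for b, e in rot_bonds]
    n_states = int(np.prod([len(g) for g in grids]))
    if n_states <= max_states:
        states = list(itertools.product(*grids))
    else:
        rng = np.random.default_rng(seed % (2**31))
        states = [
            tuple(g[i] for g, i in zip(grids, idx))
            for idx in {
                tuple(rng.integers(0, [len(g) for g in grids]))
                for _ in range(max_states)
            }
        ]
        states.sort()

    base_conf = molh.GetConformer(0)
    work = Chem.Mol(molh)
    props = AllChem.MMFFGetMoleculeProperties(work)
    scored: list[tuple[float, int]] = []
    for state in states:
        conf = Chem.Conformer(base_conf)
        for (a, b, c, d), angle in zip(quartets, state):
            rdMolTransforms.SetDihedralDeg(conf, a, b, c, d, angle)
        conf_id = work.AddConformer(conf, assignId=True)
        ff = AllChem.MMFFGetMoleculeForceField(work, props, confId=conf_id)
        if ff is None:
            continue
        scored.append((ff.CalcEnergy(), conf_id))
    scored.sort()

    # optimise the best candidates, then re-filter and pick a diverse subset
    n_candidates = min(len(scored), 3 * max_n)
    opt: list[tuple[float, int]] = []
    for _, conf_id in scored[:n_candidates]:
        ff = AllChem.MMFFGetMoleculeForceField(work, props, confId=conf_id)
        ff.Minimize(maxIts=200)
        opt.append((ff.CalcEnergy(), conf_id))
    opt.sort()

    best = opt[0][0]
    work_noh = Chem.RemoveHs(work)
    selected: list[tuple[float, int]] = []
    for energy, conf_id in opt:
        if energy - best > energy_window:
            continue
        if all(
            _heavy_rmsd(work_noh, conf_id, kept_id) >= rmsd_cutoff
            for _, kept_id in selected
        ):
            selected.append((energy, conf_id))
        if len(selected) == max_n:
            break

    out = Chem.Mol(molh)
    out.RemoveAllConformers()
    for _, conf_id in selected:
        out.AddConformer(work.GetConformer(conf_id), assignId=True)
    return ConformerSet(parent_id=name, mol=out, energies=[e for e, _ in selected])
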