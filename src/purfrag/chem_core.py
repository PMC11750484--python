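"""Core chemistry: monomer perception, urethane coupling, and isocyanate capping.

Molecules are represented as RDKit ``Chem.Mol`` objects throughout the
package; RDKit's default aromaticity model is applied once at parse time
and never re-perceived afterwards, so aromatic-atom counts are consistent
across a whole library build.

The two reactive groups the package knows about are the isocyanate group
(N=C=O) and the aliphatic hydroxyl (O-H on an sp3 carbon).  Hydroxyls that
belong to carboxylic acids, esters or carbamates are *not* alcohol sites:
their oxygen is attached to a carbonyl carbon, which the SMARTS below
excludes by requiring an sp3 carbon neighbour.  Phenols are likewise not
accepted as coupling sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "Monomer",
    "FunctionalGroupProfile",
    "parse_monomer",
    "couple_urethane",
    "cap_isocyanates",
    "find_isocyanate_sites",
    "find_hydroxyl_sites",
    "CAP_GROUPS",
]

# Reactive-group and linkage patterns.  The ester pattern demands a carbon
# substituent on the carbonyl carbon so that carbamates (N-C(=O)-O) never
# register as esters; the ether oxygen must not touch any carbonyl carbon.
_NCO = Chem.MolFromSmarts("[NX2]=[CX2]=[OX1]")
_HYDROXYL = Chem.MolFromSmarts("[OX2H1][CX4]")
_URETHANE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])[OX2][#6]")
_ESTER = Chem.MolFromSmarts("[#6;!$([#6]=[!#6])][CX3](=[OX1])[OX2][#6]")
_ETHER = Chem.MolFromSmarts("[OX2;!$([OX2][CX3]=[OX1])]([#6])[#6]")

CAP_GROUPS = ("amine", "methyl", "carbamate")

Role = Literal["isocyanate", "alcohol"]


class MonomerError(ValueError):
    """Raised for unparsable SMILES or role/functionality mismatches."""


@dataclass(frozen=True)
class FunctionalGroupProfile:
    """Atom indices of the reactive sites found in one molecule.

    ``isocyanate_sites`` holds (N, C, O) triplets; ``hydroxyl_sites`` holds
    (O, C) pairs where C is the carbinol carbon.  Both lists are ordered by
    first atom index, which makes site selection deterministic.
    """

    isocyanate_sites: tuple[tuple[int, int, int], ...]
    hydroxyl_sites: tuple[tuple[int, int], ...]


@dataclass
class Monomer:
    """A building block (isocyanate or alcohol) with its functionality profile."""

    id: str
    smiles: str
    role: Role
    functionality: int
    has_ester: bool
    has_ether: bool
    mol: Chem.Mol = field(repr=False)

    @property
    def mw(self) -> float:
        return Descriptors.MolWt(self.mol)


def find_isocyanate_sites(mol: Chem.Mol) -> tuple[tuple[int, int, int], ...]:
    """Return (N, C, O) index triplets of every isocyanate group, sorted."""
    return tuple(sorted(mol.GetSubstructMatches(_NCO)))


def find_hydroxyl_sites(mol: Chem.Mol) -> tuple[tuple[int, int], ...]:
    """Return (O, C) index pairs of every aliphatic hydroxyl, sorted.

    Acid, ester and carbamate O-H groups are excluded (their oxygen sits on
    a carbonyl carbon, not an sp3 carbon), as are phenols.
    """
    return tuple(sorted(mol.GetSubstructMatches(_HYDROXYL)))


def functional_group_profile(mol: Chem.Mol) -> FunctionalGroupProfile:
    return FunctionalGroupProfile(
        isocyanate_sites=find_isocyanate_sites(mol),
        hydroxyl_sites=find_hydroxyl_sites(mol),
    )


def has_ester(mol: Chem.Mol) -> bool:
    """True if the molecule contains an ester bond that is not a carbamate."""
    return mol.HasSubstructMatch(_ESTER)


def has_ether(mol: Chem.Mol) -> bool:
    """True for any C-O-C oxygen outside ester/carbamate/acid groups."""
    return mol.HasSubstructMatch(_ETHER)


def parse_monomer(smiles: str, role: Role, id: str | None = None) -> Monomer:
    """Parse a building-block SMILES and detect its reactive functionality.

    Parameters
    ----------
    smiles:
        Input structure.  Must be valid SMILES.
    role:
        ``"isocyanate"`` or ``"alcohol"``; functionality is counted over the
        matching reactive group only.
    id:
        Identifier used in oligomer provenance; defaults to the SMILES.

    Raises
    ------
    MonomerError
        If the SMILES does not parse, the declared role has no reactive
        group, or the functionality exceeds 2 (crosslinkers are excluded
        from library enumeration).
    """
    if role not in ("isocyanate", "alcohol"):
        raise MonomerError(f"unknown role {role!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MonomerError(f"invalid SMILES for monomer {id or smiles!r}: {smiles!r}")
    if id is None:
        id = smiles
    if role == "isocyanate":
        n_sites = len(find_isocyanate_sites(mol))
        group = "N=C=O"
    else:
        n_sites = len(find_hydroxyl_sites(mol))
        group = "C-OH"
    if n_sites == 0:
        raise MonomerError(
            f"monomer {id!r} declared as {role} but contains no {group} group"
        )
    if n_sites > 2:
        raise MonomerError(
            f"monomer {id!r} has {n_sites} {group} groups; only mono- and "
            "difunctional building blocks are supported"
        )
    return Monomer(
        id=id,
        smiles=Chem.MolToSmiles(mol),
        role=role,
        functionality=n_sites,
        has_ester=has_ester(mol),
        has_ether=has_ether(mol),
        mol=mol,
    )


def load_monomer_file(path, role: Role) -> list[Monomer]:
    """Read a ``SMILES<TAB>id`` file (one record per line, blank lines ignored)."""
    monomers = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            smiles, _, mid = line.partition("\t")
            if not mid:
                mid = smiles
            try:
                monomers.append(parse_monomer(smiles.strip(), role, mid.strip()))
            except MonomerError as exc:
                raise MonomerError(f"{path}:{lineno}: {exc}") from exc
    return monomers


def couple_urethane(
    iso: Chem.Mol, iso_site: int, ol: Chem.Mol, ol_site: int
) -> Chem.Mol:
    """Form a urethane bond: R-N=C=O + HO-R' -> R-NH-C(=O)-O-R'.

    ``iso_site``/``ol_site`` index into the site lists returned by
    :func:`find_isocyanate_sites` / :func:`find_hydroxyl_sites`.  The
    reaction is a pure addition, so the product mass equals the sum of the
    reactant masses and any unreacted sites survive untouched.
    """
    iso_sites = find_isocyanate_sites(iso)
    ol_sites = find_hydroxyl_sites(ol)
    if not 0 <= iso_site < len(iso_sites):
        raise IndexError(
            f"isocyanate site {iso_site} out of range (molecule has {len(iso_sites)})"
        )
    if not 0 <= ol_site < len(ol_sites):
        raise IndexError(
            f"hydroxyl site {ol_site} out of range (molecule has {len(ol_sites)})"
        )
    n_idx, c_idx, _ = iso_sites[iso_site]
    o_idx = ol_sites[ol_site][0]

    combined = Chem.RWMol(Chem.CombineMols(iso, ol))
    offset = iso.GetNumAtoms()
    # N=C becomes N-C (the N picks up an implicit H on sanitisation) and the
    # alcohol oxygen bonds to the former isocyanate carbon, losing its H.
    combined.GetBondBetweenAtoms(n_idx, c_idx).SetBondType(Chem.BondType.SINGLE)
    combined.AddBond(c_idx, o_idx + offset, Chem.BondType.SINGLE)
    product = combined.GetMol()
    Chem.SanitizeMol(product)
    return product


def _cap_one_site(mol: Chem.Mol, cap: str) -> Chem.Mol:
    """Cap the first isocyanate group found; assumes at least one exists."""
    n_idx, c_idx, o_idx = find_isocyanate_sites(mol)[0]
    rw = Chem.RWMol(mol)
    if cap == "amine":
        # R-N=C=O -> R-NH2: drop the C and O.
        for idx in sorted((c_idx, o_idx), reverse=True):
            rw.RemoveAtom(idx)
    elif cap == "methyl":
        # R-N=C=O -> R-CH3: replace the whole group with a fresh carbon.
        r_neighbors = [
            a.GetIdx()
            for a in rw.GetAtomWithIdx(n_idx).GetNeighbors()
            if a.GetIdx() != c_idx
        ]
        new_c = rw.AddAtom(Chem.Atom(6))
        for r in r_neighbors:
            rw.AddBond(r, new_c, Chem.BondType.SINGLE)
        for idx in sorted((n_idx, c_idx, o_idx), reverse=True):
            rw.RemoveAtom(idx)
    elif cap == "carbamate":
        # R-N=C=O -> R-NH-C(=O)-OH: formal addition of water.
        rw.GetBondBetweenAtoms(n_idx, c_idx).SetBondType(Chem.BondType.SINGLE)
        new_o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(c_idx, new_o, Chem.BondType.SINGLE)
    else:
        raise ValueError(f"unknown cap {cap!r}; expected one of {CAP_GROUPS}")
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def cap_isocyanates(mol: Chem.Mol, cap: str) -> Chem.Mol:
    """Replace every residual N=C=O group with a neutral capping group.

    ``cap`` is one of ``amine`` (R-NH2), ``methyl`` (R-CH3) or ``carbamate``
    (R-NH-C(=O)OH).  Molecules without isocyanate groups pass through
    unchanged, which makes the operation idempotent.
    """
    if cap not in CAP_GROUPS:
        raise ValueError(f"unknown cap {cap!r}; expected one of {CAP_GROUPS}")
    while find_isocyanate_sites(mol):
        mol = _cap_one_site(mol, cap)
    return mol


def count_urethane_bonds(mol: Chem.Mol) -> int:
    """Number of urethane (carbamate) linkages N-C(=O)-O-C in the molecule."""
    seen = {m[1] for m in mol.GetSubstructMatches(_URETHANE)}
    return len(seen)
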