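"""Per-oligomer physicochemical property table.

Descriptors follow the standard cheminformatics definitions: Wildman-Crippen
atom contributions for the partition coefficient (cLogP) and molar
refraction (MR), Ertl fragment contributions for the topological polar
surface area (TPSA), and the strict rotatable-bond definition (non-ring
single bonds between two non-terminal heavy atoms, excluding amide-like
C-N bonds).  Ester/ether presence uses the carbamate-aware patterns from
:mod:`purfrag.chem_core`, so the urethane linkages themselves never count
as esters or ethers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from . import chem_core
from .enumerate import Oligomer, TOPOLOGIES

__all__ = ["PropertyRecord", "compute_properties", "property_table"]

#: column order of the CSV property table
TABLE_COLUMNS = [
    "id",
    "smiles",
    "units",
    "isocyanate",
    "alcohol",
    "mw",
    "heavy_atoms",
    "rotatable_bonds",
    "has_ester",
    "has_ether",
    "aromatic_atoms",
    "aromatic_proportion",
    "clogp",
    "mr",
    "tpsa",
]


@dataclass(frozen=True)
class PropertyRecord:
    """One row of the property table."""

    mw: float
    heavy_atoms: int
    rotatable_bonds: int
    has_ester: bool
    has_ether: bool
    aromatic_atoms: int
    aromatic_proportion: float
    clogp: float
    mr: float
    tpsa: float


def compute_properties(mol: Chem.Mol) -> PropertyRecord:
    """Compute the full descriptor set for one molecule."""
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for atom in mol.GetAtoms() if atom.GetIsAromatic())
    return PropertyRecord(
        mw=Descriptors.MolWt(mol),
        heavy_atoms=heavy,
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        has_ester=chem_core.has_ester(mol),
        has_ether=chem_core.has_ether(mol),
        aromatic_atoms=aromatic,
        aromatic_proportion=aromatic / heavy if heavy else 0.0,
        clogp=Crippen.MolLogP(mol),
        mr=Crippen.MolMR(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
    )


def aromatic_ring_count(mol: Chem.Mol) -> int:
    """Number of rings (SSSR) whose atoms are all aromatic."""
    return sum(
        1
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )


def property_table(oligomers: Sequence[Oligomer]) -> pd.DataFrame:
    """Build the library property table, one row per oligomer.

    Columns are fixed (see ``TABLE_COLUMNS``) so the CSV layout is stable
    across runs; an empty input yields an empty table with the same header.
    """
    rows = []
    for olig in oligomers:
        rec = compute_properties(olig.molecule)
        rows.append(
            {
                "id": olig.id,
                "smiles": olig.smiles,
                "units": TOPOLOGIES[olig.topology][0],
                "isocyanate": olig.iso_id,
                "alcohol": olig.ol_id,
                **asdict(rec),
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def round_percent(x: float) -> int:
    """Round a percentage half away from zero to an integer."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def library_summary(table: pd.DataFrame, oligomers: Sequence[Oligomer]) -> dict:
    """Aggregate statistics used to characterise a generated library.

    Returns integer percentages of the library by unit length and by
    aromatic-ring count, plus ester/ether shares and descriptor ranges.
    """
    n = len(table)
    by_units = {
        int(u): round_percent(100 * c / n)
        for u, c in table["units"].value_counts().items()
    }
    ring_counts = pd.Series([aromatic_ring_count(o.molecule) for o in oligomers])
    by_rings = {
        int(r): round_percent(100 * c / n)
        for r, c in ring_counts.value_counts().items()
    }
    return {
        "n_compounds": n,
        "percent_by_units": dict(sorted(by_units.items())),
        "percent_by_aromatic_rings": dict(sorted(by_rings.items())),
        "percent_with_ester": round_percent(100 * table["has_ester"].mean()),
        "percent_with_ether": round_percent(100 * table["has_ether"].mean()),
        "heavy_atoms_range": (int(table["heavy_atoms"].min()), int(table["heavy_atoms"].max())),
        "mw_range": (float(table["mw"].min()), float(table["mw"].max())),
        "clogp_range": (float(table["clogp"].min()), float(table["clogp"].max())),
    }
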