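"""Combinatorial enumeration of 2-, 3- and 4-unit polyurethane fragments.

Fragment topologies follow the functionality rules for linear oligomers:

* ``IA``   (2 units) — one isocyanate + one alcohol, a single urethane bond.
* ``IAI``  (3 units) — two copies of one isocyanate flanking a diol.
* ``AIA``  (3 units) — two copies of one alcohol flanking a diisocyanate.
* ``IAIA`` (4 units) — alternating chain of two diisocyanate and two diol
  copies; one chain end is a residual N=C=O (capped), the other a hydroxyl
  (retained).

The middle unit of a 3-unit fragment, and every unit of a 4-unit fragment,
must be difunctional; building blocks with more than two reactive groups
(crosslinkers) are rejected at parse time.  Each admissible
(isocyanate, alcohol, topology) combination yields exactly one product:
reaction sites are consumed in ascending atom-index order, so asymmetric
diisocyanates contribute a single, deterministically chosen regioisomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

from . import chem_core
from .chem_core import Monomer, cap_isocyanates, couple_urethane

__all__ = [
    "Oligomer",
    "TOPOLOGIES",
    "enumerate_library",
    "count_expected",
    "assign_isocyanate_class",
    "default_isocyanates",
    "default_alcohols",
]

#: topology -> (number of units, urethane bonds)
TOPOLOGIES: dict[str, tuple[int, int]] = {
    "IA": (2, 1),
    "IAI": (3, 2),
    "AIA": (3, 2),
    "IAIA": (4, 3),
}

_LENGTH_PREFIX = {2: "dimer", 3: "trimer", 4: "tetramer"}

#: Fig-style isocyanate grouping: the three MDI isomers collapse to "MDI",
#: the two TDI isomers to "TDI"; the rest map to themselves.
DEFAULT_ISOCYANATE_CLASSES: dict[str, str] = {
    "MIC": "MIC",
    "BIC": "BIC",
    "4,4'-MDI": "MDI",
    "2,4'-MDI": "MDI",
    "2,2'-MDI": "MDI",
    "2,4-MDI": "MDI",
    "2,2-MDI": "MDI",
    "2,4-TDI": "TDI",
    "2,6-TDI": "TDI",
    "HDI": "HDI",
    "IPDI": "IPDI",
    "HMDI": "HMDI",
}


@dataclass
class Oligomer:
    """A generated PUR fragment with full provenance."""

    id: str
    molecule: Chem.Mol = field(repr=False)
    iso_id: str
    ol_id: str
    topology: str
    cap: str
    urethane_bond_count: int

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.molecule)

    @property
    def n_units(self) -> int:
        return TOPOLOGIES[self.topology][0]

    @property
    def mw(self) -> float:
        return Descriptors.MolWt(self.molecule)


def default_isocyanates() -> list[Monomer]:
    """The packaged 10-isocyanate set (2 monofunctional, 8 difunctional)."""
    path = resources.files("purfrag.data") / "isocyanates.smi"
    return chem_core.load_monomer_file(str(path), "isocyanate")


def default_alcohols() -> list[Monomer]:
    """The packaged 16-alcohol set (9 monofunctional, 7 diols), all aliphatic."""
    path = resources.files("purfrag.data") / "alcohols.smi"
    return chem_core.load_monomer_file(str(path), "alcohol")


def _assemble(iso: Monomer, ol: Monomer, topology: str) -> Chem.Mol:
    """Build the uncapped chain for one (iso, ol, topology) combination."""
    if topology == "IA":
        return couple_urethane(iso.mol, 0, ol.mol, 0)
    if topology == "IAI":
        half = couple_urethane(iso.mol, 0, ol.mol, 0)
        # the diol's remaining hydroxyl is now site 0 of the intermediate
        return couple_urethane(iso.mol, 0, half, 0)
    if topology == "AIA":
        half = couple_urethane(iso.mol, 0, ol.mol, 0)
        return couple_urethane(half, 0, ol.mol, 0)
    if topology == "IAIA":
        chain = couple_urethane(iso.mol, 0, ol.mol, 0)  # I-A
        chain = couple_urethane(iso.mol, 0, chain, 0)  # I-A-I (via free OH)
        return couple_urethane(chain, 0, ol.mol, 0)  # I-A-I-A (via free NCO)
    raise ValueError(f"unknown topology {topology!r}")


def _admissible(iso: Monomer, ol: Monomer, topology: str) -> bool:
    if topology == "IA":
        return True
    if topology == "IAI":
        return ol.functionality == 2
    if topology == "AIA":
        return iso.functionality == 2
    if topology == "IAIA":
        return iso.functionality == 2 and ol.functionality == 2
    return False


def enumerate_library(
    isos: Sequence[Monomer],
    ols: Sequence[Monomer],
    lengths: Iterable[int] = (2, 3, 4),
    cap: str | None = "amine",
) -> list[Oligomer]:
    """Generate every admissible PUR fragment of the requested unit lengths.

    Parameters
    ----------
    isos, ols:
        Validated building blocks (:func:`purfrag.chem_core.parse_monomer`).
    lengths:
        Subset of {2, 3, 4} unit counts to enumerate.
    cap:
        Capping group applied to residual isocyanate moieties after chain
        assembly (``amine``, ``methyl``, ``carbamate``), or ``None`` to
        leave free N=C=O groups in place.

    Returns
    -------
    list of :class:`Oligomer`, deterministically ordered and numbered
    sequentially within each unit-length class
    (``dimer_1 .. dimer_N, trimer_1 .. ``), following the input monomer
    order with IAI before AIA at 3 units.
    """
    lengths = sorted(set(lengths))
    if not lengths or not set(lengths) <= {2, 3, 4}:
        raise ValueError(f"lengths must be a non-empty subset of {{2,3,4}}: {lengths}")
    if not isos:
        raise ValueError("no isocyanate monomers supplied")
    if not ols:
        raise ValueError("no alcohol monomers supplied")
    for m in isos:
        if m.role != "isocyanate":
            raise ValueError(f"monomer {m.id!r} is not an isocyanate")
    for m in ols:
        if m.role != "alcohol":
            raise ValueError(f"monomer {m.id!r} is not an alcohol")

    out: list[Oligomer] = []
    for length in lengths:
        counter = 0
        topologies = [t for t, (n, _) in TOPOLOGIES.items() if n == length]
        for iso in isos:
            for ol in ols:
                for topology in topologies:
                    if not _admissible(iso, ol, topology):
                        continue
                    mol = _assemble(iso, ol, topology)
                    if cap is not None:
                        mol = cap_isocyanates(mol, cap)
                    counter += 1
                    out.append(
                        Oligomer(
                            id=f"{_LENGTH_PREFIX[length]}_{counter}",
                            molecule=mol,
                            iso_id=iso.id,
                            ol_id=ol.id,
                            topology=topology,
                            cap=cap or "none",
                            urethane_bond_count=TOPOLOGIES[topology][1],
                        )
                    )
    return out


def count_expected(
    n_iso: int,
    n_iso_di: int,
    n_ol: int,
    n_ol_di: int,
    lengths: Iterable[int] = (2, 3, 4),
) -> int:
    """Closed-form library size for a given functionality split.

    With ``n_iso`` isocyanates of which ``n_iso_di`` are difunctional (and
    likewise for alcohols), each length contributes:

    * 2 units: ``n_iso * n_ol``
    * 3 units: ``n_iso * n_ol_di`` (IAI) + ``n_iso_di * n_ol`` (AIA)
    * 4 units: ``n_iso_di * n_ol_di``
    """
    for name, val in (
        ("n_iso", n_iso),
        ("n_iso_di", n_iso_di),
        ("n_ol", n_ol),
        ("n_ol_di", n_ol_di),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if n_iso_di > n_iso or n_ol_di > n_ol:
        raise ValueError("difunctional counts cannot exceed totals")
    per_length = {
        2: n_iso * n_ol,
        3: n_iso * n_ol_di + n_iso_di * n_ol,
        4: n_iso_di * n_ol_di,
    }
    return sum(per_length[length] for length in set(lengths))


def assign_isocyanate_class(
    oligomer: Oligomer, class_map: dict[str, str] | None = None
) -> str:
    """Group an oligomer by the type of isocyanate used in its synthesis.

    The default mapping collapses MDI and TDI regioisomers into single
    classes (MDI, TDI) and keeps MIC, BIC, HDI, IPDI and HMDI as singleton
    classes.  Custom building-block sets supply their own ``class_map``.
    """
    mapping = class_map if class_map is not None else DEFAULT_ISOCYANATE_CLASSES
    if oligomer.iso_id in mapping:
        return mapping[oligomer.iso_id]
    if class_map is None:
        # tolerate id variants such as "44MDI" or "tdi-2,4"
        upper = oligomer.iso_id.upper()
        for token in ("HMDI", "IPDI", "MDI", "TDI", "HDI", "BIC", "MIC"):
            if token in upper:
                return token
    raise KeyError(
        f"isocyanate id {oligomer.iso_id!r} has no class mapping; "
        "provide class_map for custom building-block sets"
    )
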