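"""NAC classification: cleavable bonds, distances, thresholds, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from purfrag.fixtures import make_site_fixture
from purfrag.io_formats import LigandPose
from purfrag.pose_analysis import (
    ActiveSiteSpec,
    ReceptorStructure,
    SiteResolutionError,
    classify_pose,
    classifications_table,
    find_cleavable_bonds,
    summarize,
)


class TestFindCleavableBonds:
    def test_single_urethane(self):
        bonds = find_cleavable_bonds(Chem.MolFromSmiles("CNC(=O)OC"))
        assert len(bonds) == 1
        assert bonds[0].kind == "urethane"

    def test_polyester_dimer_has_both_kinds(self):
        # ester-diol based fragment: urethane + ester backbone
        mol = Chem.MolFromSmiles("CNC(=O)OCCOC(=O)CCCCC(=O)OCCO")
        kinds = {b.kind for b in find_cleavable_bonds(mol)}
        assert kinds == {"urethane", "ester"}

    def test_no_cleavable_bond(self):
        assert find_cleavable_bonds(Chem.MolFromSmiles("CCO")) == []

    def test_carbonyl_atoms_are_double_bonded(self):
        mol = Chem.MolFromSmiles("CNC(=O)OCCOC(=O)C")
        for bond in find_cleavable_bonds(mol):
            b = mol.GetBondBetweenAtoms(bond.carbonyl_c, bond.carbonyl_o)
            assert b.GetBondType() == Chem.BondType.DOUBLE


class TestClassifyPose:
    @pytest.mark.parametrize(
        "distances,productive",
        [
            ((4.0, 2.6, 3.7), True),  # cutinase-style productive geometry
            ((3.9, 3.1, 4.3), True),  # urethanase-style productive geometry
            ((0.0, 0.0, 0.0), True),
            ((4.6, 1.0, 1.0), False),
            ((10.0, 1.0, 1.0), False),
            ((1.0, 4.6, 1.0), False),  # each oxyanion distance must pass
            ((1.0, 1.0, 4.6), False),
        ],
    )
    def test_verdicts_at_default_threshold(self, distances, productive):
        fx = make_site_fixture(*distances)
        c = classify_pose(fx.pose, fx.ligand, fx.receptor, fx.site)
        assert c.productive is productive
        assert c.d_ser == pytest.approx(distances[0], abs=1e-6)
        assert c.d_oxy1 == pytest.approx(distances[1], abs=1e-6)
        assert c.d_oxy2 == pytest.approx(distances[2], abs=1e-6)

    def test_threshold_is_inclusive(self):
        """A pose at exactly 4.5 A on every distance is still productive."""
        mol = Chem.AddHs(Chem.MolFromSmiles("CNC(=O)OC"))
        AllChem.EmbedMolecule(mol, randomSeed=3)
        coords = mol.GetConformer().GetPositions()
        bond = find_cleavable_bonds(mol)[0]
        # 4.5 is exactly representable in binary, so these distances are exact
        receptor = ReceptorStructure(
            "exact",
            {
                ("A", 130, "OG"): coords[bond.carbonyl_c] + np.array([4.5, 0, 0]),
                ("A", 60, "H"): coords[bond.carbonyl_o] + np.array([0, 4.5, 0]),
                ("A", 131, "H"): coords[bond.carbonyl_o] + np.array([0, 0, 4.5]),
            },
        )
        site = ActiveSiteSpec(serine=("A", 130), oxyanion_residues=(("A", 60), ("A", 131)))
        pose = LigandPose("lig", 1, [a.GetSymbol() for a in mol.GetAtoms()], coords)
        assert classify_pose(pose, mol, receptor, site, threshold=4.5).productive

    def test_monotone_in_threshold(self):
        """The productive set at threshold t is nested within larger t'."""
        rng = np.random.default_rng(42)
        fixtures = [make_site_fixture(*np.round(rng.uniform(0, 8, 3), 3)) for _ in range(25)]
        thresholds = [2.0, 3.5, 4.5, 6.0, 9.0]
        sets = []
        for t in thresholds:
            sets.append(
                {
                    i
                    for i, fx in enumerate(fixtures)
                    if classify_pose(fx.pose, fx.ligand, fx.receptor, fx.site, threshold=t).productive
                }
            )
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_probe_modes_differ_on_protonated_receptor(self):
        h = make_site_fixture(4.0, 2.6, 3.7, probe="backbone_H")
        n = make_site_fixture(4.0, 2.6, 3.7, probe="backbone_N")
        ch = classify_pose(h.pose, h.ligand, h.receptor, h.site)
        cn = classify_pose(n.pose, n.ligand, n.receptor, n.site)
        assert ch.d_oxy1 != cn.d_oxy1
        assert cn.d_oxy1 == pytest.approx(2.6 + 1.01, abs=1e-6)

    def test_no_cleavable_bond_flagged(self):
        fx = make_site_fixture(1.0, 1.0, 1.0)
        ethanol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        AllChem.EmbedMolecule(ethanol, randomSeed=5)
        pose = LigandPose(
            "etoh", 1,
            [a.GetSymbol() for a in ethanol.GetAtoms()],
            ethanol.GetConformer().GetPositions(),
        )
        c = classify_pose(pose, ethanol, fx.receptor, fx.site)
        assert c.no_bond and not c.productive

    def test_unresolvable_site_raises(self):
        fx = make_site_fixture(1.0, 1.0, 1.0)
        bad_site = ActiveSiteSpec(serine=("B", 999), oxyanion_residues=(("A", 60), ("A", 131)))
        with pytest.raises(SiteResolutionError):
            classify_pose(fx.pose, fx.ligand, fx.receptor, bad_site)

    def test_nearest_bond_equals_brute_force(self):
        """Chosen bond minimises serine-carbonyl distance over all bonds."""
        smi = "CC(=O)OCCOC(=O)NCCCCCCNC(=O)OCCOC(=O)C"  # 4 cleavable bonds
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        AllChem.MMFFOptimizeMolecule(mol)
        coords = mol.GetConformer().GetPositions()
        bonds = find_cleavable_bonds(mol)
        assert len(bonds) >= 3
        pose = LigandPose("multi", 1, [a.GetSymbol() for a in mol.GetAtoms()], coords)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ser = rng.uniform(-8, 8, 3)
            receptor = ReceptorStructure(
                "synthetic",
                {
                    ("A", 130, "OG"): ser,
                    ("A", 60, "H"): rng.uniform(-8, 8, 3),
                    ("A", 131, "H"): rng.uniform(-8, 8, 3),
                },
            )
            site = ActiveSiteSpec(serine=("A", 130), oxyanion_residues=(("A", 60), ("A", 131)))
            c = classify_pose(pose, mol, receptor, site)
            brute = min(
                (np.linalg.norm(coords[b.carbonyl_c] - ser), b.carbonyl_c) for b in bonds
            )
            assert c.bond.carbonyl_c == brute[1]
            assert c.d_ser == pytest.approx(brute[0])

    def test_heavy_atom_mismatch_raises(self):
        fx = make_site_fixture(1.0, 1.0, 1.0)
        wrong = Chem.MolFromSmiles("CNC(=O)OCC")  # one atom more
        with pytest.raises(ValueError, match="heavy-atom count"):
            classify_pose(fx.pose, wrong, fx.receptor, fx.site)


def _classification(lig, productive, kind="urethane", d=3.0):
    fx = make_site_fixture(d if productive else 9.0, d, d, ligand_id=lig)
    c = classify_pose(fx.pose, fx.ligand, fx.receptor, fx.site)
    assert c.productive == productive
    if kind == "ester":
        c.bond = type(c.bond)("ester", c.bond.carbonyl_c, c.bond.carbonyl_o)
    return c


class TestSummarize:
    @pytest.fixture()
    def metadata(self):
        return pd.DataFrame(
            {
                "id": ["lig1", "lig2", "lig3"],
                "isocyanate_class": ["HDI", "HDI", "MDI"],
                "has_ester": [True, True, False],
            }
        )

    def test_all_productive(self, metadata):
        cs = [_classification("lig1", True), _classification("lig2", True)]
        s = summarize(cs, metadata)
        assert s["percent_productive"] == 100.0

    def test_fraction_counts(self, metadata):
        cs = [_classification("lig1", i < 3) for i in range(10)]
        s = summarize(cs, metadata)
        assert s["percent_productive"] == pytest.approx(30.0)
        assert s["percent_productive_by_class"]["HDI"] == pytest.approx(30.0)

    def test_partition_sums_to_100(self, metadata):
        cs = [_classification("lig1", bool(i % 2)) for i in range(7)]
        s = summarize(cs, metadata)
        assert s["percent_productive"] + (100 - s["percent_productive"]) == 100

    def test_urethane_vs_ester_preference(self, metadata):
        cs = [
            _classification("lig1", True, kind="urethane"),
            _classification("lig2", True, kind="ester"),
            _classification("lig1", True, kind="urethane"),
            _classification("lig3", True, kind="urethane"),  # not dual-bond
        ]
        s = summarize(cs, metadata)
        assert s["percent_urethane_among_dual_productive"] == pytest.approx(100 * 2 / 3)

    def test_permutation_invariant(self, metadata):
        cs = [_classification("lig1", i % 3 == 0) for i in range(6)]
        a = summarize(cs, metadata)
        b = summarize(list(reversed(cs)), metadata)
        assert a["percent_productive"] == b["percent_productive"]
        assert a["percent_productive_by_class"] == b["percent_productive_by_class"]

    def test_missing_metadata_listed(self, metadata):
        cs = [_classification("ghost", True)]
        with pytest.raises(KeyError, match="ghost"):
            summarize(cs, metadata)

    def test_table_layout(self, metadata):
        cs = [_classification("lig1", True)]
        table = classifications_table(cs)
        assert list(table.columns) == [
            "ligand", "pose", "bond_kind", "d_ser", "d_oxy1", "d_oxy2", "productive",
        ]
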