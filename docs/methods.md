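# Methods

## Chemical model

Building blocks are isocyanates (reactive group N=C=O) and alcohols
(reactive group O-H on an sp3 carbon). Functionality is the number of
reactive groups of the declared role; only mono- and difunctional blocks
are accepted, since blocks with three or more groups produce branched,
crosslinked architectures outside the linear-oligomer model. Hydroxyl
perception deliberately excludes O-H on carbonyl carbons (carboxylic
acids, the carbamate capping product) so that capping never creates new
coupling sites, and excludes phenols; the default set contains no phenols,
and aromatic alcohols would require their own reactivity assumptions.

Urethane formation is implemented as a pure addition on the molecular
graph: the N=C double bond becomes single, the alcohol oxygen bonds to the
former isocyanate carbon, and implicit hydrogens rebalance on
sanitisation. Mass is conserved to <1e-4 u, which the tests use as an
invariant. Capping replaces each residual N=C=O with -NH2 (Δm −25.99 u),
-CH3 (−26.98 u) or -NH-C(=O)OH (+18.02 u, formal water addition); the
operation loops until no isocyanate pattern remains and is therefore
idempotent.

Aromaticity uses RDKit's default perception model, applied once at parse
time; all aromatic-atom statistics in a library build share it.

## Enumeration and topology rules

Admissible fragments are linear alternating chains:

| code | units | composition | urethane bonds | constraint |
|------|-------|-------------|----------------|------------|
| IA   | 2 | 1 iso + 1 ol | 1 | none |
| IAI  | 3 | 2 iso + 1 ol | 2 | alcohol difunctional |
| AIA  | 3 | 1 iso + 2 ol | 2 | isocyanate difunctional |
| IAIA | 4 | 2 iso + 2 ol | 3 | both difunctional |

Three-unit fragments use two identical copies of the outer comonomer;
four-unit chains end in one capped N=C=O and one retained hydroxyl. Each
(isocyanate, alcohol, topology) triple produces exactly one product:
reaction sites are consumed in ascending atom-index order, so asymmetric
diisocyanates (2,4-TDI, 2,4'-MDI) contribute a single deterministic
regioisomer rather than a regioisomer pair — enumerating both would
inflate the library beyond the closed-form count

n_iso·n_ol + n_iso·n_ol_di + n_iso_di·n_ol + n_iso_di·n_ol_di,

which `count_expected` implements and the property tests check against
brute-force enumeration on random functionality splits. With the default
split (10 isocyanates, 8 difunctional; 16 alcohols, 7 difunctional) the
total is 160 + 70 + 128 + 56 = 414.

Fragment ids number sequentially within each unit-length class following
input order with IAI before AIA; they are stable across runs but are an
internal convention, not a universal nomenclature.

## Default building blocks

The isocyanate set is fixed by common industrial usage: methyl and benzyl
isocyanate; 4,4'-, 2,4'- and 2,2'-MDI; 2,4- and 2,6-TDI; HDI; IPDI;
4,4'-HMDI. Ring-substituent stereochemistry of IPDI/HMDI is left
unspecified. The 16 aliphatic alcohols (9 mono, 7 di) were chosen to
emulate commercial polyol chemistry — simple alkanols and alkanediols plus
ether members (glycol ethers, di-/triethylene glycol) and ester members
(an α-hydroxy ester, a glycolate, a bis(hydroxyethyl) adipate). This
composition gives the library 17% ester-containing and 26%
ether-containing members and a cLogP range of −0.7 to 8.9. Aromatic-ring
statistics are independent of the alcohol identities because all alcohols
are aliphatic.

## Descriptors

cLogP and MR use the Wildman-Crippen atom-contribution scheme and TPSA
the Ertl fragment scheme (RDKit implementations). The test suite
cross-checks cLogP and TPSA against Open Babel's independent engine at
0.01 tolerance on a benchmark set; for MR the two engines differ in their
hydrogen contribution (1.057 vs 1.1385 cm³/mol), so MR is instead pinned
to hand-summed published contributions on molecules with unambiguous atom
typing (hexane, benzene). Rotatable bonds follow the strict definition
(non-ring single bonds between non-terminal heavy atoms, amide/carbamate
C-N excluded). Ester detection requires a carbon substituent on the
carbonyl carbon, so urethane linkages are never reported as esters; ether
oxygens must not touch any carbonyl carbon. Library percentages round half
away from zero; note 56/414 = 13.5% therefore reports as 14%. Properties
are computed on the capped structures, which are what is docked.

## Conformers

Conformers come from systematic torsion driving on one seeded
distance-geometry embedding: every strict rotatable bond is set to a grid
(120° steps; 180° for amide-like or aryl-conjugated bonds), each state is
scored with MMFF94, the best 3×max_n states are force-field optimised, and
a greedy pass keeps up to max_n conformers inside the energy window
(default 50 kcal/mol) that are pairwise ≥ rmsd_cutoff (default 0.5 Å,
heavy-atom best RMS). Defaults: max_n 20, rotor_limit 8 (beyond which a
single optimised conformer is returned — tetramers routinely exceed any
tractable grid), max_states 2000 (larger grids are subsampled from the
seeded RNG), seed 0xC0FFEE. Setting torsions preserves bond lengths
exactly; the short optimisation keeps them within 0.1 Å of the embedding,
which a test asserts. MMFF94 was chosen as the energy model because it is
the standard small-molecule force field available in the toolkit; energies
are kcal/mol and reported relative ordering matters more than absolute
values.

## Pose classification

For each docked pose, cleavable bonds are located on the ligand's 2D
graph (urethane N-C(=O)-O-C; ester C-C(=O)-O-C with no nitrogen on the
carbonyl carbon) and mapped to pose coordinates by heavy-atom order —
docking formats such as PDBQT do not store bond orders, so re-perceiving
chemistry from coordinates would be less reliable. This requires pose
files to preserve the generated structure's heavy-atom order, which every
writer in this package does; element mismatches raise immediately.

The chosen bond minimises the distance from the catalytic serine
side-chain oxygen (OG) to the carbonyl carbon. A pose is productive iff
that distance and both oxyanion probe distances (probe atom to carbonyl
oxygen) are all ≤ the threshold, 4.5 Å by default and inclusive — the
generous value reflects rigid-receptor docking imprecision, not bonding
geometry. The oxyanion probe is the backbone amide hydrogen on protonated
receptors and the backbone nitrogen otherwise; both modes are explicit in
`ActiveSiteSpec` and the CLI logs which is active, since they give
systematically different distances (≈1 Å, the N-H bond length).

## Synthetic fixtures

`make_site_fixture` builds a three-residue receptor stub (SER + two
oxyanion residues with standard PDB naming, round-tripped through the real
PDB parser) whose probe atoms sit at exactly requested distances from a 3D
embedded one-urethane ligand; ligand coordinates are snapped to the PDB's
3-decimal precision so requested distances with ≤3 decimals are realised
to <1e-6 Å. These fixtures emulate active-site geometry only — no protein
fold, sterics or docking physics — so classifier tests demonstrate the
correctness of the distance logic, not docking realism. `make_monomer_set`
produces straight-chain aliphatic monomers with an exact functionality
split, distinct per seed, for enumeration oracles. Docking percentages for
real enzymes require external docking runs and receptor preparation and
are outside this package's scope.

## Known limitations

* One regioisomer per combination; no stereoisomer enumeration, tautomers
  or protonation states.
* Conformer search is not exhaustive above `max_states` grid points and
  falls back to a single conformer above `rotor_limit` rotors.
* PDBQT reading ignores charges and torsion trees; PDBQT writing, mmCIF
  and compressed transport are unsupported.
* Pose/graph matching assumes preserved heavy-atom order; tools that
  reorder atoms need a mapping step upstream.
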