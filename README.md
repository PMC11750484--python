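# purfrag

Polyurethane (PUR) is held together by urethane (carbamate) bonds,
`R-NH-C(=O)-O-R'`, formed by addition of an alcohol O-H across an
isocyanate N=C=O group. Enzymatic PUR recycling research needs small,
dockable stand-ins for the polymer chain: oligomeric fragments that carry
real urethane bonds but fit in an enzyme's active site. `purfrag` builds
such fragment libraries combinatorially from isocyanate and alcohol
building blocks, profiles them, and post-processes docking results against
serine hydrolases with a near-attack-configuration (NAC) classifier.

It is aimed at computational enzymologists and polymer chemists screening
candidate PUR-degrading enzymes (cutinases, urethanases) or designing
model substrates.

## What it does

* **Enumeration** — all linear 2-, 3- and 4-unit fragments admissible
  under functionality rules (topologies I-A, I-A-I, A-I-A, I-A-I-A; the
  middle unit of a trimer and every unit of a tetramer must be
  difunctional; crosslinkers with >2 reactive groups are rejected).
  Residual N=C=O groups are capped with amine (-NH2), methyl (-CH3) or
  carbamate (-NH-C(=O)OH) groups. The packaged default set holds 10
  industrially common isocyanates (MIC, BIC, three MDI and two TDI
  isomers, HDI, IPDI, HMDI) and 16 aliphatic alcohols (9 mono-ols, 7
  diols, including polyester- and polyether-like members).
* **Descriptors** — molecular weight, heavy atoms, rotatable bonds,
  ester/ether presence (carbamate-aware, so urethane bonds never count as
  esters), aromatic atom count and proportion, Wildman-Crippen cLogP and
  MR, Ertl TPSA; exported as `library.csv`.
* **Conformers** — up to 20 diverse conformers per fragment by systematic
  torsion driving with MMFF94 ranking, an energy window and a pairwise
  heavy-atom RMSD cutoff.
* **I/O** — MOL (V2000), SDF, TRIPOS MOL2 and SMILES writers; MOL2/SDF and
  multi-MODEL PDBQT pose readers; PDB receptor reading.
* **NAC pose classification** — a docked pose is *productive* when the
  catalytic serine oxygen is within a threshold distance (default 4.5 Å,
  inclusive) of the carbonyl carbon of the nearest cleavable bond
  (urethane or ester) **and** both oxyanion-hole backbone probes (amide H,
  or N on unprotonated receptors) are within the same threshold of that
  bond's carbonyl oxygen. Summaries report productive percentages overall,
  per isocyanate class, and the urethane-vs-ester preference among
  dual-bond ligands.

## Worked example

```python
from purfrag import (default_isocyanates, default_alcohols,
                     enumerate_library, property_table)
from purfrag.descriptors import library_summary

isos, ols = default_isocyanates(), default_alcohols()
library = enumerate_library(isos, ols, lengths=(2, 3, 4), cap="amine")
table = property_table(library)
summary = library_summary(table, library)
print(len(library), summary["percent_by_units"], summary["percent_by_aromatic_rings"])
```

prints

```
414 {2: 39, 3: 48, 4: 14} {0: 39, 1: 19, 2: 32, 4: 10}
```

i.e. the default blocks yield 414 fragments, of which 39% are 2-unit and
48% 3-unit, and whose aromatic content (0/1/2/4 aromatic rings at
39/19/32/10%) is set entirely by the isocyanates, the alcohols all being
aliphatic. The smallest member is the methyl isocyanate + methanol dimer,
`CNC(=O)OC` — 6 heavy atoms, 89 u.

The same library from the shell, plus a pose classification:

```bash
purfrag generate --out lib --formats smi,csv,mol2
purfrag analyze-poses --receptor rec.pdb --poses poses/ \
    --serine A:130:OG --oxyanion A:60,A:131 --threshold 4.5 \
    --library lib/library.csv --out summary.csv
```

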