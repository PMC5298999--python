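# igvor

Voronoi interface models for antibody–antigen (Ig–Ag) complexes.

Antibody engineering and immunoinformatics need quantitative descriptions
of how an immunoglobulin (Ig) binds its antigen (Ag): which atoms form the
interface, how tightly they pack, how the six CDR loops share the work,
and how these geometric facts relate to the ligand type and the binding
affinity. `igvor` provides a geometric interface model and three analyses
built on it, for structural bioinformaticians working from crystal
structures of complexes.

## The model

Each heavy atom is a ball of van der Waals radius expanded by a water
probe (r_w = 1.4 Å), the *solvent-accessible model*. The power (weighted
Voronoi) diagram of these balls partitions the molecular volume; the
*Voronoi restriction* of an atom — its ball intersected with its power
cell — has a volume Vol(a) that measures atomic packing. Two atoms are in
*contact* when their restrictions share a facet of positive area. Contacts
across partners (and through sandwiched water molecules) define the
interface I = I_Ig ∪ I_Ag; the exposed surface lost by each partner upon
association is the buried surface area, charged per atom and per side
(BSA = BSA_Ig + BSA_Ag). Each interface atom also gets a *shelling order*
SO(a): its hop distance, through the contact graph, to the rim of its
binding patch.

From these primitives come the per-complex descriptors:

* **bsa̅_Ig = BSA_Ig/|I_Ig|** and **bsa̅_Ag = BSA_Ag/|I_Ag|** — average
  burial per interface atom on each side, a curvature proxy: small convex
  ligands (chemicals) bury much more per antigen atom than flat protein
  epitopes. A shallow decision tree on (bsa̅_Ag, bsa̅_Ig) classifies the
  ligand type (chemical / peptide / protein), evaluated by repeated
  stratified 5-fold cross-validation against a count-preserving label
  permutation baseline and a naive |I|-only classifier.
* **IVW-IPL = Σ_{a∈I} SO(a)/Vol(a)** — the inverse volume-weighted
  internal path length, coupling interface size and morphology with
  packing; **ANSO** is its per-atom average over a region's interface
  atoms.
* **NIS^charged** — the fraction of charged residues (D, E, K, R, H) on
  the non-interacting, solvent-exposed surface.
* Binding affinity −ΔG = −RT·ln(Kd/c°) is predicted by k-nearest-neighbor
  regression (default k = 10) in (IVW-IPL, NIS^charged) space, with a
  training-mean null model and per-query reliability diagnostics
  (neighbor distance d_i, neighbor-affinity spread σ_i, and d_i/σ_i).
* CDR-resolved statistics: the 14-region (6 CDR + 8 FR) decomposition of
  BSA, IVW-IPL and ANSO, VH-vs-VL dominance fractions, and Wilcoxon
  signed-rank comparisons of CDR1+2 against CDR3 within each chain.

## Worked example

```python
from igvor import fixtures as fx
from igvor.sam_voronoi import extract_interface
from igvor.interface_params import compute_descriptor

f = fx.make_slab_complex(with_water=True)   # synthetic Ig–Ag ball complex
s = f.structure()
d = compute_descriptor(s, extract_interface(s))
```

Printing the key fields of `d` gives:

```
|I_Ig| = 12, |I_Ag| = 2
BSA_Ig = 42.87 A^2, BSA_Ag = 49.03 A^2
bsa_avg_Ig = 3.57, bsa_avg_Ag = 24.52 A^2/atom
IVW-IPL = 0.4086 A^-3
VH-CDR3: 6 interface atoms, BSA = 19.82 A^2, ANSO = 0.0396
```

Twelve antibody atoms and two ligand atoms form the interface; the
compact ligand buries ~25 Å² per atom against ~3.6 Å² on the flat antibody
patch — exactly the asymmetry the ligand-type classifier exploits. On a
synthetic 489-complex cohort with realistic class structure:

```python
from igvor.ligand_type_classifier import LabeledPoint, cross_validate, permutation_test

cohort = fx.make_classification_cohort(fx.SyntheticCohort(seed=0))
points = [LabeledPoint(r.complex_id, (r.bsa_avg_ag, r.bsa_avg_ig), r.label)
          for r in cohort.itertuples()]
cv = cross_validate(points, n_reps=50, seed=0)
perm = permutation_test([p.label for p in points], n_perms=2000, seed=0)
```

```
median CV error: 3.9%   permutation baseline: 56.2%
per-class CV: {'chemical': '0%', 'peptide': '8%', 'protein': '3%'}
```

The tree separates the three ligand types far below the 56% permutation
floor, which is set purely by the class counts (78/122/289).

A command-line interface mirrors the stages:

```sh
igvor fixtures --name two-ball --out-dir out
igvor interface out/two-ball-d2.0.pdb --ligand A --out-dir out
igvor classify --seed 0 --out-dir out
igvor predict-affinity --k 10 --sweep --out-dir out
```

Every output directory carries a `provenance.json` with the exact run
configuration and seeds; reruns with the same seed are byte-identical.

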