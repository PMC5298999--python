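# Methods

## Solvent-accessible model and power-diagram restrictions

Atoms are heavy atoms only; hydrogens are dropped because the interface
model operates on heavy-atom solvent-accessible models (configurable at
parse time). Each atom is a ball of radius r_vdw + r_w. The probe radius
r_w defaults to 1.4 Å, the standard water-probe value; r_w = 0 recovers
the plain van der Waals model. Van der Waals radii come from a named
table; the default is the Bondi element set (C 1.70, N 1.55, O 1.52,
S 1.80 Å, …), with a 1.70 Å fallback for unknown elements on hetero
ligands. The table name is recorded in every structure object so that
outputs are traceable to it.

The power diagram of the expanded balls assigns each atom the region
where its power distance is smallest. The *restriction* of an atom is its
ball intersected with its power cell. Restrictions partition the union of
balls, so per-atom restriction volumes are an exact decomposition of the
molecular volume — the property the volume-conservation tests assert.

### Exact boundary integration

Restriction volumes, exposed areas and facet areas are computed
analytically rather than by sampling:

* The part of an atom's sphere that survives in the union boundary is the
  sphere minus one spherical cap per overlapping neighbour (the cap cut
  by the radical plane; only overlapping balls can cut, because the
  radical plane of a non-overlapping pair misses both balls). The area of
  a sphere minus a union of caps follows from Gauss–Bonnet applied to the
  boundary arcs: area = R²(2πχ − Σ cos α·Δφ − Σ θ_ext). All arc terms are
  exact; the Euler characteristic χ is an integer whose candidates differ
  by 2πR², so a deterministic 2000-point sphere sample picks the right χ
  without affecting the analytic accuracy (the estimate only needs to be
  within ~half of 2πR², and it is accurate to ~1% of the sphere).
* A facet shared by two restrictions is the radical-plane disk (common to
  both balls by the radical-plane property) clipped by the half-planes of
  the other overlapping neighbours. Its area is the closed-form area of a
  convex polygon intersected with a disk (Green's theorem with circular
  sector corrections).
* The restriction volume follows from the divergence theorem with the
  origin at the atom centre: V = (R·A_sphere + Σ_j h_j·A_facet_j)/3,
  where h_j is the signed distance from the centre to the radical plane.

On two-sphere configurations the results agree with the lens/cap closed
forms to machine precision (the tests assert 1e-6 relative); on random
clusters the summed volumes agree with a Monte-Carlo union-volume oracle
within its standard error and the areas with a Shrake–Rupley-style
point-count oracle within the oracle's own sampling error.

**Degeneracies.** Tangent circles, caps touching internally, and vertices
shared by three circles make floating-point boundary topology
inconsistent. The area core detects these situations (tolerance 1e-10)
and retries with a deterministic alternating perturbation of the cap
offsets at scales 2e-9, 6e-8, 2e-6 — several orders of magnitude below
the stated accuracy. If all attempts fail, a dense deterministic sample
(2·10⁵ directions, ~1e-3 relative) is used and a warning logged.
Coincident ball centres are resolved by atom-id order (symbolic
perturbation) and reported. Iteration order is fixed by sorted atom id
throughout, so all outputs are deterministic.

## Interface, BSA and shelling order

Two atoms are in contact when their shared facet area exceeds 1e-6 Å².
Direct pairs are (Ig, Ag) contacts; interfacial waters are water
molecules whose restriction touches both partners (first-shell only —
water–water chains are not traversed); water-mediated pairs connect
partner atoms to such waters. I_Ig and I_Ag collect partner atoms from
either pair type, so an atom reachable only through a water still counts
in the denominators of bsa̅_Ig and bsa̅_Ag.

Per-atom BSA is exposed_area(partner alone, same coordinates, waters
removed) − exposed_area(full complex with waters), floored at zero
against numerical noise. The unbound reference is the rigid split of the
bound coordinates — the standard convention when only the complex
structure is available.

Shelling order is a breadth-first search over the same-partner contact
graph restricted to the patch: SO = 1 for rim atoms (patch atoms adjacent
to an exposed same-partner non-patch atom, or retaining exposed area
> 1e-6 Å² themselves), SO = 1 + min over patch neighbours otherwise.
Patch components with no rim atom get SO = 1 throughout. The choice of
rim seed (exposed-at-interface atoms as well as patch-boundary
neighbours) is fixed here and exercised against a brute-force
shortest-path oracle.

## Descriptors

IVW-IPL is implemented as Σ SO(a)/Vol(a). The name (inverse
volume-weighted), the role of packing in the denominator and the
region-level decompositions all require the quotient; a product form
Σ SO(a)·Vol(a) is available behind `form="product"` for audit. ANSO is
the quotient form averaged over a region's interface atoms; for pooled
regions (CDR1+2) it is computed on the pooled atom set, preserving the
identity ANSO(A₁∪A₂)·|A₁∪A₂| = IVW-IPL(A₁) + IVW-IPL(A₂).

NIS^charged counts residues, not area: a residue of either partner
belongs to the non-interacting surface when its summed bound exposed area
exceeds 1 Å² (configurable) and it contributes no interface atom. The
charged set is {ASP, GLU, LYS, ARG, HIS} by default, histidine removable
by flag; both partners are pooled. Empty-side averages, empty ANSO sets
and an empty non-interacting surface raise explicit "undefined" errors —
they are never reported as zero.

Region labels follow the IMGT unique numbering limits (FR1 1–26, CDR1
27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128;
beyond 128 → constant/outside-V). Numbering is consumed from the input
structure or a sidecar CSV; renumbering is out of scope.

## Classification

The ligand-type classifier is a Gini decision tree limited to four
leaves (three internal axis-aligned splits — three separating lines in
the (bsa̅_Ag, bsa̅_Ig) plane). Evaluation is k-fold cross-validation with
k = 5, repeated (default 1000 times) with fresh seeded folds; medians use
the lower-median convention for even repetition counts. Folds are
stratified by class by default to stabilise the smallest class; a flag
restores plain random folds. The permutation baseline redistributes the
existing labels (preserving class counts); its expected overall error has
the closed form 1 − Σ n_c(n_c−1)/(n(n−1)) and the per-class errors
1 − (n_c−1)/(n−1), used as convergence oracles. The naive baseline runs
the identical protocol on the single feature |I|.

## Affinity regression

−ΔG = −RT·ln(Kd/c°) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, c° = 1 M and
T = 298 K unless a per-record temperature is given. Features (IVW-IPL,
NIS^charged) are z-scored with training statistics before Euclidean
distances (the two live on scales differing by two orders of magnitude);
a raw-scale flag exists and the choice is recorded in reports. The
prediction is the unweighted mean of the k nearest training responses
(default k = 10, swept over 5..25); ties at the k-th distance resolve by
stable training order. σ_i is the population standard deviation of the
k neighbour responses (defined even at k = 1). "Within m orders of
magnitude on Kd" means |e| ≤ m·RT·ln 10 (≈ 1.36 kcal/mol per order at
298 K), boundary inclusive. The null model predicts the training mean
everywhere; with k = n_training the k-NN estimate coincides with it
exactly.

## CDR statistics

Paired comparisons drop zero differences, use the exact signed-rank null
for ≤ 25 untied pairs and the normal approximation with continuity
correction otherwise; groups with fewer than six non-tied pairs are
skipped with a warning. Complexes whose CDR1∪CDR2 or CDR3 interface-atom
set is empty contribute 0 to BSA/IVW-IPL sums but are dropped from the
ANSO pairing (the mean is undefined), and logged. VH/VL dominance counts
strict inequalities of the summed seven-region domain BSAs.

## Synthetic data

The ball fixtures (two-sphere configurations, lattice patches, the slab
complex) have analytic ground truth and exercise the geometric contract;
coordinates are chosen away from degeneracy except in dedicated
degeneracy tests. The statistical cohorts emulate the study conditions:
489 complexes with class proportions 0.16/0.25/0.59 (largest-remainder
rounding → 78/122/289); class means in (bsa̅_Ag, bsa̅_Ig) of (30, 7),
(18, 9) and (9.5, 11) Å²/atom with within-class anticorrelation,
reflecting that chemicals bury ~3× more per antigen atom than protein
epitopes while antibody-side burial varies little; an affinity cohort of
125 training / 14 test complexes whose response is linear in the two
descriptors plus Gaussian noise (1.2 kcal/mol), calibrated so the
training −ΔG is centred near 10.78 kcal/mol with spread ≈ 2.8.

What the cohorts do *not* emulate: real descriptor distributions are
neither Gaussian nor linear in the response; real class overlap is
stronger (peptides grade into proteins); and real structures carry
missing atoms, alternate conformations and crystallographic artefacts.
Passing tests therefore demonstrate correctness of the statistical
machinery and the qualitative separability mechanism, not the error
rates attainable on curated structure databases.

## Problem sizes

Default test problem sizes are chosen for exhaustive verification rather
than scale: random clusters of 10–16 balls (20 of them for volume
conservation), slab complexes of ~15 atoms, cohorts of ≤ 3000 points,
10,000 permutations, and exact signed-rank enumeration up to n = 10. The
geometry backend itself is O(n·m²) per structure for m overlapping
neighbours per atom and handles hundreds of atoms comfortably.

## Known limitations

* The unbound reference is rigid; conformational change on binding is not
  modelled, and no hot-spot or per-residue energetics are attempted.
* Only first-shell interfacial waters are considered.
* IMGT numbering must be supplied; there is no renumbering engine.
* The exact-area fallback path (unresolvable degeneracy) is ~1e-3
  relative, and is only reachable through highly symmetric synthetic
  inputs.
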