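"""Synthetic data with known ground truth.

Two families of fixtures make every stage of the pipeline testable
without external structures:

* analytic ball complexes — one-, two- and three-ball configurations with
  closed-form restriction volumes and areas, lattice patches with
  hand-computable shelling orders, and a small slab-shaped Ig–Ag complex
  (with an optional sandwiched water) whose interface topology is known by
  construction;
* statistical cohorts — labeled descriptor tables in (bsa̅_Ag, bsa̅_Ig)
  space with three ligand classes, and affinity tables in
  (IVW-IPL, NIS_charged) space with a known response surface, emitting the
  same CSV schemas as the real pipeline.

Cohort defaults mirror the study conditions: 489 complexes with class
proportions 0.16/0.25/0.59 (chemical/peptide/protein) for classification,
and a 125-complex training / 14-complex test split with training −ΔG
centred on 10.78 ± 2.84 kcal/mol for affinity regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_model import AtomRecord, ComplexStructure, CONSTANT_REGION

# fixture atoms are carbons (vdW 1.70 Å) and water oxygens (1.52 Å) so
# that PDB round trips through the element radius table are exact
R_C = 1.70
R_O = 1.52


@dataclass
class BallFixture:
    """A ball configuration with its analytically known ground truth."""

    name: str
    atoms: list[AtomRecord]
    truths: dict = field(default_factory=dict)

    def structure(self) -> ComplexStructure:
        return ComplexStructure(
            atoms=list(self.atoms), heavy_chain_id="H", light_chain_id="L",
            ligand_chain_ids=("A",), name=self.name, radius_table="bondi")


def _atom(aid: str, x: float, y: float, z: float, *, chain: str = "H",
          partner: str = "Ig", region: str = CONSTANT_REGION,
          resname: str = "ALA", resseq: str = "1",
          element: str = "C", r: float = R_C) -> AtomRecord:
    return AtomRecord(atom_id=aid, element=element, center=(x, y, z),
                      r_vdw=r, residue_name=resname, residue_seq=resseq,
                      chain_id=chain, partner=partner, region=region)


# ---------------------------------------------------------------------------
# closed-form two-sphere geometry (independent oracle, no shared code with
# the power-diagram backend)
# ---------------------------------------------------------------------------

def sphere_cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of height h on a sphere of radius r."""
    return math.pi * h * h * (3.0 * r - h) / 3.0


def two_sphere_lens_volume(d: float, r1: float, r2: float) -> float:
    """Closed-form volume of the intersection of two spheres."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r ** 3
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    return sphere_cap_volume(r1, r1 - x1) + sphere_cap_volume(r2, r2 - (d - x1))


def make_two_ball(d: float, r1: float, r2: float,
                  partners: tuple[str, str] = ("Ig", "Ag")) -> BallFixture:
    """Two balls on the x-axis with complete closed-form ground truth.

    Truths cover the union volume, per-ball power-diagram restriction
    volumes (ball cut by the radical plane), exposed spherical-cap areas
    and the shared facet (radical-plane disk) area.  ``d = 0`` with equal
    radii is the degenerate coincident case and is flagged as such.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    ball1 = 4.0 / 3.0 * math.pi * r1 ** 3
    ball2 = 4.0 / 3.0 * math.pi * r2 ** 3
    t: dict = {"degenerate": d == 0 and r1 == r2}
    if d >= r1 + r2:  # disjoint
        t.update(union_volume=ball1 + ball2, v_lens=0.0,
                 restriction_volumes=(ball1, ball2),
                 exposed_areas=(4 * math.pi * r1 ** 2, 4 * math.pi * r2 ** 2),
                 facet_area=0.0, contact=False)
    elif d > 0:
        x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
        x2 = d - x1
        lens = two_sphere_lens_volume(d, r1, r2)
        rho2 = r1 * r1 - x1 * x1
        t.update(
            union_volume=ball1 + ball2 - lens, v_lens=lens,
            restriction_volumes=(ball1 - sphere_cap_volume(r1, r1 - x1),
                                 ball2 - sphere_cap_volume(r2, r2 - x2)),
            exposed_areas=(2 * math.pi * r1 * (r1 + x1),
                           2 * math.pi * r2 * (r2 + x2)),
            facet_area=math.pi * max(rho2, 0.0),
            contact=rho2 > 0 and d < r1 + r2,
        )
    atoms = [
        _atom("a1", 0.0, 0.0, 0.0, partner=partners[0],
              chain="H" if partners[0] == "Ig" else "A", r=r1),
        _atom("a2", d, 0.0, 0.0, partner=partners[1],
              chain="A" if partners[1] == "Ag" else "H", r=r2),
    ]
    return BallFixture(name=f"two-ball-d{d}", atoms=atoms, truths=t)


# ---------------------------------------------------------------------------
# shelling-order patch fixtures
# ---------------------------------------------------------------------------

def make_patch_fixture(shape: str, n: int = 5) -> BallFixture:
    """Lattice patches with hand-computable shelling orders.

    ``path``  — n collinear patch atoms, both ends on the rim:
                SO = 1, 2, ..., 2, 1.
    ``disk``  — hexagonal 7-atom patch, rim ring SO = 1, centre SO = 2.
    ``two-component`` — two isolated patch atoms, SO = 1 each.

    Truths carry the patch set, same-partner contact graph, rim
    (boundary) atoms and the expected SO map.
    """
    spacing = 1.5
    atoms: list[AtomRecord] = []
    if shape == "path":
        ids = [f"p{i}" for i in range(n)]
        for i, aid in enumerate(ids):
            atoms.append(_atom(aid, spacing * i, 0.0, 0.0))
        graph = {ids[i]: {ids[j] for j in (i - 1, i + 1) if 0 <= j < n}
                 for i in range(n)}
        boundary = {ids[0], ids[-1]}
        expected = {ids[i]: 1 + min(i, n - 1 - i) for i in range(n)}
    elif shape == "disk":
        ids = ["center"] + [f"ring{i}" for i in range(6)]
        atoms.append(_atom("center", 0.0, 0.0, 0.0))
        for i in range(6):
            ang = math.pi / 3 * i
            atoms.append(_atom(f"ring{i}", spacing * math.cos(ang),
                               spacing * math.sin(ang), 0.0))
        graph = {"center": set(ids[1:])}
        for i in range(6):
            graph[f"ring{i}"] = {"center", f"ring{(i + 1) % 6}", f"ring{(i - 1) % 6}"}
        boundary = set(ids[1:])
        expected = {"center": 2, **{f"ring{i}": 1 for i in range(6)}}
    elif shape == "two-component":
        ids = ["s0", "s1"]
        atoms = [_atom("s0", 0.0, 0.0, 0.0), _atom("s1", 10.0, 0.0, 0.0)]
        graph = {"s0": set(), "s1": set()}
        boundary = set()          # no rim atom at all: SO defaults to 1
        expected = {"s0": 1, "s1": 1}
    else:
        raise ValueError(f"unknown patch shape {shape!r}")
    return BallFixture(name=f"patch-{shape}-{len(atoms)}", atoms=atoms,
                       truths={"patch": set(a.atom_id for a in atoms),
                               "graph": graph, "boundary": boundary,
                               "expected_so": expected})


# ---------------------------------------------------------------------------
# slab Ig–Ag complex fixtures
# ---------------------------------------------------------------------------

def make_slab_complex(with_water: bool = False, nx: int = 4, ny: int = 3,
                      ag_atoms: int = 3, gap: float = 4.2,
                      ag_layout: str = "stack") -> BallFixture:
    """A flat antibody patch facing a small convex ligand.

    The Ig side is an nx × ny carbon grid (spacing 1.8 Å) at z = 0 whose
    central columns are labeled VH CDR residues (IMGT-numbered 105–107,
    i.e. CDR3) and flanks FR3/constant; the Ag side is a short vertical
    stack of ``ag_atoms`` carbons above the centre at z = ``gap``.  With
    ``with_water`` a water oxygen sits between patch edge and ligand,
    touching both partners.
    """
    spacing = 1.8
    atoms: list[AtomRecord] = []
    cx = (nx - 1) * spacing / 2.0
    cy = (ny - 1) * spacing / 2.0
    for i in range(nx):
        for j in range(ny):
            near_center = abs(i * spacing - cx) < spacing
            if near_center:
                seq, region, resname = str(105 + j), "VH-CDR3", "TYR"
            elif i == 0:
                seq, region, resname = str(66 + j), "VH-FR3", "LYS"
            else:
                seq, region, resname = str(130 + i * ny + j), CONSTANT_REGION, "GLU"
            atoms.append(_atom(
                f"H{i}{j}", round(i * spacing, 3), round(j * spacing, 3), 0.0,
                chain="H", partner="Ig", region=region, resname=resname,
                resseq=seq))
    for m in range(ag_atoms):
        if ag_layout == "stack":      # convex/compact ligand: vertical rod
            x, y, z = cx, cy, gap + 1.4 * m
        elif ag_layout == "plate":    # extended flat ligand facing the slab
            x, y, z = (m - (ag_atoms - 1) / 2.0) * spacing + cx, cy, gap
        else:
            raise ValueError(f"unknown ag_layout {ag_layout!r}")
        atoms.append(_atom(f"A{m}", round(x, 3), round(y, 3), round(z, 3),
                           chain="A", partner="Ag", region="antigen",
                           resname="LIG", resseq=str(m + 1)))
    if with_water:
        atoms.append(_atom("W0", round(cx + 2.6, 3), round(cy, 3), 2.6,
                           chain="S", partner="water", region="water",
                           resname="HOH", resseq="1", element="O", r=R_O))
    return BallFixture(name="slab" + ("-water" if with_water else ""),
                       atoms=atoms, truths={})


def make_water_bridge() -> BallFixture:
    """Three collinear balls Ig–W–Ag: no direct partner contact, one
    interfacial water touching both partners."""
    atoms = [
        _atom("ig", 0.0, 0.0, 0.0, chain="H", partner="Ig"),
        _atom("w", 3.2, 0.0, 0.0, chain="S", partner="water",
              resname="HOH", element="O", r=R_O),
        _atom("ag", 6.4, 0.0, 0.0, chain="A", partner="Ag", region="antigen",
              resname="LIG"),
    ]
    return BallFixture(name="water-bridge", atoms=atoms,
                       truths={"n_direct": 0, "n_interfacial_waters": 1})


def random_cluster(n: int, seed: int, box: float = 7.0,
                   rmin: float = 1.2, rmax: float = 2.4) -> list:
    """Random ball cluster for volume-conservation property tests."""
    from .sam_voronoi import SAMBall
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, box, size=(n, 3))
    radii = rng.uniform(rmin, rmax, size=n)
    return [SAMBall(f"r{i:03d}", tuple(centers[i]), float(radii[i]))
            for i in range(n)]


# ---------------------------------------------------------------------------
# PDB round trip
# ---------------------------------------------------------------------------

def write_fixture_pdb(fixture: BallFixture, path: str | Path) -> Path:
    """Write fixture atoms as a PDB file readable by
    :func:`igvor.structure_model.read_structure`."""
    import gemmi

    st = gemmi.Structure()
    st.name = fixture.name
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in fixture.atoms:
        ch = chains.setdefault(a.chain_id, gemmi.Chain(a.chain_id))
        res = None
        for r in ch:
            if str(r.seqid.num) == a.residue_seq and r.name == a.residue_name:
                res = r
                break
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(int(a.residue_seq), " ")
            res.het_flag = "H" if a.residue_name in ("HOH", "LIG") else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.atom_id[-4:].upper()
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.center)
        at.occ = 1.0
        res.add_atom(at)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# statistical cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Specification of a synthetic descriptor/affinity cohort.

    Defaults are the study conditions: 489 complexes, class proportions
    0.16/0.25/0.59, class means in (bsa̅_Ag, bsa̅_Ig) that place chemicals
    at high antigen-side burial per atom and proteins at low, with the two
    features anticorrelated within each class; affinity training/test of
    125/14 with a linear response on (IVW-IPL, NIS_charged) plus Gaussian
    noise, centred on −ΔG = 10.78 kcal/mol.
    """

    n: int = 489
    proportions: dict[str, float] = field(default_factory=lambda: {
        "chemical": 0.16, "peptide": 0.25, "protein": 0.59})
    class_means: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "chemical": (30.0, 7.0), "peptide": (18.0, 9.0), "protein": (9.5, 11.0)})
    class_covs: dict[str, np.ndarray] = field(default_factory=lambda: {
        "chemical": np.array([[9.0, -1.5], [-1.5, 1.0]]),
        "peptide": np.array([[9.0, -1.5], [-1.5, 1.0]]),
        "protein": np.array([[4.0, -1.0], [-1.0, 1.0]])})
    n_train: int = 125
    n_test: int = 14
    ivw_mean: float = 20.0
    ivw_sd: float = 8.0
    nis_mean: float = 0.27
    nis_sd: float = 0.05
    response_coefs: tuple[float, float, float] = (6.94, 0.3, -8.0)  # a+b·ivw+c·nis
    noise_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for c, cov in self.class_covs.items():
            if np.min(np.linalg.eigvalsh(np.asarray(cov))) < -1e-12:
                raise ValueError(f"covariance for {c} not positive semidefinite")


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder rounding of n·p_c to integer counts.

    Remainder ties break by class name for determinism.
    """
    raw = {c: n * p for c, p in proportions.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in order[:short]:
        counts[c] += 1
    return counts


def make_classification_cohort(spec: SyntheticCohort | None = None) -> pd.DataFrame:
    """Labeled (bsa̅_Ag, bsa̅_Ig) table with the requested class structure."""
    spec = spec or SyntheticCohort()
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.n, spec.proportions)
    rows = []
    idx = 0
    for label in sorted(counts):
        mean = np.asarray(spec.class_means[label], dtype=float)
        cov = np.asarray(spec.class_covs[label], dtype=float)
        pts = rng.multivariate_normal(mean, cov, size=counts[label])
        pts = np.maximum(pts, 0.5)  # physical features stay positive
        for x in pts:
            rows.append({"complex_id": f"syn{idx:04d}",
                         "bsa_avg_ag": float(x[0]), "bsa_avg_ig": float(x[1]),
                         "label": label})
            idx += 1
    return pd.DataFrame(rows)


def make_affinity_cohort(spec: SyntheticCohort | None = None) -> pd.DataFrame:
    """Affinity table in (IVW-IPL, NIS_charged) space with a known linear
    response and Gaussian noise; ``is_ig_ag`` marks the test split."""
    spec = spec or SyntheticCohort()
    rng = np.random.default_rng(spec.seed + 1)
    a, b, c = spec.response_coefs
    rows = []
    for part, m in (("train", spec.n_train), ("test", spec.n_test)):
        # test complexes fall in a narrower, well-covered region
        sd_scale = 0.5 if part == "test" else 1.0
        ivw = rng.normal(spec.ivw_mean, spec.ivw_sd * sd_scale, size=m)
        ivw = np.maximum(ivw, 1.0)
        nis = np.clip(rng.normal(spec.nis_mean, spec.nis_sd * sd_scale, size=m),
                      0.0, 1.0)
        resp = a + b * ivw + c * nis + rng.normal(0.0, spec.noise_sd, size=m)
        for i in range(m):
            rows.append({"complex_id": f"{part}{i:04d}",
                         "ivw_ipl": float(ivw[i]), "nis_charged": float(nis[i]),
                         "minus_dG": float(resp[i]),
                         "is_ig_ag": part == "test"})
    return pd.DataFrame(rows)


def make_cohort(spec: SyntheticCohort | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both cohort tables (classification, affinity) from one spec."""
    return make_classification_cohort(spec), make_affinity_cohort(spec)
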