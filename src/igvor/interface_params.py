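"""Per-complex interface descriptors.

From an :class:`~igvor.sam_voronoi.InterfaceModel` this module derives the
statistics that summarise an Ig–Ag interface:

* ``bsa_avg_Ig`` / ``bsa_avg_Ag`` — average buried surface area per
  interface atom on each side (Å²/atom), a curvature proxy distinguishing
  ligand types;
* ``IVW-IPL`` — the inverse volume-weighted internal path length,
  ``Σ_a SO(a)/Vol_bound(a)`` over interface atoms (Å⁻³), combining patch
  morphology (shelling order) with atomic packing (restriction volume);
* ``ANSO`` — IVW-IPL of a region's interface atoms divided by their count;
* ``NIS_charged`` — the fraction of charged residues on the non-interacting
  (solvent-exposed, non-interface) surface of both partners;
* the per-region decomposition over the 6 CDR + 8 FR regions, plus
  constant/outside-V and the antigen side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .sam_voronoi import EXPOSED_AREA_EPS, InterfaceModel
from .structure_model import ComplexStructure, IG_REGIONS

logger = logging.getLogger(__name__)

#: residues counted as charged on the non-interacting surface
DEFAULT_CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"})

#: a residue counts as surface-exposed if its summed bound exposed area
#: exceeds this threshold (Å²)
NIS_SURFACE_THRESHOLD = 1.0

#: region keys of the descriptor decomposition
ALL_REGIONS = IG_REGIONS + ("constant/outside-V", "antigen")


class UndefinedDescriptorError(ValueError):
    """A descriptor is undefined for this interface (e.g. empty side)."""


@dataclass
class RegionStats:
    n_atoms: int = 0
    bsa: float = 0.0
    ivw_ipl: float = 0.0
    anso: float | None = None
    mean_so: float | None = None
    mean_vol: float | None = None


@dataclass
class ComplexDescriptor:
    complex_id: str
    n_interface_ig: int
    n_interface_ag: int
    bsa_ig: float
    bsa_ag: float
    bsa_avg_ig: float
    bsa_avg_ag: float
    ivw_ipl: float
    nis_charged: float | None
    per_region: dict[str, RegionStats] = field(default_factory=dict)

    @property
    def bsa(self) -> float:
        return self.bsa_ig + self.bsa_ag

    @property
    def n_interface(self) -> int:
        return self.n_interface_ig + self.n_interface_ag


def bsa_averages(im: InterfaceModel) -> tuple[float, float]:
    """Average BSA per interface atom, (Ig side, Ag side), Å²/atom.

    Undefined (raises) when either side has no interface atoms; an
    undefined average is never silently reported as zero.
    """
    if not im.interface_ig or not im.interface_ag:
        raise UndefinedDescriptorError("empty interface side: bsa averages undefined")
    return (im.bsa_side("Ig") / len(im.interface_ig),
            im.bsa_side("Ag") / len(im.interface_ag))


def ivw_ipl(im: InterfaceModel, atom_ids: set[str] | None = None,
            form: str = "quotient") -> float:
    """Inverse volume-weighted internal path length over the given atoms.

    ``Σ SO(a)/Vol_bound(a)`` (Å⁻³) over interface atoms; ``atom_ids``
    restricts the sum (whole interface when None).  ``form="product"``
    computes ``Σ SO(a)·Vol_bound(a)`` instead, for audit purposes.
    """
    ids = (im.interface_ig | im.interface_ag) if atom_ids is None \
        else atom_ids & (im.interface_ig | im.interface_ag)
    total = 0.0
    for a in ids:
        so = im.shelling_order.get(a)
        if so is None or so < 1:
            raise ValueError(f"interface atom {a} without shelling order")
        vol = im.restrictions[a].volume_bound
        if vol <= 0:
            raise ValueError(f"interface atom {a} has zero restriction volume")
        total += so * vol if form == "product" else so / vol
    return total


def anso(im: InterfaceModel, atom_ids: set[str], form: str = "quotient") -> float:
    """Average normalized shelling order: IVW-IPL of the atom set divided
    by its size.  Undefined (raises) for an empty set."""
    ids = atom_ids & (im.interface_ig | im.interface_ag)
    if not ids:
        raise UndefinedDescriptorError("ANSO undefined for empty interface atom set")
    return ivw_ipl(im, ids, form=form) / len(ids)


def nis_charged(structure: ComplexStructure, im: InterfaceModel,
                charged: frozenset[str] = DEFAULT_CHARGED_RESIDUES,
                surface_threshold: float = NIS_SURFACE_THRESHOLD) -> float:
    """Fraction of charged residues on the non-interacting surface.

    A residue of either partner belongs to the NIS when it is
    surface-exposed in the bound state (summed bound exposed area above
    ``surface_threshold`` Å²) and contributes no interface atom.  Both
    partners are pooled; waters are ignored.
    """
    interface_atoms = im.interface_ig | im.interface_ag
    n_total = 0
    n_charged = 0
    for partner in ("Ig", "Ag"):
        for key, atoms in structure.residues_of(partner).items():
            if any(a.atom_id in interface_atoms for a in atoms):
                continue
            area = sum(im.restrictions[a.atom_id].exposed_area_bound
                       for a in atoms if a.atom_id in im.restrictions)
            if area <= surface_threshold:
                continue
            n_total += 1
            if atoms[0].residue_name in charged:
                n_charged += 1
    if n_total == 0:
        raise UndefinedDescriptorError("no non-interacting surface residues")
    return n_charged / n_total


def region_atoms(structure: ComplexStructure, im: InterfaceModel) -> dict[str, set[str]]:
    """Interface atoms grouped by region label (Ig regions, outside-V,
    antigen)."""
    interface = im.interface_ig | im.interface_ag
    out: dict[str, set[str]] = {r: set() for r in ALL_REGIONS}
    for a in structure.atoms:
        if a.atom_id in interface and a.region in out:
            out[a.region].add(a.atom_id)
    return out


def compute_descriptor(structure: ComplexStructure, im: InterfaceModel,
                       charged: frozenset[str] = DEFAULT_CHARGED_RESIDUES,
                       surface_threshold: float = NIS_SURFACE_THRESHOLD,
                       ivw_form: str = "quotient") -> ComplexDescriptor:
    """All per-complex descriptors, including the per-region decomposition.

    Interface atoms reachable only through water-mediated pairs count in
    |I_Ig| / |I_Ag| even when their direct BSA is zero.
    """
    bsa_avg_i, bsa_avg_a = bsa_averages(im)
    try:
        nis = nis_charged(structure, im, charged, surface_threshold)
    except UndefinedDescriptorError:
        logger.warning("%s: NIS_charged undefined (all residues at interface)",
                       structure.name)
        nis = None

    per_region: dict[str, RegionStats] = {}
    for reg, ids in region_atoms(structure, im).items():
        rs = RegionStats(n_atoms=len(ids))
        rs.bsa = float(sum(im.per_atom_bsa.get(a, 0.0) for a in ids))
        if ids:
            rs.ivw_ipl = ivw_ipl(im, ids, form=ivw_form)
            rs.anso = rs.ivw_ipl / len(ids)
            rs.mean_so = sum(im.shelling_order[a] for a in ids) / len(ids)
            rs.mean_vol = sum(im.restrictions[a].volume_bound for a in ids) / len(ids)
        per_region[reg] = rs

    return ComplexDescriptor(
        complex_id=structure.name,
        n_interface_ig=len(im.interface_ig),
        n_interface_ag=len(im.interface_ag),
        bsa_ig=im.bsa_side("Ig"),
        bsa_ag=im.bsa_side("Ag"),
        bsa_avg_ig=bsa_avg_i,
        bsa_avg_ag=bsa_avg_a,
        ivw_ipl=ivw_ipl(im, form=ivw_form),
        nis_charged=nis,
        per_region=per_region,
    )


#: flat column order of the descriptor table
DESCRIPTOR_COLUMNS = [
    "complex_id", "n_interface_ig", "n_interface_ag", "bsa_ig", "bsa_ag",
    "bsa_avg_ig", "bsa_avg_ag", "ivw_ipl", "nis_charged",
]


def descriptor_table(descriptors_or_pairs) -> pd.DataFrame:
    """Batch descriptor table: one row per complex, stable column order.

    Accepts either computed :class:`ComplexDescriptor` objects or
    ``(structure, interface_model)`` pairs; per-complex failures are logged
    and skipped without aborting the batch.  Per-region statistics are
    appended as ``<region>_{n,bsa,ivw_ipl,anso}`` columns.
    """
    rows = []
    for item in descriptors_or_pairs:
        try:
            d = item if isinstance(item, ComplexDescriptor) \
                else compute_descriptor(*item)
        except Exception as exc:  # noqa: BLE001 - batch robustness by design
            name = getattr(item, "complex_id", None) or getattr(
                item[0] if isinstance(item, tuple) else item, "name", "?")
            logger.error("descriptor failed for %s: %s", name, exc)
            continue
        row = {c: getattr(d, c) for c in DESCRIPTOR_COLUMNS}
        for reg, rs in d.per_region.items():
            tag = reg.replace("/", "_").replace("-", "_")
            row[f"{tag}_n"] = rs.n_atoms
            row[f"{tag}_bsa"] = rs.bsa
            row[f"{tag}_ivw_ipl"] = rs.ivw_ipl
            row[f"{tag}_anso"] = rs.anso
        rows.append(row)
    return pd.DataFrame(rows)
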