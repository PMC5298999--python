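"""Atomic structures of antibody–antigen complexes.

Parses PDB/mmCIF files (via gemmi), assigns van der Waals radii from a
named radius table, attaches partner roles (heavy/light chain = Ig, ligand
chains = Ag, waters) and CDR/FR region labels following the IMGT unique
numbering, and validates the canonical one-heavy / one-light / one-ligand
complex shape.

IMGT numbering is consumed, never computed: either the Ig chains already
carry IMGT residue numbers, or a sidecar CSV supplies residue ranges per
region.  Hydrogens are dropped (the geometry operates on heavy-atom
solvent-accessible models); altlocs are resolved to the highest occupancy,
ties broken alphabetically.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi

# --- radius tables ---------------------------------------------------------

#: Bondi (1964) element van der Waals radii, Å — the default heavy-atom set
BONDI_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "H": 1.20, "D": 1.20, "B": 1.92, "SI": 2.10,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75,
    "MN": 2.00, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}

#: uniform-carbon table: every heavy atom 1.7 Å (useful for synthetic tests)
UNIFORM_RADII = {"*": 1.70}

RADIUS_TABLES = {"bondi": BONDI_RADII, "uniform": UNIFORM_RADII}

#: fallback radius for unknown elements on hetero ligands, Å
DEFAULT_FALLBACK_RADIUS = 1.70

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}

#: IMGT unique-numbering limits of the V-domain regions (residue numbers)
IMGT_REGION_LIMITS = [
    ("FR1", 1, 26), ("CDR1", 27, 38), ("FR2", 39, 55), ("CDR2", 56, 65),
    ("FR3", 66, 104), ("CDR3", 105, 117), ("FR4", 118, 128),
]

IG_REGIONS = tuple(
    f"{dom}-{reg}" for dom in ("VH", "VL")
    for reg in ("CDR1", "CDR2", "CDR3", "FR1", "FR2", "FR3", "FR4")
)
CONSTANT_REGION = "constant/outside-V"

LIGAND_CLASSES = ("chemical", "peptide", "protein")


@dataclass(frozen=True)
class LigandClass:
    """Closed three-way ligand typing of the antigen."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in LIGAND_CLASSES:
            raise ValueError(f"unknown ligand class {self.value!r}; "
                             f"expected one of {LIGAND_CLASSES}")


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom (or water oxygen) with its ball radius and identity."""

    atom_id: str
    element: str
    center: tuple[float, float, float]
    r_vdw: float
    residue_name: str
    residue_seq: str           # number + optional insertion code, as string
    chain_id: str
    partner: str               # "Ig" | "Ag" | "water"
    region: str                # e.g. "VH-CDR3", "antigen", "water"

    def __post_init__(self) -> None:
        if self.r_vdw <= 0:
            raise ValueError(f"non-positive vdW radius for {self.atom_id}")
        if self.partner not in ("Ig", "Ag", "water"):
            raise ValueError(f"bad partner {self.partner!r}")
        if (self.partner == "water") != (self.residue_name in WATER_RESIDUES):
            raise ValueError(f"partner/water mismatch for {self.atom_id}")

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain_id, self.residue_seq)


@dataclass
class ComplexStructure:
    """A parsed complex: atoms plus chain-role and typing metadata."""

    atoms: list[AtomRecord]
    heavy_chain_id: str | None = None
    light_chain_id: str | None = None
    ligand_chain_ids: tuple[str, ...] = ()
    ligand_type: LigandClass | None = None
    ligand_types_by_chain: dict[str, str] = field(default_factory=dict)
    species: str = "unknown"       # carried metadata, unused by computations
    name: str = ""
    radius_table: str = "bondi"

    def atoms_of(self, partner: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.partner == partner]

    def residues_of(self, partner: str) -> dict[tuple[str, str], list[AtomRecord]]:
        out: dict[tuple[str, str], list[AtomRecord]] = {}
        for a in self.atoms:
            if a.partner == partner:
                out.setdefault(a.residue_key, []).append(a)
        return out

    def to_json(self) -> str:
        """Debug serialization of the atom table."""
        return json.dumps([a.__dict__ for a in self.atoms], indent=1)


class StructureParseError(ValueError):
    pass


def _element_radius(element: str, table: dict[str, float],
                    fallback: float | None) -> float:
    el = element.upper()
    if el in table:
        return table[el]
    if "*" in table:
        return table["*"]
    if fallback is not None:
        return fallback
    raise StructureParseError(f"unknown element {element!r} and no fallback "
                              "radius enabled")


def read_structure(path: str | Path, dialect: str | None = None, *,
                   heavy_chain: str | None = None,
                   light_chain: str | None = None,
                   ligand_chains: tuple[str, ...] | None = None,
                   ligand_type: str | None = None,
                   radius_table: str = "bondi",
                   fallback_radius: float | None = DEFAULT_FALLBACK_RADIUS,
                   keep_waters: bool = True) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Heavy atoms only; altlocs resolved to highest occupancy then
    alphabetical; waters retained as ``partner="water"``.  Chain roles must
    be supplied (or set later); chains not named heavy/light/ligand default
    to ligand when no roles are given at all.
    """
    path = Path(path)
    if dialect is None:
        dialect = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    try:
        if dialect == "mmCIF":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureParseError(f"{path}: no model or no chains")
    st.setup_entities()
    model = st[0]

    table = RADIUS_TABLES[radius_table]
    ig_chains = {c for c in (heavy_chain, light_chain) if c}
    lig_chains = set(ligand_chains or ())

    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            is_water = res.name in WATER_RESIDUES
            # altloc resolution per atom name: highest occupancy, then
            # alphabetical altloc id
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.element.name.upper() in ("H", "D"):
                    continue
                by_name.setdefault(at.name, []).append(at)
            for name, group in sorted(by_name.items()):
                at = sorted(group, key=lambda a: (-a.occ, a.altloc or "~"))[0]
                seq = f"{res.seqid.num}{res.seqid.icode.strip()}"
                if is_water:
                    partner, region = "water", "water"
                elif chain.name in ig_chains:
                    partner, region = "Ig", CONSTANT_REGION
                elif chain.name in lig_chains or not ig_chains:
                    partner, region = "Ag", "antigen"
                else:
                    partner, region = "Ag", "antigen"
                if is_water and not keep_waters:
                    continue
                r = _element_radius(at.element.name, table, fallback_radius)
                atoms.append(AtomRecord(
                    atom_id=f"{chain.name}/{seq}/{res.name}/{name}",
                    element=at.element.name.upper(),
                    center=(at.pos.x, at.pos.y, at.pos.z),
                    r_vdw=r, residue_name=res.name, residue_seq=seq,
                    chain_id=chain.name, partner=partner, region=region,
                ))
    if not atoms:
        raise StructureParseError(f"{path}: no heavy atoms")
    if len({a.atom_id for a in atoms}) != len(atoms):
        raise StructureParseError(f"{path}: duplicate atom identifiers")

    lt = LigandClass(ligand_type) if ligand_type else None
    if ligand_chains is None:
        lig = tuple(sorted({a.chain_id for a in atoms
                            if a.partner == "Ag"}))
    else:
        lig = tuple(ligand_chains)
    return ComplexStructure(
        atoms=atoms, heavy_chain_id=heavy_chain, light_chain_id=light_chain,
        ligand_chain_ids=lig, ligand_type=lt, name=path.stem,
        radius_table=radius_table,
    )


# --- region annotation -----------------------------------------------------

def _split_seq(residue_seq: str) -> tuple[int, str]:
    num = "".join(ch for ch in residue_seq if ch.isdigit() or ch == "-")
    icode = residue_seq[len(num):]
    return int(num), icode


def _imgt_region(residue_seq: str) -> str:
    num, _ = _split_seq(residue_seq)
    for reg, lo, hi in IMGT_REGION_LIMITS:
        if lo <= num <= hi:
            return reg
    return CONSTANT_REGION


def annotate_regions(s: ComplexStructure,
                     annotation: str | Path = "imgt-numbered") -> ComplexStructure:
    """Attach CDR/FR region labels to every Ig atom.

    ``annotation="imgt-numbered"`` applies the IMGT unique-numbering limits
    (FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117,
    FR4 118–128; beyond → constant/outside-V) to the residue numbers of the
    heavy and light chains.  Any other value is a sidecar CSV with columns
    chain_id,start,end,insertion_codes,region listing residue ranges.
    Re-annotation is idempotent.
    """
    domain_of = {}
    if s.heavy_chain_id:
        domain_of[s.heavy_chain_id] = "VH"
    if s.light_chain_id:
        domain_of[s.light_chain_id] = "VL"

    if annotation == "imgt-numbered":
        def label(a: AtomRecord) -> str:
            dom = domain_of.get(a.chain_id)
            if dom is None:
                return a.region
            reg = _imgt_region(a.residue_seq)
            return CONSTANT_REGION if reg == CONSTANT_REGION else f"{dom}-{reg}"
    else:
        ranges: list[tuple[str, int, int, str]] = []
        with open(annotation, newline="") as fh:
            for row in csv.DictReader(fh):
                ranges.append((row["chain_id"], int(row["start"]),
                               int(row["end"]), row["region"]))
        # overlap rejection within each chain
        by_chain: dict[str, list[tuple[int, int, str]]] = {}
        for ch, lo, hi, reg in ranges:
            by_chain.setdefault(ch, []).append((lo, hi, reg))
        for ch, rs in by_chain.items():
            rs.sort()
            for (lo1, hi1, r1), (lo2, hi2, r2) in zip(rs, rs[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"overlapping region ranges on chain {ch}: "
                        f"{r1} [{lo1},{hi1}] and {r2} [{lo2},{hi2}]")

        def label(a: AtomRecord) -> str:
            if a.partner != "Ig":
                return a.region
            num, _ = _split_seq(a.residue_seq)
            for lo, hi, reg in by_chain.get(a.chain_id, ()):
                if lo <= num <= hi:
                    return reg
            return None  # type: ignore[return-value]

    new_atoms = []
    unlabeled: set[tuple[str, str]] = set()
    for a in s.atoms:
        if a.partner != "Ig":
            new_atoms.append(a)
            continue
        reg = label(a)
        if reg is None:
            unlabeled.add(a.residue_key)
            new_atoms.append(a)
        else:
            new_atoms.append(replace(a, region=reg))
    if unlabeled:
        raise ValueError("unlabeled Ig residues under sidecar annotation: "
                         + ", ".join(f"{c}/{r}" for c, r in sorted(unlabeled)))
    return replace(s, atoms=new_atoms)


def validate_canonical(s: ComplexStructure) -> list[str]:
    """Report deviations from the canonical one-H / one-L / one-ligand shape.

    Returns an empty list iff the complex has exactly one heavy chain, one
    light chain, at least one ligand chain, and all ligand chains share one
    ligand class.  Reports, never throws.
    """
    violations = []
    if not s.heavy_chain_id:
        violations.append("missing heavy chain")
    if not s.light_chain_id:
        violations.append("missing light chain")
    if not s.ligand_chain_ids or not s.atoms_of("Ag"):
        violations.append("no ligand atoms")
    if s.ligand_types_by_chain:
        distinct = set(s.ligand_types_by_chain.values())
        if len(distinct) > 1:
            violations.append("mixed ligand types: " + ", ".join(sorted(distinct)))
    return violations
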