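"""Reading, writing, and normalizing crystal structures and annotations.

Structures are parsed with gemmi (PDB and mmCIF dialects) into a flat,
explicit atom-record model.  Only the first model of multi-model entries is
kept: the downstream B-factor analysis assumes a single X-ray conformer.
Alternate locations are collapsed to the highest-occupancy conformer (ties
broken by file order) so that every atom has exactly one coordinate.
Hydrogens are dropped by default; the analyses are heavy-atom based.

DSSP secondary-structure assignments are read from pre-computed DSSP output
files (via Biopython's parser) — the geometric assignment itself is out of
scope here.  A simple CSV table format is also accepted for synthetic data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np

from .radii import DEFAULT_RADII, RadiusSet

#: Residue names treated as water across common PDB dialects.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: DSSP 8-state alphabet; "-" marks coil / unassigned.
SS_CLASSES = ("H", "G", "I", "E", "B", "T", "S", "-")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

ResidueKey = tuple[str, int, str]  # (chain_id, residue_seq, insertion_code)


class StructureError(ValueError):
    """Base class for structure I/O failures."""


class FormatError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class UnknownElementError(StructureError):
    pass


class AnnotationMismatchError(StructureError):
    pass


@dataclass
class AtomRecord:
    """One atom of a crystal structure (single conformer)."""

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float
    b_factor: float  # Å²
    is_hetero: bool
    is_water: bool
    vdw_radius: float | None = None

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_side_chain(self) -> bool:
        """True for side-chain atoms; Gly's CA acts as its side-chain surrogate."""
        if self.residue_name == "GLY" and self.atom_name == "CA":
            return True
        return self.atom_name not in BACKBONE_ATOMS


@dataclass
class Structure:
    """An ordered collection of atom records plus entry-level metadata."""

    id: str
    atoms: list[AtomRecord]
    resolution: float | None = None
    thermal_class: str = "unknown"  # psychrophile / mesophile / thermophile / unknown
    growth_temp: float | None = None

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        out = np.empty(len(self.atoms))
        for i, a in enumerate(self.atoms):
            if a.vdw_radius is None:
                raise StructureError(
                    f"{self.id}: atom {a.serial} ({a.atom_name}) has no vdW radius; "
                    "run assign_radii first"
                )
            out[i] = a.vdw_radius
        return out

    def residue_keys(self, chain: str | None = None) -> list[ResidueKey]:
        """Unique residue keys in atom order, optionally restricted to a chain."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            if chain is None or a.chain_id == chain:
                seen.setdefault(a.residue_key, None)
        return list(seen)

    def n_residues(self, chain: str | None = None, include_waters: bool = False) -> int:
        seen = set()
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if a.is_water and not include_waters:
                continue
            seen.add(a.residue_key)
        return len(seen)

    def subset(self, indices, sid: str | None = None) -> "Structure":
        return Structure(
            id=sid or self.id,
            atoms=[self.atoms[i] for i in indices],
            resolution=self.resolution,
            thermal_class=self.thermal_class,
            growth_temp=self.growth_temp,
        )


@dataclass
class SSAnnotation:
    """Per-residue DSSP class map; unannotated residues read as '-'."""

    classes: dict[ResidueKey, str]

    def get(self, key: ResidueKey) -> str:
        return self.classes.get(key, "-")

    def __len__(self) -> int:
        return len(self.classes)


def _resolve_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per (residue, atom name): max occupancy, ties by file order."""
    best: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        key = (rec.residue_key, rec.residue_name, rec.atom_name)
        if key not in best or rec.occupancy > records[best[key]].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [records[i] for i in keep]


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    keep_hydrogens: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    All ATOM and HETATM records of the first model are captured; waters are
    flagged by residue name; B-factors and occupancies are preserved.
    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default the format is
    detected from the file contents.
    """
    path = Path(path)
    coor_fmt = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[fmt]
    try:
        st = gemmi.read_structure(str(path), format=coor_fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    records: list[AtomRecord] = []
    serial = 0
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]  # first model only
    for chain in model:
        for res in chain:
            hetero = res.het_flag == "H"
            water = res.name in WATER_NAMES or res.is_water()
            for atom in res:
                if not keep_hydrogens and atom.element.is_hydrogen:
                    continue
                serial += 1
                records.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        alt_loc=atom.altloc.replace("\x00", "").strip(),
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=float(atom.occ),
                        b_factor=float(atom.b_iso),
                        is_hetero=hetero,
                        is_water=water,
                    )
                )
    records = _resolve_altlocs(records)
    if not records:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return Structure(
        id=structure_id or st.name or path.stem,
        atoms=records,
        resolution=resolution,
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure to PDB format (fixture/round-trip support)."""
    # gemmi's add_residue/add_chain copy their argument, so the hierarchy is
    # grouped first and assembled bottom-up.
    grouped: dict[str, list[tuple[tuple, list[AtomRecord]]]] = {}
    for rec in structure.atoms:
        rkey = (rec.residue_seq, rec.insertion_code, rec.residue_name)
        chain_groups = grouped.setdefault(rec.chain_id, [])
        if not chain_groups or chain_groups[-1][0] != rkey:
            chain_groups.append((rkey, []))
        chain_groups[-1][1].append(rec)

    st = gemmi.Structure()
    st.name = structure.id
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (seq, icode, name), recs in residues:
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(seq, icode or " ")
            res.het_flag = "H" if recs[0].is_hetero else "A"
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.atom_name
                atom.element = gemmi.Element(rec.element.capitalize())
                atom.pos = gemmi.Position(*rec.coords)
                atom.occ = rec.occupancy
                atom.b_iso = rec.b_factor
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def assign_radii(
    structure: Structure,
    radii: RadiusSet = DEFAULT_RADII,
    overwrite: bool = False,
) -> Structure:
    """Return a structure in which every atom carries a vdW radius.

    Radii already present are kept unless ``overwrite`` is set, which makes
    the operation idempotent and lets generators plant exact radii.  An
    unknown element raises :class:`UnknownElementError` unless the radius
    set defines a fallback.
    """
    out = []
    for a in structure.atoms:
        if a.vdw_radius is not None and not overwrite:
            out.append(a)
            continue
        try:
            r = radii.lookup(a.element, a.atom_name)
        except KeyError as exc:
            raise UnknownElementError(
                f"{structure.id}: no vdW radius for element {a.element!r} "
                f"(atom {a.serial} {a.atom_name})"
            ) from exc
        out.append(replace(a, vdw_radius=r))
    return replace_atoms(structure, out)


def replace_atoms(structure: Structure, atoms: list[AtomRecord]) -> Structure:
    return Structure(
        id=structure.id,
        atoms=atoms,
        resolution=structure.resolution,
        thermal_class=structure.thermal_class,
        growth_temp=structure.growth_temp,
    )


def partition_solvent(structure: Structure) -> tuple[Structure, Structure, Structure]:
    """Split into (polymer, waters, other heteroatoms); conserves atoms exactly."""
    poly, wat, het = [], [], []
    for i, a in enumerate(structure.atoms):
        if a.is_water:
            wat.append(i)
        elif a.is_hetero:
            het.append(i)
        else:
            poly.append(i)
    return (
        structure.subset(poly),
        structure.subset(wat),
        structure.subset(het),
    )


def read_dssp(
    path: str | Path,
    structure: Structure,
    max_mismatch: float = 0.2,
) -> SSAnnotation:
    """Read a classic DSSP output file for ``structure``.

    Residues present in the DSSP file are mapped to their 8-state class
    (G and I are kept distinct from H); residues absent from the file read
    as '-'.  If the fraction of DSSP residues that cannot be matched to the
    structure exceeds ``max_mismatch`` the file is presumed to belong to a
    different entry and an error is raised.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp_dict, _keys = make_dssp_dict(str(path))
    except Exception as exc:  # Bio raises bare Exception subtypes
        raise FormatError(f"{path}: not parseable as DSSP ({exc})") from exc

    known = set(structure.residue_keys())
    classes: dict[ResidueKey, str] = {}
    missing = 0
    for (chain_id, res_id), values in dssp_dict.items():
        _het, seq, icode = res_id
        key = (chain_id, int(seq), icode.strip())
        ss = values[1] if len(values) > 1 else "-"
        if ss in (" ", "", "C"):
            ss = "-"
        if key not in known:
            missing += 1
            continue
        classes[key] = ss
    total = len(dssp_dict)
    if total and missing / total > max_mismatch:
        raise AnnotationMismatchError(
            f"{path}: {missing}/{total} DSSP residues absent from structure "
            f"{structure.id}; wrong entry?"
        )
    return SSAnnotation(classes)


def read_ss_table(path: str | Path) -> SSAnnotation:
    """Read secondary structure from a CSV table (chain,residue_seq,icode,ss)."""
    classes: dict[ResidueKey, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["chain"], int(row["residue_seq"]), row.get("icode", "") or "")
            classes[key] = row["ss"]
    return SSAnnotation(classes)


def write_ss_table(ss: SSAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain", "residue_seq", "icode", "ss"])
        for (chain, seq, icode), cls in ss.classes.items():
            w.writerow([chain, seq, icode, cls])
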